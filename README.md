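# branchnet

Stochastic models and image-analysis tools for **branched microtubule
networks** — the autocatalytic structures formed when new microtubules
(MTs) nucleate from the lattice of existing ones, as in branching MT
nucleation driven by TPX2 and augmin/γ-TuRC in *Xenopus* egg extract.

The package is aimed at quantitative cell biologists and modelers who want
to (a) simulate branched-network assembly under competing kinetic schemes,
(b) validate tracking and lineage-assignment pipelines against synthetic
microscopy data with exact ground truth, and (c) estimate binding kinetics
from kymographs and single-molecule photobleaching.

## The models

A network starts from one de novo MT of zero length; plus-ends grow at the
constant net speed v_pe = 0.09 µm/s and daughters branch at shallow
Gaussian angles (0° ± 9°).

* **Single-step model** — nucleators bind the lattice and instantly fire a
  branch: per step, N ~ Poisson(k·Δt·L(t)) branches appear uniformly over
  the existing length L(t), with k = 1.1×10⁻³ µm⁻¹s⁻¹.  The fractional
  position of a branch along its mother is Uniform(0, 1); on a single
  mother the first-branch law is Rayleigh, S(t) = exp(−k·v_pe·t²/2), with
  mean mother length √(π·v_pe/2k) ≈ 11.3 µm.
* **Sequential model** — nucleation *sites* deposit first
  (k_bind = 0.1 µm⁻¹s⁻¹, Poisson over the lattice) and each site later
  fires at rate k_branch = 2.5×10⁻⁴ s⁻¹.  Sites accumulate on old lattice
  while the plus-end keeps growing, so branching is biased toward the
  minus-end with a dead zone at the plus-end.  The regime is set by the
  dimensionless ratio k_branch/√(k_bind·v_pe) (≈ 2.6×10⁻³ at the
  defaults); above ~100 the model collapses onto the single-step limit.

Analytic first-branch and growth-rate oracles accompany both simulators,
so every stochastic result can be checked against an independent
reference.

Around the models, the package provides ground-truthed synthetic
microscopy (tubulin/EB1 stacks, fragmented plus-end tracks, illumination
fields, photobleach traces, TPX2 kymographs), reconstruction of complete
MT trajectories from broken EB1 comet tracks via a temporally greedy,
lattice-evidence-gated merge (cost 1.03^t_gap·D_min), greedy
mother-assignment and branch-angle statistics, bootstrap distribution
comparisons, and slope/step kinetic estimators.  See `docs/methods.md`
for the full model and algorithm description.

## Worked example

```python
import numpy as np
from branchnet import SimParams, simulate_sequential, first_branch_record
from branchnet.simulate import sample_first_branch, sequential_first_branch_oracle
from branchnet.pipeline import truth_trajectories
from branchnet.architecture import assign_mothers

params = SimParams(seed=1)

# first-branch ensemble vs the analytic oracle
ens = sample_first_branch("sequential", params, 2000, np.random.default_rng(2))
mean_len = (ens["d_minus"] + ens["d_plus"]).mean()
_, mean_t, oracle_len = sequential_first_branch_oracle(params)
print(f"mean mother length at first branch: {mean_len:.2f} um "
      f"(oracle {oracle_len:.2f} um, mean time {mean_t:.1f} s)")
print(f"mean fractional position: {ens['fraction'].mean():.3f}")

# branch-angle recovery from simulated trajectories
angles = []
for i in range(20):
    net = simulate_sequential(params.replace(seed=100 + i, t_max=2400, max_mts=20))
    trajs = [t for t in truth_trajectories(net) if t.n_frames >= 6]
    angles += [a.angle_deg for a in assign_mothers(trajs)]
angles = np.array(angles)
print(f"{angles.size} assignments: median {np.median(angles):+.2f} deg, "
      f"sd {angles.std(ddof=1):.2f} deg")
```

Output:

```
mean mother length at first branch: 11.32 um (oracle 11.18 um, mean time 124.2 s)
mean fractional position: 0.331
322 assignments: median +0.30 deg, sd 9.55 deg
```

The mean fractional position well below 0.5 is the minus-end bias of the
sequential model (a uniform profile would give 0.500); the recovered
branch angles reproduce the generative 0° ± 9° distribution.

A command-line interface mirrors the library:

```bash
branchnet simulate --model sequential --n 2000 --seed 1 \
    --first-branch-only --out ensemble
branchnet kinetics --seed 1 --out kinetics.json
branchnet report --seed 1 --n 1000 --out report/
```

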