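"""Domain types and bookkeeping for simulated branched microtubule networks.

A branched network starts from a single de novo microtubule (MT) of zero
length at t = 0 and grows by branching nucleation: daughters are born on the
lattice of an existing mother, at a shallow angle, with the same polarity.
Every MT is a straight 2-D ray growing at the constant net plus-end speed
``v_pe`` (growth, pause and catastrophe phases are subsumed in the net
speed).  Units throughout: lengths in µm, times in s, angles in degrees.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

FORMAT_NAME = "branchnet-network"
FORMAT_VERSION = 1


@dataclass
class SimParams:
    """Kinetic and geometric parameters shared by both branching models.

    Parameters
    ----------
    v_pe : float
        Net plus-end growth speed, µm/s.
    k : float
        Single-step model nucleator binding rate, molecules µm⁻¹ s⁻¹.
    k_bind : float
        Sequential model site-deposition rate, molecules µm⁻¹ s⁻¹.
    k_branch : float
        Sequential model per-site branching rate, s⁻¹.
    angle_mean, angle_sd : float
        Branch-angle distribution (Gaussian, degrees); the rotation sign
        is a fair coin.
    dt : float
        Simulation step, s.
    t_max : float
        Maximum simulated time, s.
    max_mts : int
        Stop once this many MTs exist.
    seed : int
        RNG seed.
    """

    v_pe: float = 0.09
    k: float = 1.1e-3
    k_bind: float = 0.1
    k_branch: float = 2.5e-4
    angle_mean: float = 0.0
    angle_sd: float = 9.0
    dt: float = 1.0
    t_max: float = 600.0
    max_mts: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        if self.v_pe <= 0:
            raise ValueError("v_pe must be > 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        for name in ("k", "k_bind", "k_branch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.angle_sd < 0:
            raise ValueError("angle_sd must be >= 0")
        # step-accuracy guard: per-step branching probability must stay small
        if self.dt * self.k_branch >= 0.1:
            raise ValueError("dt * k_branch must be < 0.1 (step too coarse)")

    def replace(self, **kwargs) -> "SimParams":
        d = asdict(self)
        d.update(kwargs)
        return SimParams(**d)


@dataclass
class Microtubule:
    id: int
    birth_time: float
    minus_end: tuple[float, float]
    direction: tuple[float, float]  # unit vector
    mother_id: Optional[int] = None
    branch_arc_pos: Optional[float] = None  # µm from mother's minus-end

    def length(self, t: float, v_pe: float) -> float:
        """Length at time t (0 before birth)."""
        return max(0.0, v_pe * (t - self.birth_time))

    def plus_end(self, t: float, v_pe: float) -> np.ndarray:
        return np.asarray(self.minus_end) + self.length(t, v_pe) * np.asarray(
            self.direction
        )


@dataclass
class NucleationSite:
    """A deposited, not-yet-fired branching site (sequential model only)."""

    id: int
    mt_id: int
    arc_pos: float  # µm from host minus-end
    deposit_time: float
    branch_time: Optional[float] = None  # set when the site fires


@dataclass
class BranchNetwork:
    params: SimParams
    mts: list[Microtubule] = field(default_factory=list)
    sites: list[NucleationSite] = field(default_factory=list)
    t_end: float = 0.0
    model: str = "single_step"  # or "sequential"

    def mt_by_id(self, mt_id: int) -> Microtubule:
        return self._index()[mt_id]

    def _index(self) -> dict[int, Microtubule]:
        return {m.id: m for m in self.mts}

    @property
    def seed_mt(self) -> Microtubule:
        roots = [m for m in self.mts if m.mother_id is None]
        if len(roots) != 1:
            raise ValueError(f"network has {len(roots)} seed MTs, expected 1")
        return roots[0]


def total_length(network: BranchNetwork, t: float) -> float:
    """Total MT length at time t: Σ v_pe·(t − birth_i) over MTs born by t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t > network.t_end + 1e-9:
        raise ValueError(f"t={t} exceeds simulated horizon t_end={network.t_end}")
    v = network.params.v_pe
    return float(sum(v * (t - m.birth_time) for m in network.mts if m.birth_time <= t))


def validate(network: BranchNetwork) -> list[str]:
    """Check the structural invariants; return a list of violation messages.

    An empty list means the network is internally consistent: unit
    directions, a single seed, mothers born before daughters (so the
    lineage is a tree), branch origins within the mother's length at the
    daughter's birth, and sites within their host's length at deposit.
    """
    out: list[str] = []
    v = network.params.v_pe
    idx = network._index()
    roots = [m for m in network.mts if m.mother_id is None]
    if network.mts and len(roots) != 1:
        out.append(f"network: {len(roots)} seed MTs (mother_id=None), expected exactly 1")
    for m in network.mts:
        n = math.hypot(*m.direction)
        if abs(n - 1.0) > 1e-6:
            out.append(f"mt {m.id}: |direction| = {n:.6f} != 1")
        if m.mother_id is not None:
            mother = idx.get(m.mother_id)
            if mother is None:
                out.append(f"mt {m.id}: mother {m.mother_id} not in network")
                continue
            if mother.birth_time > m.birth_time:
                out.append(
                    f"mt {m.id}: mother {mother.id} born later "
                    f"({mother.birth_time} > {m.birth_time})"
                )
            if m.branch_arc_pos is None:
                out.append(f"mt {m.id}: non-seed MT missing branch_arc_pos")
            elif m.branch_arc_pos > mother.length(m.birth_time, v) + 1e-9:
                out.append(
                    f"mt {m.id}: branch_arc_pos {m.branch_arc_pos:.4f} exceeds "
                    f"mother length {mother.length(m.birth_time, v):.4f} at birth"
                )
    for s in network.sites:
        host = idx.get(s.mt_id)
        if host is None:
            out.append(f"site {s.id}: host MT {s.mt_id} not in network")
            continue
        if s.arc_pos > host.length(s.deposit_time, v) + 1e-9:
            out.append(
                f"site {s.id}: arc_pos {s.arc_pos:.4f} exceeds host length "
                f"{host.length(s.deposit_time, v):.4f} at deposit"
            )
        if s.branch_time is not None and s.branch_time < s.deposit_time:
            out.append(f"site {s.id}: branch_time precedes deposit_time")
    return out


@dataclass
class FirstBranchRecord:
    """Geometry of the first branching event on the naked de novo mother.

    m0 is the mother's minus-end, m1 the daughter origin, p0 the mother's
    plus-end at the branch time t1.  d_minus = |m0−m1|, d_plus = |p0−m1|,
    fraction = d_minus/(d_minus+d_plus) ∈ [0, 1].
    """

    m0: tuple[float, float]
    m1: tuple[float, float]
    p0: tuple[float, float]
    d_minus: float
    d_plus: float
    fraction: float
    t1: float


# ---------------------------------------------------------------------------
# serialization (JSON with a units header)

def _network_to_dict(network: BranchNetwork) -> dict:
    return {
        "format": FORMAT_NAME,
        "version": FORMAT_VERSION,
        "units": {"length": "um", "time": "s", "angle": "deg"},
        "model": network.model,
        "t_end": network.t_end,
        "params": asdict(network.params),
        "mts": [asdict(m) for m in network.mts],
        "sites": [asdict(s) for s in network.sites],
    }


def save_network(network: BranchNetwork, path) -> None:
    with open(path, "w") as fh:
        json.dump(_network_to_dict(network), fh, indent=1)


def load_network(path) -> BranchNetwork:
    with open(path) as fh:
        d = json.load(fh)
    if d.get("format") != FORMAT_NAME:
        raise ValueError(f"not a {FORMAT_NAME} file: format={d.get('format')!r}")
    if d.get("version") != FORMAT_VERSION:
        warnings.warn(
            f"network file version {d.get('version')} != {FORMAT_VERSION}; "
            "attempting best-effort load"
        )
    try:
        params = SimParams(**d["params"])
    except KeyError as e:
        raise ValueError(f"network file missing field: {e}") from e
    except TypeError as e:
        raise ValueError(f"network file params malformed: {e}") from e
    if "params" not in d or "v_pe" not in d["params"]:
        raise ValueError("network file missing field: v_pe")
    mts = [
        Microtubule(
            id=m["id"],
            birth_time=m["birth_time"],
            minus_end=tuple(m["minus_end"]),
            direction=tuple(m["direction"]),
            mother_id=m["mother_id"],
            branch_arc_pos=m["branch_arc_pos"],
        )
        for m in d["mts"]
    ]
    sites = [NucleationSite(**s) for s in d.get("sites", [])]
    return BranchNetwork(
        params=params, mts=mts, sites=sites, t_end=d["t_end"], model=d["model"]
    )
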