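"""Network-architecture statistics: branch angles, nucleation profiles,
end-position distributions, bootstrap confidence bands, self-similarity.

The central operation is greedy mother assignment: each reconstructed
trajectory is matched to the earlier trajectory whose recorded lattice
passes closest to the daughter's origin, subject to distance, angle and
crossing gates.  The signed angle between the daughter's initial direction
and the mother's local direction is the branch angle; over an ensemble of
branched networks its median is ~0° with an s.d. of ~9°.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from shapely.geometry import LineString, Point

from .core import BranchNetwork, FirstBranchRecord
from .tracking import Trajectory

__all__ = [
    "MotherAssignment",
    "DistanceDistribution",
    "AssignConfig",
    "assign_mothers",
    "first_branch_profile",
    "plus_end_distance_distribution",
    "minus_end_distance_distribution",
    "bootstrap_ci",
    "exponential_count_fit",
    "self_similarity_ks",
]


@dataclass
class MotherAssignment:
    daughter: int
    mother: int
    angle_deg: float  # signed
    D_min: float
    D_perp: float
    N_dot: float


@dataclass
class AssignConfig:
    max_angle_deg: float = 150.0
    max_dist_px: float = 20.0  # cap on both D_min and D_perp
    extrapolate_d_perp_px: float = 8.0  # trigger backward extrapolation
    extrapolate_angle_deg: float = 9.0  # near-parallel trigger
    many_candidates: int = 3  # above this, cost = D_min + 1 − N_dot
    n_fit: int = 10
    cross_ignore_px: float = 3.0  # the daughter origin touches the mother


def _tls_direction(pts: np.ndarray) -> np.ndarray:
    if len(pts) < 2:
        return np.array([1.0, 0.0])
    c = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    d = vt[0]
    if np.dot(pts[-1] - pts[0], d) < 0:
        d = -d
    n = np.linalg.norm(d)
    return d / n if n > 0 else np.array([1.0, 0.0])


def _signed_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Signed angle (degrees) rotating u onto v, in (−180, 180]."""
    return math.degrees(math.atan2(
        u[0] * v[1] - u[1] * v[0], u[0] * v[0] + u[1] * v[1]
    ))


def assign_mothers(
    trajectories: list[Trajectory], config: AssignConfig | None = None
) -> list[MotherAssignment]:
    """Greedy mother assignment for every non-first trajectory.

    For daughter i, every earlier-born trajectory j is scored by the
    distance D_min from i's start to the closest point of j recorded
    before i's birth.  Candidates fail on |angle| > 150°, D_min or
    D_perp > 20 px, or when i's path crosses over j.  When the geometry is
    ambiguous (D_perp > 8 px, or the tracks are nearly parallel, < 9°),
    the daughter is extrapolated backwards and D_min re-assigned to the
    intersection with j.  The minimum D_min wins (D_min + 1 − N_dot when
    more than 3 candidates survive).  Unassigned daughters are treated as
    de novo nucleations, not errors.
    """
    cfg = config or AssignConfig()
    by_birth = sorted(trajectories, key=lambda tr: (tr.birth_frame, tr.id))
    out: list[MotherAssignment] = []
    for idx, ti in enumerate(by_birth):
        if idx == 0:
            continue
        start = ti.xy[0]
        dir_i = _tls_direction(ti.xy[: cfg.n_fit])
        line_i = LineString(ti.xy[1:]) if ti.n_frames > 2 else None
        candidates = []
        for tj in by_birth:
            if tj.id == ti.id or tj.birth_frame >= ti.birth_frame:
                continue
            # positions of j recorded before i's start
            mask = tj.frames <= ti.birth_frame
            pts = tj.xy[mask]
            if len(pts) < 2:
                continue
            d = np.linalg.norm(pts - start, axis=1)
            kmin = int(d.argmin())
            D_min = float(d[kmin])
            lo = max(0, kmin - cfg.n_fit // 2)
            local = pts[lo : lo + cfg.n_fit]
            dir_j = _tls_direction(local)
            p_j = pts[kmin]
            # perpendicular distance of i's start from j's local line
            rel = start - p_j
            D_perp = abs(rel[0] * dir_j[1] - rel[1] * dir_j[0])
            angle = _signed_angle(dir_j, dir_i)
            if abs(angle) > cfg.max_angle_deg:
                continue
            # ambiguous geometry: extrapolate i backwards to intersect j
            if D_perp > cfg.extrapolate_d_perp_px or abs(angle) < cfg.extrapolate_angle_deg:
                q = _line_intersection(start, dir_i, p_j, dir_j)
                if q is None:
                    continue
                # the intersection must lie on lattice recorded before i starts
                along = np.dot(q - pts[0], dir_j)
                max_along = np.dot(pts[-1] - pts[0], dir_j)
                if along < -cfg.cross_ignore_px or along > max_along + cfg.cross_ignore_px:
                    continue
                D_min = float(np.linalg.norm(q - start))
            if D_min > cfg.max_dist_px or D_perp > cfg.max_dist_px:
                continue
            # reject candidates whose path the daughter crosses over
            if line_i is not None and _crosses(line_i, tj.xy, start, cfg.cross_ignore_px):
                continue
            n_dot = float(np.dot(dir_i, dir_j))
            candidates.append((D_min, D_perp, n_dot, angle, tj.id))
        if not candidates:
            continue
        if len(candidates) > cfg.many_candidates:
            best = min(candidates, key=lambda c: c[0] + 1.0 - c[2])
        else:
            best = min(candidates, key=lambda c: c[0])
        D_min, D_perp, n_dot, angle, mother = best
        out.append(
            MotherAssignment(
                daughter=ti.id, mother=mother, angle_deg=angle,
                D_min=D_min, D_perp=D_perp, N_dot=n_dot,
            )
        )
    return out


def _line_intersection(p, u, q, v):
    """Intersection of lines p + s·u and q + r·v; None if near-parallel."""
    det = u[0] * v[1] - u[1] * v[0]
    if abs(det) < 1e-9:
        return None
    dq = q - p
    s = (dq[0] * v[1] - dq[1] * v[0]) / det
    return p + s * u


def _crosses(line_i: LineString, xy_j: np.ndarray, start, ignore_px: float) -> bool:
    if len(xy_j) < 2:
        return False
    inter = line_i.intersection(LineString(xy_j))
    if inter.is_empty:
        return False
    origin = Point(start)
    geoms = getattr(inter, "geoms", [inter])
    for g in geoms:
        if g.distance(origin) > ignore_px:
            return True
    return False


# ---------------------------------------------------------------------------
# distributions

@dataclass
class DistanceDistribution:
    values: np.ndarray  # normalized distances in [0, 1]
    bin_edges: np.ndarray
    prob: np.ndarray  # per-bin probability (sums to 1)
    ci_lo: np.ndarray | None = None
    ci_hi: np.ndarray | None = None
    level: float = 0.95

    @property
    def n(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        centers = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        d = {"bin_center": centers, "probability": self.prob}
        if self.ci_lo is not None:
            d["ci_lo"], d["ci_hi"] = self.ci_lo, self.ci_hi
        return pd.DataFrame(d)


def _make_distribution(
    values: np.ndarray,
    bins: int | np.ndarray = 10,
    rng: np.random.Generator | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    vmax: float | None = None,
) -> DistanceDistribution:
    values = np.asarray(values, dtype=float)
    edges = (
        np.linspace(0.0, vmax if vmax is not None else max(1.0, values.max()), bins + 1)
        if np.isscalar(bins)
        else np.asarray(bins, dtype=float)
    )
    counts, _ = np.histogram(values, bins=edges)
    prob = counts / max(1, counts.sum())
    ci_lo = ci_hi = None
    if rng is not None and len(values) >= 10:
        ci_lo, ci_hi = bootstrap_ci(values, edges, n_boot=n_boot, level=level, rng=rng)
    return DistanceDistribution(values, edges, prob, ci_lo, ci_hi, level)


def first_branch_profile(
    records: list[FirstBranchRecord],
    bins: int = 10,
    rng: np.random.Generator | None = None,
    n_boot: int = 1000,
) -> dict[str, DistanceDistribution]:
    """Histograms (with bootstrap CIs) of d_minus, d_plus and the
    fractional first-branch position.  The d_plus histogram measures the
    distance from the mother's plus-end, so small values mean branches
    close to the growing tip."""
    if not records:
        raise ValueError("need at least one first-branch record")
    d_minus = np.array([r.d_minus for r in records])
    d_plus = np.array([r.d_plus for r in records])
    fraction = np.array([r.fraction for r in records])
    dmax = float(max(d_minus.max(), d_plus.max()))
    return {
        "d_minus": _make_distribution(d_minus, bins, rng, n_boot, vmax=dmax),
        "d_plus": _make_distribution(d_plus, bins, rng, n_boot, vmax=dmax),
        "fraction": _make_distribution(fraction, bins, rng, n_boot, vmax=1.0),
    }


def plus_end_distance_distribution(
    comets: pd.DataFrame,
    origin: tuple[float, float],
    count_window: tuple[int, int] = (10, 55),
    bins: int = 10,
    rng: np.random.Generator | None = None,
) -> DistanceDistribution:
    """Pooled, per-frame self-normalized comet distances from the origin.

    Frames whose comet count lies outside ``count_window`` are skipped;
    within a frame every distance is rescaled by that frame's maximum
    (a proxy for the network length).
    """
    vals = []
    for f, g in comets.groupby("frame"):
        n = len(g)
        if not (count_window[0] <= n <= count_window[1]):
            continue
        d = np.hypot(g["x_px"] - origin[0], g["y_px"] - origin[1]).to_numpy()
        m = d.max()
        vals.append(d / m if m > 0 else np.zeros_like(d))
    if not vals:
        return DistanceDistribution(
            np.empty(0), np.linspace(0, 1, bins + 1), np.zeros(bins)
        )
    return _make_distribution(np.concatenate(vals), bins, rng, vmax=1.0)


def minus_end_distance_distribution(
    network: BranchNetwork,
    t: float | None = None,
    bins: int = 10,
    rng: np.random.Generator | None = None,
) -> DistanceDistribution:
    """Normalized minus-end distances from the network origin (simulation
    truth; minus-ends are unobservable in images).  The seed MT length at
    t (the network extent proxy) sets the scale."""
    t = network.t_end if t is None else t
    seed = network.seed_mt
    origin = np.asarray(seed.minus_end)
    scale = seed.length(t, network.params.v_pe)
    if scale <= 0:
        return DistanceDistribution(
            np.zeros(1), np.linspace(0, 1, bins + 1),
            np.eye(1, bins, 0).ravel(),
        )
    d = np.array(
        [
            np.linalg.norm(np.asarray(m.minus_end) - origin) / scale
            for m in network.mts
            if m.birth_time <= t
        ]
    )
    return _make_distribution(d, bins, rng, vmax=max(1.0, float(d.max())))


def bootstrap_ci(
    sample: np.ndarray,
    bin_edges: np.ndarray,
    n_boot: int = 1000,
    level: float = 0.95,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Percentile bootstrap CI for per-bin histogram probabilities."""
    sample = np.asarray(sample)
    if len(sample) < 10:
        raise ValueError("need at least 10 observations for a bootstrap CI")
    rng = np.random.default_rng(0) if rng is None else rng
    n = len(sample)
    probs = np.empty((n_boot, len(bin_edges) - 1))
    for b in range(n_boot):
        res = sample[rng.integers(0, n, n)]
        counts, _ = np.histogram(res, bins=bin_edges)
        probs[b] = counts / n
    alpha = (1.0 - level) / 2.0
    return (
        np.quantile(probs, alpha, axis=0),
        np.quantile(probs, 1.0 - alpha, axis=0),
    )


def exponential_count_fit(counts: np.ndarray, times_min: np.ndarray) -> float:
    """Least-squares fit of a·exp(k·t) to MT counts; returns k in min⁻¹.

    Falls back to a log-linear regression when the nonlinear fit fails.
    """
    counts = np.asarray(counts, dtype=float)
    times_min = np.asarray(times_min, dtype=float)
    if (counts < 1).any():
        raise ValueError("counts must be >= 1")
    if np.allclose(counts, counts[0]):
        return 0.0
    try:
        (a, k), _ = optimize.curve_fit(
            lambda t, a, k: a * np.exp(k * t),
            times_min, counts, p0=(counts[0], 0.1), maxfev=10000,
        )
        return float(k)
    except RuntimeError:
        import warnings

        warnings.warn("exponential fit failed; using log-linear fallback")
        slope, _ = np.polyfit(times_min, np.log(counts), 1)
        return float(slope)


def self_similarity_ks(dist_early: np.ndarray, dist_late: np.ndarray) -> float:
    """Two-sample KS statistic between normalized distance samples."""
    if len(dist_early) == 0 or len(dist_late) == 0:
        raise ValueError("both samples must be non-empty")
    return float(stats.ks_2samp(dist_early, dist_late).statistic)
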