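"""Reconstruction of complete microtubule trajectories from EB1 comets.

EB1 comets mark growing plus-ends but vanish during pauses and
catastrophes, so raw comet tracks are fragments of the true MT trajectory.
The pipeline here is: temporal median filtering of the EB1 channel, comet
detection, frame-to-frame linking into track segments, and a temporally
greedy merge of segments across gaps.  The merge combines geometric gates
(fluctuation radius, forward cones, catastrophe back-steps) with evidence
from the tubulin channel: the mean line-integral intensity I_MT across the
gap chord must exceed a cutoff, because a genuine gap lies on lattice that
is already polymerized.  Cost for competing candidates is
``1.03^t_gap · D_min`` and the minimum wins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, interpolate
from skimage.feature import peak_local_max

from .imaging import ImageStack

__all__ = [
    "CometDetection",
    "TrackSegment",
    "MergeConfig",
    "CandidateScore",
    "Trajectory",
    "temporal_median_filter",
    "preprocess_tubulin",
    "detect_comets",
    "link_comets",
    "line_integral_intensity",
    "merge_tracks",
    "segments_from_table",
    "measure_length_series",
    "net_plus_end_speed",
]


@dataclass
class CometDetection:
    frame: int
    x: float
    y: float
    intensity: float = 0.0


@dataclass
class TrackSegment:
    id: int
    frames: np.ndarray  # strictly increasing
    xy: np.ndarray  # (n, 2) sub-pixel positions

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=int)
        self.xy = np.asarray(self.xy, dtype=float)
        if len(self.frames) > 1 and not (np.diff(self.frames) > 0).all():
            raise ValueError("segment frames must be strictly increasing")

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def start(self) -> np.ndarray:
        return self.xy[0]

    @property
    def end(self) -> np.ndarray:
        return self.xy[-1]

    def extent_px(self) -> float:
        return float(np.linalg.norm(self.xy[-1] - self.xy[0]))

    def direction(self, at: str = "end", n_fit: int = 10) -> np.ndarray:
        """Unit direction of motion by total-least-squares over the first or
        last min(n_fit, len) detections, oriented along increasing time."""
        pts = self.xy[-n_fit:] if at == "end" else self.xy[:n_fit]
        if len(pts) == 1:
            return np.array([1.0, 0.0])
        c = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(c, full_matrices=False)
        d = vt[0]
        if np.dot(pts[-1] - pts[0], d) < 0:
            d = -d
        n = np.linalg.norm(d)
        return d / n if n > 0 else np.array([1.0, 0.0])


@dataclass
class MergeConfig:
    """Parameters of the greedy gap-merging procedure (pixels / frames)."""

    dt_max: int = 30
    r_fluc: float = 3.0
    pause_max_frames: int = 15
    long_gap_speed_max: float = 2.0  # px/frame
    forward_gap_speed_min: float = 0.5  # px/frame; a forward gap is growth
    short_gap_frames_max: int = 6
    short_gap_speed_max: float = 5.0  # px/frame
    catastrophe_max_dist: float = 10.0
    d_perp_max: float = 10.0
    angle_small_track_deg: float = 40.0
    angle_strict_deg: float = 20.0
    angle_catastrophe_deg: float = 30.0
    catastrophe_fallback_deg: float = 90.0
    cost_base: float = 1.03
    i_cutoff_factor: float = 20.0
    median_gap_px: float = 8.8
    min_track_frames: int = 6

    def i_cutoff(self, processed_tubulin: np.ndarray) -> float:
        """Evidence threshold: (factor × mean processed tubulin) / median gap length."""
        return self.i_cutoff_factor * float(np.mean(processed_tubulin)) / self.median_gap_px


@dataclass
class CandidateScore:
    i: int
    j: int
    t_gap: int
    d_ends: float
    D_min: float
    D_perp: float
    N_dot: float
    I_MT: float
    gap_class: str  # zero_gap | pause | forward_gap | catastrophe
    cost: float = 0.0


@dataclass
class Trajectory:
    id: int
    frames: np.ndarray  # one entry per frame over the lifespan
    xy: np.ndarray
    source_segments: list[int] = field(default_factory=list)
    gap_classes: list[str] = field(default_factory=list)

    @property
    def birth_frame(self) -> int:
        return int(self.frames[0])

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# preprocessing and detection

def temporal_median_filter(stack: ImageStack, window: int = 15) -> ImageStack:
    """Subtract the per-pixel moving median over ``window`` frames.

    out[t] = in[t] − median(in[t−w..t+w]), clamped at 0; windows are
    truncated at the stack edges.  Static background vanishes while moving
    comets (which occupy any pixel for less than half the window) survive.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    data = stack.data
    T = data.shape[0]
    if T < window:
        warnings.warn(f"stack has {T} < {window} frames; windows truncated throughout")
    half = window // 2
    out = np.empty_like(data)
    for t in range(T):
        lo, hi = max(0, t - half), min(T, t + half + 1)
        out[t] = np.clip(data[t] - np.median(data[lo:hi], axis=0), 0, None)
    return ImageStack(out, stack.pixel_size, stack.frame_interval, stack.channel)


def preprocess_tubulin(
    stack: ImageStack,
    background_roi: tuple[slice, slice] | None = None,
    highpass_px: float = 60.0,
) -> ImageStack:
    """Prepare the tubulin channel for gap-evidence measurements.

    Structures larger than ~``highpass_px`` are removed by subtracting a
    wide Gaussian blur; photobleaching is corrected by a simple-ratio
    scheme from an exponential-plus-offset fit to the mean of an MT-free
    ROI over time; finally the first frame (no MTs yet) is subtracted.
    """
    data = stack.data.astype(float)
    sigma = highpass_px / 3.0
    hp = np.stack([f - ndimage.gaussian_filter(f, sigma) for f in data])
    roi = background_roi or (slice(0, max(8, hp.shape[1] // 8)),
                             slice(0, max(8, hp.shape[2] // 8)))
    means = data[:, roi[0], roi[1]].mean(axis=(1, 2))
    t = np.arange(len(means), dtype=float)
    corrected = hp
    if len(means) >= 4 and means.std() > 0:
        from scipy.optimize import curve_fit

        try:
            p0 = (max(means[0] - means[-1], 1e-6), max(len(means) / 2.0, 1.0),
                  means[-1])
            (a, tau, c), _ = curve_fit(
                lambda tt, a, tau, c: a * np.exp(-tt / tau) + c,
                t, means, p0=p0, maxfev=5000,
            )
            fit = a * np.exp(-t / tau) + c
            ratio = (fit[0] - c) / np.clip(fit - c, 1e-9, None)
            if a > 0 and tau > 0:
                corrected = hp * ratio[:, None, None]
        except RuntimeError:
            warnings.warn("bleach fit did not converge; skipping bleach correction")
    corrected = corrected - corrected[0]
    return ImageStack(
        corrected, stack.pixel_size, stack.frame_interval, stack.channel
    )


def _robust_sd(frame: np.ndarray) -> float:
    med = np.median(frame)
    return 1.4826 * float(np.median(np.abs(frame - med))) or float(frame.std()) or 1.0


def detect_comets(
    filtered_eb1: ImageStack, threshold_sd: float = 12.0, step_sd: float = 2.0
) -> list[CometDetection]:
    """Local-maximum comet detection with sub-pixel centroid refinement.

    The intensity threshold is ``threshold_sd`` robust (MAD-based) standard
    deviations of the frame; maxima are refined by a 5×5 centroid.
    """
    out: list[CometDetection] = []
    for f, frame in enumerate(filtered_eb1.data):
        thr = threshold_sd * _robust_sd(frame)
        peaks = peak_local_max(frame, min_distance=3, threshold_abs=thr)
        H, W = frame.shape
        for (py, px) in peaks:
            y0, y1 = max(0, py - 2), min(H, py + 3)
            x0, x1 = max(0, px - 2), min(W, px + 3)
            win = np.clip(frame[y0:y1, x0:x1], 0, None)
            tot = win.sum()
            if tot <= 0:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            out.append(
                CometDetection(
                    frame=f,
                    x=float((xx * win).sum() / tot),
                    y=float((yy * win).sum() / tot),
                    intensity=float(frame[py, px]),
                )
            )
    return out


def link_comets(
    detections: list[CometDetection],
    max_radius: float = 9.0,
    min_len: int = 3,
    min_displacement: float = 2.0,
    min_speed: float = 1.0,
    gap_frames: int = 5,
    gap_forward_angle_deg: float = 20.0,
) -> list[TrackSegment]:
    """Greedy nearest-neighbor linking of comets into track segments.

    Frame-to-frame assignment within ``max_radius``; an unmatched track end
    stays open for up to ``gap_frames`` frames (short-gap closing, as in
    standard plus-tip linkers), zero-gap matches taking precedence.  A gap
    closure must lie within a forward cone of ``gap_forward_angle_deg``
    about the track's recent direction, so a comet appearing behind the tip
    (e.g. a newborn branch) does not capture the track.  Short spurious
    tracks (< min_len frames with net displacement < min_displacement px or
    net speed < min_speed px/frame) are discarded.
    """
    by_frame: dict[int, list[CometDetection]] = {}
    for d in detections:
        by_frame.setdefault(d.frame, []).append(d)
    frames_sorted = sorted(by_frame)
    open_tracks: list[list[CometDetection]] = []
    closed: list[list[CometDetection]] = []
    for f in frames_sorted:
        dets = by_frame[f]
        taken = [False] * len(dets)
        still_open = []
        for tr in open_tracks:
            if f - tr[-1].frame > gap_frames + 1:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open
        pairs = []
        for ti, tr in enumerate(open_tracks):
            last = tr[-1]
            gap = f - last.frame - 1
            tr_dir = None
            if gap > 0 and len(tr) >= 3:
                p0, p1 = tr[0], tr[-1]
                ext = math.hypot(p1.x - p0.x, p1.y - p0.y)
                if ext > 2.0:
                    tr_dir = ((p1.x - p0.x) / ext, (p1.y - p0.y) / ext)
            for di, d in enumerate(dets):
                dx, dy = d.x - last.x, d.y - last.y
                r = math.hypot(dx, dy)
                if r > max_radius:
                    continue
                if tr_dir is not None and r > 3.0:
                    cosang = (dx * tr_dir[0] + dy * tr_dir[1]) / r
                    if cosang < math.cos(math.radians(gap_forward_angle_deg)):
                        continue
                pairs.append((gap, r, ti, di))
        used_t = set()
        for gap, r, ti, di in sorted(pairs):
            if ti in used_t or taken[di]:
                continue
            open_tracks[ti].append(dets[di])
            used_t.add(ti)
            taken[di] = True
        for di, d in enumerate(dets):
            if not taken[di]:
                open_tracks.append([d])
    closed.extend(open_tracks)
    segments = []
    for tr in closed:
        n = len(tr)
        disp = math.hypot(tr[-1].x - tr[0].x, tr[-1].y - tr[0].y)
        span = max(1, tr[-1].frame - tr[0].frame)
        if n < min_len and (disp < min_displacement or disp / span < min_speed):
            continue
        segments.append(
            TrackSegment(
                id=len(segments),
                frames=[d.frame for d in tr],
                xy=[(d.x, d.y) for d in tr],
            )
        )
    return segments


def segments_from_table(detections: pd.DataFrame) -> list[TrackSegment]:
    """Build TrackSegments from a (frame, x_px, y_px, segment_id) table."""
    segs = []
    for sid, g in detections.groupby("segment_id"):
        g = g.sort_values("frame")
        segs.append(
            TrackSegment(
                id=int(sid),
                frames=g["frame"].to_numpy(),
                xy=g[["x_px", "y_px"]].to_numpy(),
            )
        )
    return segs


def line_integral_intensity(image: np.ndarray, p0, p1) -> float:
    """Mean interpolated intensity along the chord p0→p1, sampled at 1 px
    spacing (au/px).  A zero-length chord returns the intensity at p0."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    n = max(2, int(math.ceil(length)) + 1)
    xs = np.linspace(p0[0], p1[0], n)
    ys = np.linspace(p0[1], p1[1], n)
    vals = ndimage.map_coordinates(image, [ys, xs], order=1, mode="nearest")
    return float(vals.mean())


def _angle_between(u, v) -> float:
    c = float(np.clip(np.dot(u, v), -1.0, 1.0))
    return math.degrees(math.acos(c))


def _score_candidate(
    si: TrackSegment,
    sj: TrackSegment,
    cfg: MergeConfig,
    tubulin_frame: np.ndarray | None,
    i_cutoff: float | None,
) -> CandidateScore | None:
    """Apply the class rules to a candidate pair; None when rejected."""
    t_gap = sj.start_frame - si.end_frame - 1
    if t_gap < 0 or t_gap > cfg.dt_max:
        return None
    d_ends = float(np.linalg.norm(sj.start - si.end))

    def imt(p0, p1):
        if tubulin_frame is None:
            return math.inf
        return line_integral_intensity(tubulin_frame, p0, p1)

    # (1) zero frame gap: plain positional continuation
    if t_gap == 0:
        if d_ends > cfg.r_fluc:
            return None
        return CandidateScore(
            si.id, sj.id, 0, d_ends, d_ends, d_ends, 1.0,
            imt(si.end, sj.start), "zero_gap",
        )

    # (5) pause: end effectively stationary for a bounded time
    if d_ends <= cfg.r_fluc and t_gap <= cfg.pause_max_frames:
        I = imt(si.end, sj.start)
        if not (I > (i_cutoff or 0.0) / 4.0 or d_ends <= 1.0):
            return None
        return CandidateScore(
            si.id, sj.id, t_gap, d_ends, d_ends, d_ends, 1.0, I, "pause"
        )

    if tubulin_frame is None:
        return None  # only zero-gap/pause merges without lattice evidence

    # orientation of the track that the merge would produce (long baseline)
    merged_vec = sj.end - si.start
    nm = float(np.linalg.norm(merged_vec))
    dir_merged = merged_vec / nm if nm > 0 else np.array([1.0, 0.0])
    # small segments carry direction estimates dominated by jitter; the
    # merged orientation is the better estimator for them
    small_i = si.extent_px() <= 3 * cfg.r_fluc
    small_j = sj.extent_px() <= 3 * cfg.r_fluc
    dir_i = dir_merged if small_i else si.direction("end")
    dir_j = dir_merged if small_j else sj.direction("start")
    gap_vec = sj.start - si.end
    dir_gap = gap_vec / d_ends if d_ends > 0 else dir_i
    forward = float(np.dot(gap_vec, dir_i)) >= 0.0

    if forward:
        # (2) for long tracks the end of i must be i's closest approach to
        # j's start (within the fluctuation radius, to tolerate jitter);
        # inapplicable to catastrophes, whose restart point lies behind the
        # end and is always closest to an interior point
        if si.extent_px() > 3 * cfg.r_fluc and sj.extent_px() > 3 * cfg.r_fluc:
            dists = np.linalg.norm(si.xy - sj.start, axis=1)
            if dists.min() < d_ends - cfg.r_fluc:
                return None
        # (6) forward gap: net displacement bounded by a speed cap
        ok_long = d_ends <= cfg.long_gap_speed_max * t_gap
        ok_short = (
            t_gap <= cfg.short_gap_frames_max
            and d_ends <= cfg.short_gap_speed_max * t_gap
        )
        if not (ok_long or ok_short):
            return None
        # beyond the pause window a forward gap must reflect real growth:
        # the displacement cannot be far below the net plus-end speed
        # (a near-stationary long gap is not a plausible continuation)
        if t_gap > cfg.pause_max_frames and d_ends < cfg.forward_gap_speed_min * t_gap:
            return None
        # (3) direction gates on dir_i, dir_j and the merged orientation
        max_ang = (
            cfg.angle_small_track_deg if (small_i or small_j) else cfg.angle_strict_deg
        )
        if (
            _angle_between(dir_i, dir_j) > max_ang
            or _angle_between(dir_i, dir_merged) > max_ang
            or _angle_between(dir_j, dir_merged) > max_ang
        ):
            return None
        d_perp = abs(dir_i[0] * gap_vec[1] - dir_i[1] * gap_vec[0])
        if d_perp > cfg.d_perp_max:
            return None
        n_dot = float(np.dot(dir_i, dir_gap))
        gap_class = "forward_gap"
    else:
        # (4) catastrophe: the end stepped backwards along the axis
        if d_ends > cfg.catastrophe_max_dist:
            return None
        if _angle_between(dir_i, dir_j) > cfg.angle_catastrophe_deg:
            return None
        if d_ends > 2 * cfg.r_fluc:
            back_gap = -dir_gap  # shrink direction is opposite to growth
            ang = min(_angle_between(back_gap, dir_i), _angle_between(back_gap, dir_j))
            if ang > cfg.angle_catastrophe_deg and _angle_between(
                back_gap, dir_i
            ) > cfg.catastrophe_fallback_deg:
                return None
        d_perp = abs(dir_i[0] * gap_vec[1] - dir_i[1] * gap_vec[0])
        if d_perp > cfg.d_perp_max:
            return None
        n_dot = float(np.dot(dir_i, dir_j))
        gap_class = "catastrophe"

    I = imt(si.end, sj.start)
    if i_cutoff is not None and I < i_cutoff:
        return None
    return CandidateScore(
        si.id, sj.id, t_gap, d_ends, d_ends, d_perp, n_dot, I, gap_class
    )



def merge_tracks(
    segments: list[TrackSegment],
    processed_tubulin: ImageStack | np.ndarray | None,
    config: MergeConfig | None = None,
) -> list[Trajectory]:
    """Temporally greedy merge of EB1 track segments into full trajectories.

    Segments are processed in order of appearance; for each segment end the
    surviving candidates (per the class rules) compete on
    cost = cost_base^t_gap · D_min and the minimum is merged.  Gaps are
    closed by linear interpolation; trajectories spanning fewer than
    ``min_track_frames`` frames are discarded.
    """
    cfg = config or MergeConfig()
    if not segments:
        return []
    tub = None
    i_cutoff = None
    if processed_tubulin is not None:
        tub = (
            processed_tubulin.data
            if isinstance(processed_tubulin, ImageStack)
            else np.atleast_3d(np.asarray(processed_tubulin, dtype=float))
        )
        if tub.ndim == 2:
            tub = tub[None]
        i_cutoff = cfg.i_cutoff(tub)
    else:
        warnings.warn(
            "no tubulin stack: only zero-gap and pause-by-distance merges allowed"
        )

    by_id = {s.id: s for s in segments}
    order = sorted(segments, key=lambda s: (s.start_frame, s.id))
    next_of: dict[int, tuple[int, str]] = {}
    consumed_starts: set[int] = set()
    for si in order:
        best: CandidateScore | None = None
        for sj in order:
            if sj.id == si.id or sj.id in consumed_starts:
                continue
            if sj.start_frame <= si.end_frame:
                continue
            if tub is not None:
                f = min(sj.start_frame, tub.shape[0] - 1)
                tub_frame = tub[f]
            else:
                tub_frame = None
            cand = _score_candidate(si, sj, cfg, tub_frame, i_cutoff)
            if cand is None:
                continue
            cand.cost = cfg.cost_base**cand.t_gap * cand.D_min
            if best is None or cand.cost < best.cost:
                best = cand
        if best is not None:
            next_of[si.id] = (best.j, best.gap_class)
            consumed_starts.add(best.j)

    # chains: heads are segments whose start was never consumed
    trajectories = []
    heads = [s for s in order if s.id not in consumed_starts]
    for ti, head in enumerate(heads):
        chain = [head.id]
        classes = []
        while chain[-1] in next_of:
            nxt, cls = next_of[chain[-1]]
            chain.append(nxt)
            classes.append(cls)
        frames_parts, xy_parts = [], []
        for a, b in zip(chain[:-1], chain[1:]):
            sa, sb = by_id[a], by_id[b]
            frames_parts.append(sa.frames)
            xy_parts.append(sa.xy)
            gap = sb.start_frame - sa.end_frame - 1
            if gap > 0:  # linear interpolation across the gap
                gf = np.arange(sa.end_frame + 1, sb.start_frame)
                w = (gf - sa.end_frame) / (sb.start_frame - sa.end_frame)
                gxy = sa.end[None, :] * (1 - w[:, None]) + sb.start[None, :] * w[:, None]
                frames_parts.append(gf)
                xy_parts.append(gxy)
        tail = by_id[chain[-1]]
        frames_parts.append(tail.frames)
        xy_parts.append(tail.xy)
        frames = np.concatenate(frames_parts)
        xy = np.concatenate(xy_parts)
        # fill single-frame holes inside original segments, if any
        full = np.arange(frames[0], frames[-1] + 1)
        if len(full) != len(frames):
            fx = np.interp(full, frames, xy[:, 0])
            fy = np.interp(full, frames, xy[:, 1])
            frames, xy = full, np.stack([fx, fy], axis=1)
        if frames[-1] - frames[0] + 1 < cfg.min_track_frames:
            continue
        trajectories.append(
            Trajectory(
                id=len(trajectories),
                frames=frames,
                xy=xy,
                source_segments=chain,
                gap_classes=classes,
            )
        )
    return trajectories


# ---------------------------------------------------------------------------
# length and speed measurements

def measure_length_series(
    trajectory: Trajectory,
    pixel_size: float,
    smoothing: float | None = None,
    end_weight: float = 10.0,
) -> np.ndarray:
    """Arc length (µm) of the smoothed trajectory up to each frame.

    A smoothing spline is fit to x(t), y(t) with the start and end points
    weighted higher; the cumulative arc length of the fitted curve is
    returned per frame.  Falls back to the raw polyline on spline failure.
    """
    if trajectory.n_frames < 6:
        raise ValueError("trajectory must span at least 6 frames")
    t = trajectory.frames.astype(float)
    w = np.ones_like(t)
    w[0] = w[-1] = end_weight
    if smoothing is None:
        smoothing = trajectory.n_frames * 1.0  # ~1 px residual sd
    try:
        sx = interpolate.UnivariateSpline(t, trajectory.xy[:, 0], w=w, s=smoothing, k=3)
        sy = interpolate.UnivariateSpline(t, trajectory.xy[:, 1], w=w, s=smoothing, k=3)
        fine = np.linspace(t[0], t[-1], 10 * len(t))
        fx, fy = sx(fine), sy(fine)
        seglen = np.hypot(np.diff(fx), np.diff(fy))
        cum = np.concatenate([[0.0], np.cumsum(seglen)])
        arc = np.interp(t, fine, cum)
    except Exception:
        warnings.warn("spline fit failed; using polyline arc length")
        seglen = np.hypot(*np.diff(trajectory.xy, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seglen)])
    return arc * pixel_size


def net_plus_end_speed(
    trajectory: Trajectory,
    pixel_size: float,
    frame_interval: float,
    min_frames: int = 50,
) -> float | None:
    """Net growth speed, µm/min: final length / lifespan.

    Trajectories spanning fewer than ``min_frames`` frames are excluded
    (returns None).
    """
    if trajectory.n_frames < min_frames:
        return None
    lengths = measure_length_series(trajectory, pixel_size)
    lifespan_s = (trajectory.frames[-1] - trajectory.frames[0]) * frame_interval
    return float(lengths[-1] / lifespan_s * 60.0)
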