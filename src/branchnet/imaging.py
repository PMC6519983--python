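"""Synthetic fluorescence-microscopy data with known ground truth.

Everything the downstream stages consume can be generated here: tubulin and
EB1 image stacks rendered from a simulated network, fragmented plus-end
tracks with pause/catastrophe/dropout gaps, Gaussian-beam illumination
fields, single-molecule photobleaching step traces, and TPX2 accumulation
kymographs with Poisson arrivals over constant background.

Conventions: pixel centers at integer coordinates, 0-based, (x, y) order in
tables and (row=y, col=x) order inside arrays.  Tracking stacks default to
0.13 µm pixels at 2 s/frame; TPX2 stacks to 0.16 µm pixels at 5 s/frame.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .core import BranchNetwork

__all__ = [
    "ImageStack",
    "RenderConfig",
    "GapModel",
    "PhotobleachTrace",
    "KymographTruth",
    "trajectories_from_network",
    "render_tubulin_stack",
    "render_eb1_stack",
    "fragment_tracks",
    "generate_blank_illumination",
    "generate_photobleach_traces",
    "generate_tpx2_kymograph",
    "save_stack",
    "load_stack",
]


@dataclass
class ImageStack:
    """T×H×W intensity stack with physical metadata."""

    data: np.ndarray
    pixel_size: float  # µm/px
    frame_interval: float  # s
    channel: str = "blank"  # tubulin | eb1 | tpx2 | blank

    def __post_init__(self):
        self.data = np.atleast_3d(np.asarray(self.data, dtype=float))
        if self.data.ndim != 3:
            raise ValueError("data must be T x H x W")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise ValueError("pixel_size and frame_interval must be > 0")
        if not np.isfinite(self.data).all():
            raise ValueError("intensities must be finite")


@dataclass
class RenderConfig:
    psf_sigma: float = 1.5  # px
    psf_kernel: int = 30  # px, kernel extent of the blur
    tubulin_amp: float = 200.0  # au per µm of lattice
    eb1_amp: float = 800.0  # au, comet peak
    eb1_comet_length: float = 10.0  # px FWHM along the growth axis
    eb1_comet_width: float = 4.0  # px FWHM across
    noise_sd: float = 0.0  # Gaussian read noise, au
    poisson_noise: bool = False
    illumination: np.ndarray | None = None  # multiplicative field, H×W
    pixel_size: float = 0.13  # µm/px
    frame_interval: float = 2.0  # s

    def __post_init__(self):
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.eb1_comet_length < 1 or self.eb1_comet_width < 1:
            raise ValueError("comet dimensions must be >= 1 px")


def trajectories_from_network(
    network: BranchNetwork,
    times: np.ndarray,
    pixel_size: float,
    origin_px: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Ground-truth plus-end positions per frame (px), one row per comet.

    Columns: frame, t, mt_id, x_px, y_px, arc_px (plus-end arc length).
    A comet exists from the MT's birth frame onward.
    """
    v = network.params.v_pe
    rows = []
    for m in network.mts:
        mx, my = m.minus_end
        dx, dy = m.direction
        for f, t in enumerate(times):
            if t < m.birth_time:
                continue
            arc_um = v * (t - m.birth_time)
            rows.append(
                (
                    f,
                    float(t),
                    m.id,
                    origin_px[0] + (mx + arc_um * dx) / pixel_size,
                    origin_px[1] + (my + arc_um * dy) / pixel_size,
                    arc_um / pixel_size,
                )
            )
    return pd.DataFrame(rows, columns=["frame", "t", "mt_id", "x_px", "y_px", "arc_px"])


def _apply_noise(data, cfg: RenderConfig, rng: np.random.Generator):
    if cfg.poisson_noise:
        data = rng.poisson(np.clip(data, 0, None)).astype(float)
    if cfg.noise_sd > 0:
        data = data + rng.normal(0.0, cfg.noise_sd, size=data.shape)
    return data


def _splat_line(frame, x0, y0, x1, y1, weight_per_px):
    """Deposit intensity along a straight segment with bilinear sub-pixel
    splatting (0.25 px sampling); total deposited = weight_per_px * length."""
    length = math.hypot(x1 - x0, y1 - y0)
    n = max(2, int(math.ceil(length / 0.25)) + 1)
    xs = np.linspace(x0, x1, n)
    ys = np.linspace(y0, y1, n)
    w = np.full(n, weight_per_px * length / n)
    H, W = frame.shape
    ix, iy = np.floor(xs).astype(int), np.floor(ys).astype(int)
    fx, fy = xs - ix, ys - iy
    for ddx, ddy, ww in (
        (0, 0, (1 - fx) * (1 - fy)),
        (1, 0, fx * (1 - fy)),
        (0, 1, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        cx, cy = ix + ddx, iy + ddy
        ok = (cx >= 0) & (cx < W) & (cy >= 0) & (cy < H)
        np.add.at(frame, (cy[ok], cx[ok]), w[ok] * ww[ok])
    return bool((~((ix >= 0) & (ix < W) & (iy >= 0) & (iy < H))).any())


def render_tubulin_stack(
    network: BranchNetwork,
    cfg: RenderConfig,
    times: np.ndarray,
    shape: tuple[int, int] = (256, 256),
    origin_px: tuple[float, float] = (20.0, 128.0),
    rng: np.random.Generator | None = None,
) -> ImageStack:
    """Render the tubulin channel: each MT is a line of amplitude
    tubulin_amp·pixel_size au/px, blurred by the Gaussian PSF."""
    rng = np.random.default_rng(0) if rng is None else rng
    v = network.params.v_pe
    H, W = shape
    truncate = cfg.psf_kernel / (2.0 * cfg.psf_sigma)
    out = np.zeros((len(times), H, W))
    clipped = False
    for f, t in enumerate(times):
        frame = out[f]
        for m in network.mts:
            if t < m.birth_time:
                continue
            arc_px = v * (t - m.birth_time) / cfg.pixel_size
            if arc_px <= 0:
                continue
            x0 = origin_px[0] + m.minus_end[0] / cfg.pixel_size
            y0 = origin_px[1] + m.minus_end[1] / cfg.pixel_size
            x1 = x0 + arc_px * m.direction[0]
            y1 = y0 + arc_px * m.direction[1]
            clipped |= _splat_line(
                frame, x0, y0, x1, y1, cfg.tubulin_amp * cfg.pixel_size
            )
        out[f] = ndimage.gaussian_filter(frame, cfg.psf_sigma, truncate=truncate)
        if cfg.illumination is not None:
            out[f] *= cfg.illumination
    if clipped:
        warnings.warn("some MTs extend outside the field of view; clipped")
    out = _apply_noise(out, cfg, rng)
    return ImageStack(out, cfg.pixel_size, cfg.frame_interval, "tubulin")


def _comet_kernel(cfg: RenderConfig, direction):
    fwhm = 2.0 * math.sqrt(2.0 * math.log(2.0))
    s_long = cfg.eb1_comet_length / fwhm
    s_short = cfg.eb1_comet_width / fwhm
    return s_long, s_short


def render_eb1_stack(
    network: BranchNetwork,
    cfg: RenderConfig,
    times: np.ndarray,
    shape: tuple[int, int] = (256, 256),
    origin_px: tuple[float, float] = (20.0, 128.0),
    rng: np.random.Generator | None = None,
    truth: pd.DataFrame | None = None,
) -> tuple[ImageStack, pd.DataFrame]:
    """Render the EB1 channel: an anisotropic Gaussian comet at each growing
    plus-end, long axis along the growth direction.  Returns the stack and a
    truth table of exact sub-pixel comet positions.

    When ``truth`` is given (e.g. the warped table from fragment_tracks),
    comets are drawn at those positions instead of the constant-speed law.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    H, W = shape
    if truth is None:
        truth = trajectories_from_network(network, times, cfg.pixel_size, origin_px)
    dirs = {m.id: np.asarray(m.direction) for m in network.mts}
    out = np.zeros((len(times), H, W))
    s_long, s_short = _comet_kernel(cfg, None)
    half = int(math.ceil(4 * s_long))
    for row in truth.itertuples():
        f = int(row.frame)
        if f >= len(times):
            continue
        d = dirs[int(row.mt_id)]
        cx, cy = row.x_px, row.y_px
        x_lo, x_hi = int(cx) - half, int(cx) + half + 1
        y_lo, y_hi = int(cy) - half, int(cy) + half + 1
        xs = np.arange(max(0, x_lo), min(W, x_hi))
        ys = np.arange(max(0, y_lo), min(H, y_hi))
        if xs.size == 0 or ys.size == 0:
            continue
        gx, gy = np.meshgrid(xs - cx, ys - cy)
        u = gx * d[0] + gy * d[1]  # along axis
        w = -gx * d[1] + gy * d[0]  # across
        out[f, ys[0] : ys[-1] + 1, xs[0] : xs[-1] + 1] += cfg.eb1_amp * np.exp(
            -0.5 * (u / s_long) ** 2 - 0.5 * (w / s_short) ** 2
        )
    out = _apply_noise(out, cfg, rng)
    return ImageStack(out, cfg.pixel_size, cfg.frame_interval, "eb1"), truth


# ---------------------------------------------------------------------------
# track fragmentation

@dataclass
class GapModel:
    """Stochastic model of EB1 track breaks.

    Pauses freeze the plus-end (the comet vanishes, the lattice stays);
    catastrophes shrink the end by a few pixels before regrowth; dropouts
    are single-frame detection misses.  Positional jitter emulates the
    fluctuation radius of a detected comet.
    """

    pause_rate: float = 0.01  # per frame
    pause_max_frames: int = 15
    dropout_p: float = 0.05
    jitter_sd: float = 1.0  # px
    catastrophe_rate: float = 0.001  # per frame (rare under vanadate)
    shrink_max_px: float = 10.0
    shrink_frames: int = 2  # invisible frames while shrinking
    min_segment_frames: int = 3
    drop_short_segments: bool = False
    # emulated upstream linker: short gaps it would already have closed
    upstream_gap_frames: int = 5
    upstream_radius: float = 9.0  # px, forward gap closure
    upstream_pause_radius: float = 4.0  # px, fluctuation closure


def fragment_tracks(
    truth: pd.DataFrame,
    gap_model: GapModel,
    rng: np.random.Generator | None = None,
    speed_px_per_frame: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cut ground-truth trajectories into track segments with realistic gaps.

    The trajectory is re-parametrized by arc length so that pauses freeze
    the end and catastrophes move it backwards before regrowth, then cut at
    invisible stretches, with Gaussian jitter added to visible detections.

    Returns
    -------
    detections : DataFrame(frame, x_px, y_px, mt_id, segment_id)
        Visible, jittered detections grouped into segments.
    gaps : DataFrame(mt_id, seg_before, seg_after, gap_class, t_gap)
        Ground-truth adjacent segment pairs and their break class
        (pause | forward_gap | catastrophe).
    warped : DataFrame(frame, x_px, y_px, mt_id)
        The exact (unjittered) warped plus-end position per frame.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    det_rows, gap_rows, warp_rows = [], [], []
    seg_counter = 0
    for mt_id, g in truth.groupby("mt_id"):
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy()
        xs, ys = g["x_px"].to_numpy(), g["y_px"].to_numpy()
        if len(frames) < 2:
            continue
        x0, y0 = xs[0], ys[0]
        dx, dy = xs[-1] - x0, ys[-1] - y0
        norm = math.hypot(dx, dy)
        if norm == 0:
            continue
        ux, uy = dx / norm, dy / norm
        speed = (
            speed_px_per_frame
            if speed_px_per_frame is not None
            else norm / (frames[-1] - frames[0])
        )
        # state machine over frames
        arc = 0.0
        state = "grow"  # grow | pause | shrink
        state_left = 0
        visible, arcs, classes = [], [], []
        cls_at_break = None
        for i, f in enumerate(frames):
            # state transition first, so a pause freezes this frame's arc
            if state == "grow":
                u = rng.random()
                if u < gap_model.pause_rate:
                    state = "pause"
                    state_left = int(rng.integers(2, gap_model.pause_max_frames + 1))
                    cls_at_break = "pause"
                elif u < gap_model.pause_rate + gap_model.catastrophe_rate:
                    state = "shrink"
                    shrink = rng.uniform(3.0, gap_model.shrink_max_px)
                    state_left = gap_model.shrink_frames
                    shrink_per_frame = shrink / gap_model.shrink_frames
                    cls_at_break = "catastrophe"
            if i > 0:
                if state == "grow":
                    arc += speed
                elif state == "shrink":
                    arc = max(0.0, arc - shrink_per_frame)
            arcs.append(arc)
            if state == "grow":
                vis = rng.random() >= gap_model.dropout_p
                classes.append("forward_gap")
            else:
                vis = False
                classes.append(cls_at_break)
                state_left -= 1
                if state_left <= 0:
                    state = "grow"
            visible.append(vis)
        # emit warped truth + visible detections grouped into segments
        cur_seg, last_seg, last_cls = None, None, None
        seg_len = 0
        for i, f in enumerate(frames):
            wx, wy = x0 + arcs[i] * ux, y0 + arcs[i] * uy
            warp_rows.append((int(f), wx, wy, mt_id))
            if visible[i]:
                if cur_seg is None:
                    cur_seg = seg_counter
                    seg_counter += 1
                    if last_seg is not None:
                        gap_rows.append(
                            (mt_id, last_seg, cur_seg, last_cls, int(f - last_f - 1))
                        )
                    seg_len = 0
                det_rows.append(
                    (
                        int(f),
                        wx + rng.normal(0, gap_model.jitter_sd),
                        wy + rng.normal(0, gap_model.jitter_sd),
                        mt_id,
                        cur_seg,
                    )
                )
                seg_len += 1
                last_f = f
            else:
                if cur_seg is not None:
                    last_seg, last_cls = cur_seg, classes[i]
                    cur_seg = None
    detections = pd.DataFrame(
        det_rows, columns=["frame", "x_px", "y_px", "mt_id", "segment_id"]
    )
    gaps = pd.DataFrame(
        gap_rows, columns=["mt_id", "seg_before", "seg_after", "gap_class", "t_gap"]
    )
    warped = pd.DataFrame(warp_rows, columns=["frame", "x_px", "y_px", "mt_id"])
    if gap_model.upstream_gap_frames > 0 and len(gaps):
        detections, gaps = _close_upstream_gaps(detections, gaps, gap_model)
    if gap_model.drop_short_segments and len(detections):
        sizes = detections.groupby("segment_id")["frame"].size()
        keep = set(sizes[sizes >= gap_model.min_segment_frames].index)
        detections = detections[detections["segment_id"].isin(keep)]
        # rebuild adjacency between retained segments of the same MT
        cls_by_pair = {
            (r.seg_before, r.seg_after): r.gap_class for r in gaps.itertuples()
        }
        new_rows = []
        for mt_id, g in detections.groupby("mt_id"):
            order = (
                g.groupby("segment_id")["frame"].agg(["min", "max"]).sort_values("min")
            )
            ids = order.index.to_list()
            for s1, s2 in zip(ids[:-1], ids[1:]):
                cls = cls_by_pair.get((s1, s2), "forward_gap")
                t_gap = int(order.loc[s2, "min"] - order.loc[s1, "max"] - 1)
                new_rows.append((mt_id, s1, s2, cls, t_gap))
        gaps = pd.DataFrame(
            new_rows,
            columns=["mt_id", "seg_before", "seg_after", "gap_class", "t_gap"],
        )
    return detections, gaps, warped


def render_tubulin_from_truth(
    warped: pd.DataFrame,
    cfg: RenderConfig,
    n_frames: int,
    shape: tuple[int, int] = (512, 512),
    rng: np.random.Generator | None = None,
) -> ImageStack:
    """Render the tubulin channel from per-frame plus-end truth positions.

    The lattice of each MT at frame f is the chord from its first recorded
    position (the minus-end) to its current tip, so pauses and catastrophe
    shrinkage are reflected in the image — a paused or shrunk MT has no
    polymer beyond its present tip.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    H, W = shape
    truncate = cfg.psf_kernel / (2.0 * cfg.psf_sigma)
    out = np.zeros((n_frames, H, W))
    origins = {
        mt: (g.iloc[0].x_px, g.iloc[0].y_px)
        for mt, g in warped.sort_values("frame").groupby("mt_id")
    }
    for f in range(n_frames):
        frame = out[f]
        sub = warped[warped.frame == f]
        for r in sub.itertuples():
            x0, y0 = origins[r.mt_id]
            _splat_line(
                frame, x0, y0, r.x_px, r.y_px, cfg.tubulin_amp * cfg.pixel_size
            )
        out[f] = ndimage.gaussian_filter(frame, cfg.psf_sigma, truncate=truncate)
        if cfg.illumination is not None:
            out[f] *= cfg.illumination
    out = _apply_noise(out, cfg, rng)
    return ImageStack(out, cfg.pixel_size, cfg.frame_interval, "tubulin")


def _close_upstream_gaps(detections, gaps, gm: GapModel):
    """Emulate the output of the upstream comet linker: short gaps between
    same-trajectory segments (within its time window and search radius) are
    already closed before the merge stage ever sees the data."""
    firsts = detections.groupby("segment_id").first()
    lasts = detections.groupby("segment_id").last()
    relabel: dict[int, int] = {}

    def root(s):
        while s in relabel:
            s = relabel[s]
        return s

    keep_rows = []
    for r in gaps.itertuples():
        if r.t_gap > gm.upstream_gap_frames:
            keep_rows.append(r)
            continue
        e, f0 = lasts.loc[r.seg_before], firsts.loc[r.seg_after]
        d = math.hypot(f0.x_px - e.x_px, f0.y_px - e.y_px)
        if d <= gm.upstream_pause_radius or (
            r.gap_class == "forward_gap" and d <= gm.upstream_radius
        ):
            relabel[r.seg_after] = r.seg_before
        else:
            keep_rows.append(r)
    if relabel:
        detections = detections.copy()
        detections["segment_id"] = detections["segment_id"].map(root)
        gaps = pd.DataFrame(
            [
                (r.mt_id, root(r.seg_before), root(r.seg_after), r.gap_class, r.t_gap)
                for r in keep_rows
            ],
            columns=["mt_id", "seg_before", "seg_after", "gap_class", "t_gap"],
        )
    return detections, gaps


# ---------------------------------------------------------------------------
# illumination, photobleaching, kymographs

def generate_blank_illumination(
    H: int,
    W: int,
    beam_sd_px: float,
    amp: float = 1000.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> ImageStack:
    """Single-frame Gaussian-beam illumination field, maximal at the center."""
    rng = np.random.default_rng(0) if rng is None else rng
    yy, xx = np.mgrid[0:H, 0:W]
    d2 = (xx - (W - 1) / 2.0) ** 2 + (yy - (H - 1) / 2.0) ** 2
    if math.isinf(beam_sd_px):
        field_ = np.full((H, W), amp)
    else:
        field_ = amp * np.exp(-d2 / (2.0 * beam_sd_px**2))
    if noise_sd > 0:
        field_ = field_ + rng.normal(0, noise_sd, size=field_.shape)
    return ImageStack(field_[None], 0.13, 1.0, "blank")


@dataclass
class PhotobleachTrace:
    intensity: np.ndarray  # per frame
    amplitude: float  # true step amplitude, au
    bleach_frame: int
    noise_sd: float
    offset: float = 0.0


def generate_photobleach_traces(
    n: int,
    amplitude: float = 2700.0,
    noise_sd: float = 300.0,
    length: int = 80,
    offset: float = 0.0,
    bleach_frame_range: tuple[int, int] | None = None,
    rng: np.random.Generator | None = None,
) -> list[PhotobleachTrace]:
    """Single-fluorophore step traces: amplitude·1[t < t_bleach] + offset + noise."""
    if amplitude <= 0:
        raise ValueError("amplitude must be > 0")
    rng = np.random.default_rng(0) if rng is None else rng
    lo, hi = bleach_frame_range or (length // 4, 3 * length // 4)
    out = []
    for _ in range(n):
        bf = int(rng.integers(lo, hi + 1))
        tr = offset + amplitude * (np.arange(length) < bf).astype(float)
        if noise_sd > 0:
            tr = tr + rng.normal(0, noise_sd, size=length)
        out.append(PhotobleachTrace(tr, amplitude, bf, noise_sd, offset))
    return out


@dataclass
class KymographTruth:
    data: np.ndarray  # n_pixels x n_frames intensity
    rate: float  # molecules µm⁻¹ s⁻¹
    single_intensity: float  # au per molecule
    background_molecules: float
    pixel_size: float  # µm
    frame_interval: float  # s
    arrival_frame: np.ndarray  # lattice-arrival frame per pixel


def generate_tpx2_kymograph(
    rate: float = 0.4,
    single_intensity: float = 2700.0,
    background_molecules: float = 7.0,
    pixel_size: float = 0.16,
    frame_interval: float = 5.0,
    growth_speed: float = 0.09,
    n_pixels: int = 60,
    n_frames: int = 120,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> KymographTruth:
    """Position-time map of TPX2 accumulating on a growing MT lattice.

    Pixel p becomes lattice once the plus-end passes it; thereafter the
    bound-molecule count is cumulative Poisson with mean
    rate·pixel_size·(elapsed lattice age), on top of a constant background.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(0) if rng is None else rng
    arrival = np.ceil(
        np.arange(n_pixels) * pixel_size / (growth_speed * frame_interval)
    ).astype(int)
    data = np.zeros((n_pixels, n_frames))
    for p in range(n_pixels):
        mol = np.full(n_frames, float(background_molecules))
        a = arrival[p]
        if a < n_frames and rate > 0:
            # per-frame increments on lattice pixels accumulate
            inc = rng.poisson(rate * pixel_size * frame_interval, size=n_frames - a)
            mol[a:] += np.cumsum(inc)
        data[p] = mol * single_intensity
    if noise_sd > 0:
        data = data + rng.normal(0, noise_sd, size=data.shape)
    return KymographTruth(
        data,
        rate,
        single_intensity,
        background_molecules,
        pixel_size,
        frame_interval,
        arrival,
    )


# ---------------------------------------------------------------------------
# TIFF I/O with sidecar metadata

def save_stack(stack: ImageStack, path) -> None:
    tifffile.imwrite(path, stack.data.astype(np.float32))
    meta = {
        "pixel_size_um": stack.pixel_size,
        "frame_interval_s": stack.frame_interval,
        "channel": stack.channel,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh)


def load_stack(path) -> ImageStack:
    data = tifffile.imread(path)
    try:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        meta = {"pixel_size_um": 0.13, "frame_interval_s": 2.0, "channel": "blank"}
    return ImageStack(
        data, meta["pixel_size_um"], meta["frame_interval_s"], meta["channel"]
    )
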