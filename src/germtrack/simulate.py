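"""Ground-truthed synthetic germination time-lapse lots.

The generator emulates a grid of seeds on coloured germination paper imaged
at a fixed interval.  Each seed is an ellipse that swells during imbibition;
its roots emerge at stochastic times from the seed coat and grow downward
along jittered polylines whose arc length follows a logistic law (root
elongation accelerates, peaks, then saturates).  Seedlings appear above the
seed at a stochastic hour and later shift colour toward green (chloroplast
biogenesis).  Adjacent seeds' radicles can be steered to cross exactly once.

Everything is rendered both as RGB frames (with Gaussian pixel noise) and as
noise-free label maps, alongside exact ground truth: per-root emergence
frame and per-frame true length, crossing events, and per-seed event hours.

The defaults mirror a wheat-like experiment: hourly frames, 0.05 mm/px
(~5,000 px per seed), 3 mm x 2 mm seeds, radicle emergence around 30-60 h,
chloroplast biogenesis within an 80-100 h horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse

from .series_io import (BACKGROUND, ROOT, SEED_BODY, SEEDLING, Frame,
                        ImageSeries, LabelMap, SeedROI)

PAPER_RGB = {
    "blue": (45, 95, 200),
    "black": (28, 28, 33),
    "dark_red": (150, 45, 55),
    "light_blue": (150, 190, 230),
}
SEED_RGB = (150, 110, 72)
ROOT_RGB = (235, 232, 225)
SEEDLING_RGB = (205, 215, 160)       # pale coleoptile, ExG = 65
SEEDLING_GREEN_RGB = (95, 185, 75)   # after chloroplast biogenesis, ExG = 200

INITIAL_ROOT_MM = 0.4  # visible length at the emergence frame


@dataclass
class RootParams:
    emergence_mean_h: float
    emergence_sd_h: float
    l_max_mm: float = 12.0
    rate_per_h: float = 0.12          # logistic steepness
    midpoint_offset_h: float = 18.0   # inflection, hours after emergence


@dataclass
class GenotypeParams:
    name: str
    roots: tuple[RootParams, ...] = (
        RootParams(40.0, 5.0, 12.0),
        RootParams(55.0, 6.0, 8.0),
        RootParams(65.0, 6.0, 6.0),
    )
    heading_spread_deg: float = 12.0   # sd of initial heading around straight down
    heading_clip_deg: float = 30.0     # max deviation from the base heading
    heading_jitter_deg: float = 5.0    # per-step random turn
    crossing_probability: float = 0.0
    lateral_after_crossing: bool = False  # force root 2 to emerge post-crossing
    seedling_mean_h: float = 62.0
    seedling_sd_h: float = 5.0
    greening_delay_mean_h: float = 12.0
    greening_delay_sd_h: float = 3.0
    imbibition_swell: float = 1.3      # area factor reached by swell_end_h
    designed_tier: str | None = None


@dataclass
class SimConfig:
    rng_seed: int = 0
    n_rows: int = 4
    n_cols: int = 4
    n_frames: int = 96
    interval_h: float = 1.0
    scale_mm_per_px: float = 0.05
    paper_color: str = "blue"
    pixel_noise_sd: float = 3.0
    genotypes: list[GenotypeParams] = field(
        default_factory=lambda: [GenotypeParams("G1")])
    genotype_of_seed: list[int] | None = None
    seed_len_mm: float = 3.0
    seed_wid_mm: float = 2.0
    root_width_px: int = 3
    seedling_rate_mm_per_h: float = 0.3
    seedling_max_mm: float = 6.0
    seedling_width_px: int = 5
    swell_end_h: float = 20.0
    frame_shape: tuple[int, int] | None = None  # override; may overflow

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if self.genotype_of_seed is None:
            n = self.n_rows * self.n_cols
            g = len(self.genotypes)
            self.genotype_of_seed = [i * g // n for i in range(n)]

    @property
    def n_seeds(self) -> int:
        return self.n_rows * self.n_cols


@dataclass
class RootTruth:
    seed_id: int
    root_index: int
    t_e: int | None                    # emergence frame; None = never emerges
    lengths_mm: np.ndarray             # true length per frame
    polyline: np.ndarray               # (N, 2) float points, row/col
    arclen_px: np.ndarray              # cumulative arc length per point
    emerged_after_crossing: bool = False


@dataclass
class SeedTruth:
    seed_id: int
    genotype: int
    center: tuple[float, float]
    axes_px: tuple[float, float]       # (half length, half width), pre-swell
    swell_factor: np.ndarray           # area factor per frame
    coleoptile_frame: int | None
    greening_frame: int | None

    def area_mm2(self, frame: int, scale: float) -> float:
        a, b = self.axes_px
        return float(np.pi * a * b * self.swell_factor[frame] * scale ** 2)


@dataclass
class CrossingEvent:
    frame: int
    seed_a: int
    root_a: int
    seed_b: int
    root_b: int
    point: tuple[float, float]


@dataclass
class GroundTruth:
    cfg: SimConfig
    seeds: list[SeedTruth]
    roots: list[RootTruth]
    crossings: list[CrossingEvent]
    rois: list[SeedROI]

    def roots_of(self, seed_id: int) -> list[RootTruth]:
        return [r for r in self.roots if r.seed_id == seed_id]


# ---------------------------------------------------------------------------
# geometry helpers


def _heading_vec(deg: float) -> np.ndarray:
    """Unit (drow, dcol) for a clockwise-from-12-o'clock angle in degrees."""
    rad = np.radians(deg)
    return np.array([-np.cos(rad), np.sin(rad)])


def _logistic_lengths(hours: np.ndarray, t_e_h: float, p: RootParams
                      ) -> np.ndarray:
    """True root length per frame: 0 before emergence, shifted logistic after.

    The transform is affine in the raw logistic, so the inflection stays at
    ``t_e_h + midpoint_offset_h`` exactly.
    """
    raw = 1.0 / (1.0 + np.exp(-p.rate_per_h * (hours - t_e_h
                                               - p.midpoint_offset_h)))
    raw0 = 1.0 / (1.0 + np.exp(p.rate_per_h * p.midpoint_offset_h))
    L = INITIAL_ROOT_MM + (p.l_max_mm - INITIAL_ROOT_MM) * (raw - raw0) / (1.0 - raw0)
    L[hours < t_e_h] = 0.0
    return np.maximum(L, 0.0)


def _grow_polyline(rng, start, base_heading_deg, total_len_px, gp: GenotypeParams,
                   step_px: float = 1.5, waypoint=None):
    """A jittered polyline of the requested arc length.

    If ``waypoint`` is given the line first heads (with jitter) to the
    waypoint, then continues along its incoming direction — producing
    exactly one controlled crossing with a partner routed through the same
    point from the other side.
    """
    pts = [np.asarray(start, float)]
    heading = base_heading_deg + rng.normal(0.0, gp.heading_spread_deg / 2)
    base = base_heading_deg
    reached_wp = waypoint is None
    length = 0.0
    while length < total_len_px:
        if not reached_wp:
            d = np.asarray(waypoint, float) - pts[-1]
            dist = np.linalg.norm(d)
            if dist <= step_px:
                pts.append(np.asarray(waypoint, float))
                length += dist
                # continue straight through the crossing
                base = float(np.degrees(np.arctan2(d[1], -d[0]))) % 360.0
                heading = base
                reached_wp = True
                continue
            desired = float(np.degrees(np.arctan2(d[1], -d[0]))) % 360.0
            heading = desired + rng.normal(0.0, gp.heading_jitter_deg)
        else:
            heading = heading + rng.normal(0.0, gp.heading_jitter_deg)
            lo, hi = base - gp.heading_clip_deg, base + gp.heading_clip_deg
            heading = float(np.clip(heading, lo, hi))
        pts.append(pts[-1] + step_px * _heading_vec(heading))
        length += step_px
    pts = np.array(pts)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, arclen


def _ellipse_boundary_point(center, a, b, angle_deg):
    """Point on an axis-aligned ellipse in a clock-angle direction."""
    v = _heading_vec(angle_deg)
    # scale the direction until it hits the ellipse (rows ~ b, cols ~ a)
    denom = np.sqrt((v[0] / b) ** 2 + (v[1] / a) ** 2)
    return np.asarray(center, float) + v / denom


# ---------------------------------------------------------------------------
# lot construction


def simulate_lot(cfg: SimConfig, render: str = "rgb"):
    """Simulate one lot.

    ``render``: ``"rgb"`` (frames + label maps), ``"labels"`` (label maps
    only, RGB frames omitted) or ``"none"`` (ground truth only).

    Returns ``(series, label_maps, truth)``; the first two may be None
    depending on ``render``.  Deterministic given ``cfg.rng_seed``.
    """
    if render not in ("rgb", "labels", "none"):
        raise ValueError(f"unknown render mode {render!r}")
    rng = np.random.default_rng(cfg.rng_seed)
    scale = cfg.scale_mm_per_px
    hours = np.arange(cfg.n_frames) * cfg.interval_h

    a0 = cfg.seed_len_mm / 2 / scale   # half length, px (col direction)
    b0 = cfg.seed_wid_mm / 2 / scale   # half width, px (row direction)
    max_lmm = max(r.l_max_mm for g in cfg.genotypes for r in g.roots)
    max_lpx = max_lmm / scale
    max_clip = max(g.heading_clip_deg for g in cfg.genotypes)
    lateral = max_lpx * np.sin(np.radians(max_clip)) + 3 * cfg.root_width_px
    seedling_px = cfg.seedling_max_mm / scale

    cell_w = int(np.ceil(2 * max(lateral, a0 + 10) + 10))
    cell_h = int(np.ceil(b0 * 2 + seedling_px + max_lpx + 30))
    top_pad = int(np.ceil(seedling_px + 10))

    H = cfg.n_rows * cell_h + 10
    W = cfg.n_cols * cell_w + 10
    if cfg.frame_shape is not None:
        if cfg.frame_shape[0] < H or cfg.frame_shape[1] < W:
            raise ValueError("layout overflow: grid too dense for seed size")
        H, W = cfg.frame_shape

    seeds: list[SeedTruth] = []
    rois: list[SeedROI] = []
    centers = []
    for sid in range(cfg.n_seeds):
        row, col = divmod(sid, cfg.n_cols)
        cr = 5 + row * cell_h + top_pad + b0
        cc = 5 + col * cell_w + cell_w / 2
        centers.append((cr, cc))
        gi = cfg.genotype_of_seed[sid]
        gp = cfg.genotypes[gi]
        swell = 1.0 + (gp.imbibition_swell - 1.0) * np.minimum(
            1.0, hours / cfg.swell_end_h)
        seeds.append(SeedTruth(sid, gi, (cr, cc), (a0, b0), swell,
                               coleoptile_frame=None, greening_frame=None))
        r0 = max(0, int(cr - b0 - seedling_px - 8))
        r1 = min(H, int(5 + (row + 1) * cell_h))
        c0 = max(0, int(5 + col * cell_w - 0.25 * cell_w))
        c1 = min(W, int(5 + (col + 1) * cell_w + 0.25 * cell_w))
        rois.append(SeedROI(sid, (r0, c0, r1, c1)))

    # decide which horizontally adjacent pairs cross
    crossing_pairs = []
    for sid in range(cfg.n_seeds):
        row, col = divmod(sid, cfg.n_cols)
        if col + 1 < cfg.n_cols:
            gp = cfg.genotypes[cfg.genotype_of_seed[sid]]
            if rng.random() < gp.crossing_probability:
                crossing_pairs.append((sid, sid + 1))

    swell_axes = {s.seed_id: (a0 * np.sqrt(s.swell_factor[-1]),
                              b0 * np.sqrt(s.swell_factor[-1]))
                  for s in seeds}

    # --- radicles (root 1), with optional crossing steering -----------------
    roots: list[RootTruth] = []
    crossings: list[CrossingEvent] = []
    partners = {a: b for a, b in crossing_pairs} | {b: a for a, b in
                                                    crossing_pairs}
    is_left = {a for a, _ in crossing_pairs}

    r1_truth: dict[int, RootTruth] = {}
    for s in seeds:
        gp = cfg.genotypes[s.genotype]
        p = gp.roots[0]
        t_e_h = rng.normal(p.emergence_mean_h, p.emergence_sd_h)
        t_e = int(np.ceil(max(0.0, t_e_h) / cfg.interval_h))
        sa, sb = swell_axes[s.seed_id]
        waypoint = None
        base = 180.0
        if s.seed_id in partners:
            other = partners[s.seed_id]
            sign = 1.0 if s.seed_id in is_left else -1.0
            base = 180.0 - sign * 20.0
            midc = (centers[s.seed_id][1] + centers[other][1]) / 2
            depth = centers[s.seed_id][0] + sb + 0.45 * (p.l_max_mm / scale)
            waypoint = (depth, midc)
        start = _ellipse_boundary_point(s.center, sa, sb, base)
        total_px = p.l_max_mm / scale + 10
        poly, arclen = _grow_polyline(rng, start, base, total_px, gp,
                                      waypoint=waypoint)
        if t_e >= cfg.n_frames:
            lengths = np.zeros(cfg.n_frames)
            t_e_frame = None
        else:
            lengths = _logistic_lengths(hours, t_e * cfg.interval_h, p)
            t_e_frame = t_e
        rt = RootTruth(s.seed_id, 1, t_e_frame, lengths, poly, arclen)
        r1_truth[s.seed_id] = rt
        roots.append(rt)

    # crossing events: first frame both radicles have passed the waypoint
    crossing_frame_of_seed: dict[int, int] = {}
    for a, b in crossing_pairs:
        ra, rb = r1_truth[a], r1_truth[b]
        if ra.t_e is None or rb.t_e is None:
            continue
        # the crossing point is the closest approach of the two polylines
        da = np.linalg.norm(ra.polyline[:, None, :] - rb.polyline[None, :, :],
                            axis=2)
        ia, ib = np.unravel_index(int(np.argmin(da)), da.shape)
        point = tuple((ra.polyline[ia] + rb.polyline[ib]) / 2)
        arc_a = ra.arclen_px[ia] * cfg.scale_mm_per_px
        arc_b = rb.arclen_px[ib] * cfg.scale_mm_per_px
        fa = int(np.searchsorted(ra.lengths_mm, arc_a, side="left"))
        fb = int(np.searchsorted(rb.lengths_mm, arc_b, side="left"))
        f = max(fa, fb)
        if f >= cfg.n_frames:
            continue
        crossings.append(CrossingEvent(f, a, 1, b, 1, point))
        crossing_frame_of_seed[a] = f
        crossing_frame_of_seed[b] = f

    # --- lateral roots ------------------------------------------------------
    for s in seeds:
        gp = cfg.genotypes[s.genotype]
        sa, sb = swell_axes[s.seed_id]
        r1 = r1_truth[s.seed_id]
        prev_h = None if r1.t_e is None else r1.t_e * cfg.interval_h
        for ri, p in enumerate(gp.roots[1:], start=2):
            t_e_h = rng.normal(p.emergence_mean_h, p.emergence_sd_h)
            if prev_h is None:
                # the radicle never emerged: laterals cannot either
                t_e_h = cfg.n_frames * cfg.interval_h + 1
            else:
                # laterals follow the radicle; emergence order defines the
                # root numbering, so keep it strict
                t_e_h = max(t_e_h, prev_h + 2.0 * cfg.interval_h)
            if (gp.lateral_after_crossing and ri == 2
                    and s.seed_id in crossing_frame_of_seed):
                t_e_h = (crossing_frame_of_seed[s.seed_id] + 4) * cfg.interval_h
            prev_h = t_e_h
            t_e = int(np.ceil(max(0.0, t_e_h) / cfg.interval_h))
            base = 180.0 - 45.0 if ri == 2 else 180.0 + 45.0
            start = _ellipse_boundary_point(s.center, sa, sb, base)
            poly, arclen = _grow_polyline(rng, start, base,
                                          p.l_max_mm / scale + 10, gp)
            if t_e >= cfg.n_frames:
                lengths = np.zeros(cfg.n_frames)
                t_e_frame = None
            else:
                lengths = _logistic_lengths(hours, t_e * cfg.interval_h, p)
                t_e_frame = t_e
            roots.append(RootTruth(
                s.seed_id, ri, t_e_frame, lengths, poly, arclen,
                emerged_after_crossing=(
                    s.seed_id in crossing_frame_of_seed
                    and t_e_frame is not None
                    and t_e_frame >= crossing_frame_of_seed[s.seed_id])))

    # --- seedling events ----------------------------------------------------
    for s in seeds:
        gp = cfg.genotypes[s.genotype]
        col_h = rng.normal(gp.seedling_mean_h, gp.seedling_sd_h)
        green_h = col_h + max(1.0, rng.normal(gp.greening_delay_mean_h,
                                              gp.greening_delay_sd_h))
        col_f = int(np.ceil(max(0.0, col_h) / cfg.interval_h))
        green_f = int(np.ceil(green_h / cfg.interval_h))
        s.coleoptile_frame = col_f if col_f < cfg.n_frames else None
        s.greening_frame = (green_f if s.coleoptile_frame is not None
                            and green_f < cfg.n_frames else None)

    truth = GroundTruth(cfg, seeds, roots, crossings, rois)
    if render == "none":
        return None, None, truth

    label_maps, frames = _render(cfg, truth, (H, W), rng,
                                 with_rgb=(render == "rgb"))
    series = None
    if render == "rgb":
        series = ImageSeries(frames, cfg.interval_h, scale,
                             cfg.paper_color)
    return series, label_maps, truth


# ---------------------------------------------------------------------------
# rendering


def _stamp_points(canvas, pts, radius, value):
    H, W = canvas.shape
    for r, c in pts:
        rr, cc = draw_disk((r, c), radius, shape=(H, W))
        canvas[rr, cc] = value


def _polyline_points_upto(rt: RootTruth, length_px: float) -> np.ndarray:
    """Polyline vertices covering the first ``length_px`` of arc length."""
    if length_px <= 0:
        return np.empty((0, 2))
    idx = int(np.searchsorted(rt.arclen_px, length_px, side="right"))
    pts = rt.polyline[:max(1, idx)]
    if idx < len(rt.polyline):
        # interpolate the tip so rendered arc length matches the truth
        prev = rt.polyline[idx - 1] if idx > 0 else rt.polyline[0]
        seg = rt.polyline[idx] - prev
        seglen = np.linalg.norm(seg)
        excess = length_px - rt.arclen_px[max(0, idx - 1)]
        if seglen > 0 and excess > 0:
            tip = prev + seg * min(1.0, excess / seglen)
            pts = np.vstack([pts, tip])
    return pts


def _render(cfg: SimConfig, truth: GroundTruth, shape, rng, with_rgb: bool):
    H, W = shape
    scale = cfg.scale_mm_per_px
    root_r = max(1, cfg.root_width_px // 2)
    seedling_r = max(1, cfg.seedling_width_px // 2)
    label_maps = []
    frames = []
    paper = np.array(PAPER_RGB[cfg.paper_color], float)

    for t in range(cfg.n_frames):
        labels = np.zeros((H, W), np.uint8)
        for rt in truth.roots:
            if rt.t_e is None or t < rt.t_e:
                continue
            pts = _polyline_points_upto(rt, rt.lengths_mm[t] / scale)
            _stamp_points(labels, pts, root_r, ROOT)
        for s in truth.seeds:
            a, b = s.axes_px
            f = np.sqrt(s.swell_factor[t])
            rr, cc = draw_ellipse(s.center[0], s.center[1], b * f, a * f,
                                  shape=(H, W))
            labels[rr, cc] = SEED_BODY
        for s in truth.seeds:
            if s.coleoptile_frame is None or t < s.coleoptile_frame:
                continue
            hrs = (t - s.coleoptile_frame) * cfg.interval_h
            length = min(cfg.seedling_max_mm,
                         0.3 + hrs * cfg.seedling_rate_mm_per_h) / scale
            a, b = s.axes_px
            f = np.sqrt(s.swell_factor[t])
            top = np.array([s.center[0] - b * f + 1.0, s.center[1]])
            n_pts = max(2, int(length / 1.5))
            pts = [top + i / (n_pts - 1) * np.array([-length, 0.0])
                   for i in range(n_pts)]
            _stamp_points(labels, pts, seedling_r, SEEDLING)
        label_maps.append(LabelMap(labels))

        if with_rgb:
            img = np.empty((H, W, 3), float)
            img[:] = paper
            img[labels == SEED_BODY] = SEED_RGB
            img[labels == ROOT] = ROOT_RGB
            img[labels == SEEDLING] = SEEDLING_RGB
            for s in truth.seeds:
                if s.greening_frame is not None and t >= s.greening_frame:
                    # recolour only this seed's seedling pixels
                    roi = truth.rois[s.seed_id]
                    r0, c0, r1, c1 = roi.box
                    sub = labels[r0:r1, c0:c1] == SEEDLING
                    img[r0:r1, c0:c1][sub] = SEEDLING_GREEN_RGB
            img += rng.normal(0.0, cfg.pixel_noise_sd, img.shape)
            np.clip(img, 0, 255, out=img)
            frames.append(Frame(t, t * cfg.interval_h, img.astype(np.uint8)))
    return label_maps, frames


# ---------------------------------------------------------------------------
# truth tables


def truth_tables(gt: GroundTruth, scale_mm_per_px: float | None = None):
    """Emit the pipeline's ``lengths`` / ``events`` schemas from ground truth."""
    cfg = gt.cfg
    rows = []
    for rt in gt.roots:
        for f in range(cfg.n_frames):
            rows.append({"seed_id": rt.seed_id, "root_index": rt.root_index,
                         "frame": f, "hour": f * cfg.interval_h,
                         "length_mm": float(rt.lengths_mm[f])})
    lengths = pd.DataFrame(rows)

    erows = []
    for s in gt.seeds:
        r1 = next((r for r in gt.roots_of(s.seed_id) if r.root_index == 1),
                  None)
        gp = cfg.genotypes[s.genotype]

        def first_hour(target):
            if r1 is None or r1.t_e is None:
                return None
            idx = np.nonzero(r1.lengths_mm >= target)[0]
            return float(idx[0] * cfg.interval_h) if idx.size else None

        prot = None if r1 is None or r1.t_e is None else float(
            r1.t_e * cfg.interval_h)
        erows.append({
            "seed_id": s.seed_id,
            "genotype": gp.name,
            "protrusion_h": prot,
            "t2mm_h": first_hour(2.0),
            "t10mm_h": first_hour(10.0),
            "coleoptile_h": (None if s.coleoptile_frame is None
                             else float(s.coleoptile_frame * cfg.interval_h)),
            "chloroplast_h": (None if s.greening_frame is None
                              else float(s.greening_frame * cfg.interval_h)),
            "designed_tier": gp.designed_tier,
        })
    events = pd.DataFrame(erows)
    return lengths, events


# ---------------------------------------------------------------------------
# presets


def preset(name: str, rng_seed: int = 0, **overrides) -> SimConfig:
    """Named scenario configurations used throughout the test-suite."""
    if name == "no-crossings":
        cfg = SimConfig(rng_seed=rng_seed, n_rows=4, n_cols=4, n_frames=96,
                        genotypes=[GenotypeParams("G1")])
    elif name == "one-crossing":
        gp = GenotypeParams("G1", crossing_probability=1.0,
                            lateral_after_crossing=True,
                            roots=(RootParams(35.0, 3.0, 13.0),
                                   RootParams(55.0, 5.0, 7.0),
                                   RootParams(65.0, 5.0, 5.0)))
        cfg = SimConfig(rng_seed=rng_seed, n_rows=1, n_cols=2, n_frames=96,
                        genotypes=[gp])
    elif name == "three-tier-vigor":
        tiers = {
            "high": dict(mean=30.0, sd=1.5, seedling=55.0, ssd=1.5,
                         delay=10.0, dsd=1.5, lmax=13.0),
            "medium": dict(mean=42.0, sd=3.0, seedling=62.0, ssd=3.0,
                           delay=12.0, dsd=3.0, lmax=12.0),
            "low": dict(mean=56.0, sd=10.0, seedling=74.0, ssd=10.0,
                        delay=16.0, dsd=9.0, lmax=11.0),
        }
        genotypes = []
        for tier, tp in tiers.items():
            for j in range(3):
                shift = (j - 1) * 1.5
                genotypes.append(GenotypeParams(
                    f"{tier[0].upper()}{j + 1}",
                    roots=(RootParams(tp["mean"] + shift, tp["sd"],
                                      tp["lmax"]),
                           RootParams(tp["mean"] + 18 + shift, tp["sd"] + 1,
                                      7.0),
                           RootParams(tp["mean"] + 28 + shift, tp["sd"] + 1,
                                      5.0)),
                    seedling_mean_h=tp["seedling"] + shift,
                    seedling_sd_h=tp["ssd"],
                    greening_delay_mean_h=tp["delay"],
                    greening_delay_sd_h=tp["dsd"],
                    designed_tier=tier))
        n_geno = len(genotypes)
        seeds_per_geno = 20
        n = n_geno * seeds_per_geno
        cfg = SimConfig(rng_seed=rng_seed, n_rows=n_geno, n_cols=seeds_per_geno,
                        n_frames=96, genotypes=genotypes,
                        genotype_of_seed=[i // seeds_per_geno
                                          for i in range(n)])
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(cfg, **overrides) if overrides else cfg
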