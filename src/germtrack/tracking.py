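"""Temporal-graph tracking of root tips.

Every root is modelled as a growing directed graph over time.  Before the
root emerges the graph is empty; at emergence it holds a single vertex — the
skeleton point at the seed coat — and from then on each frame may append the
newly detected tip position together with the skeleton route connecting it
to the previous tip.  A candidate tip ``P`` is accepted when

* the route from the current tip ``V_t`` to ``P`` has minimum weight, where
  stepping onto a skeleton pixel costs 0 and onto any other pixel costs 1
  (8-connected grid search), and
* the turn is limited: ``cos(dir(V_{t-1}, V_t), dir(V_t, P)) >= cos_min``
  (0.5, i.e. at most 60 degrees, by default).

If no candidate qualifies the graph is simply left unchanged for the frame.
Once a root crossing is seen for a seed, no *new* roots are opened for it;
existing tracks continue through crossings along resolved arm pairings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.graph import MCP

from .intersections import (CrossingRegion, detect_crossing_regions,
                            resolve_crossing, route_respects_crossings)
from .series_io import MaskTriplet, SeedROI
from .skeleton import SkeletonGraph, clockwise_angle, detect_root_tips

# Resampling stride (px) for geometric length of a digitised route.
# Summing raw 1 / sqrt(2) chain steps overestimates the length of digitised
# lines at intermediate orientations by up to ~8%; measuring the route as a
# polyline resampled every few pixels removes the staircase bias (residual
# error well under 1% for root-scale curvature).
LENGTH_RESAMPLE_PX = 4

# Minimum tip-to-tip baseline (px) for growth-direction estimates; below
# this the 8-connected grid quantises angles too coarsely for the 60-degree
# acceptance cone to be meaningful.
DIR_BASELINE_PX = 5.0


@dataclass
class TrackConfig:
    cos_min: float = 0.5                 # cos(60 deg): max turn per frame
    dilation_px: int = 3                 # seed-coat margin for tip removal
    arm_len_px: int = 15                 # crossing-arm direction window
    max_missed: int = 5                  # frames without a tip before closing
    max_roots: int = 3                   # radicle + two lateral roots
    roi_dilate_frac: float = 0.2         # candidate search margin around ROI
    no_new_tracks_after_crossing: bool = True
    origin_max_dist_px: float = 6.0      # new root must start at the seed coat
    max_route_cost: float = 20.0         # off-skeleton pixel budget per route
    max_step_px: float = 15.0            # per-frame tip displacement cap
    component_radius_px: float = 3.0     # locate a track on the skeleton
    length_resample_px: int = LENGTH_RESAMPLE_PX
    merge_radius: float = 5.0            # branch-point pairing distance
    new_root_attach_px: float = 3.0      # tip this close to a track is not new

    def __post_init__(self):
        if not -1.0 <= self.cos_min <= 1.0:
            raise ValueError("cos_min must be in [-1, 1]")


@dataclass
class TipCandidates:
    frame: int
    positions: list[tuple[int, int]]


@dataclass
class TrackingGraph:
    """One root's temporal graph (coordinates local to the seed's crop)."""

    seed_id: int
    root_index: int
    t_e: int                              # emergence frame
    origin: tuple[int, int]               # skeleton point at the seed coat
    vertices: list[tuple[int, tuple[int, int]]] = field(default_factory=list)
    route_lengths_px: list[float] = field(default_factory=list)
    cumlen_px: list[float] = field(default_factory=list)  # per frame
    closed: bool = False
    close_frame: int | None = None
    missed: int = 0

    @property
    def last_vertex(self):
        return self.vertices[-1][1] if self.vertices else self.origin

    @property
    def last_direction(self) -> np.ndarray | None:
        """Recent growth direction (unit vector), or None before any growth.

        Measured tip-to-tip over a baseline of at least ``DIR_BASELINE_PX``
        so that single-pixel steps do not quantise the angle: the reference
        vertex is the most recent one at least that far behind the tip
        (falling back to the origin).
        """
        if not self.vertices:
            return None
        last = np.array(self.last_vertex, float)
        ref = np.array(self.origin, float)
        for _, p in reversed(self.vertices[:-1]):
            if np.hypot(*(last - p)) >= DIR_BASELINE_PX:
                ref = np.array(p, float)
                break
        vec = last - ref
        n = np.linalg.norm(vec)
        return vec / n if n > 0 else None

    def total_length_px(self) -> float:
        return float(sum(self.route_lengths_px))


# ---------------------------------------------------------------------------
# route search


def route_costs(skel_mask: np.ndarray, start, goals, window_mask=None):
    """Min-weight routes from ``start`` to each goal over the 0/1 grid.

    Weights follow the tracking rule: skeleton pixels cost 0, all other
    pixels cost 1; moves are 8-connected; a path's cost is the sum of the
    costs of every pixel it visits (start included).

    Returns ``{goal: (cost, route)}`` with routes as lists of (row, col).
    """
    goals = [tuple(g) for g in goals]
    if not goals:
        return {}
    start = tuple(start)
    # search window: the skeleton's bounding box plus the query points.
    # Zero-cost detours all lie on the skeleton, so restricting the grid to
    # this window (with margin) preserves optimal costs.
    pts = np.array([start] + goals)
    box_mask = skel_mask if window_mask is None else window_mask
    if box_mask.any():
        rows = np.flatnonzero(box_mask.any(axis=1))
        cols = np.flatnonzero(box_mask.any(axis=0))
        r_lo = min(pts[:, 0].min(), rows[0])
        r_hi = max(pts[:, 0].max(), rows[-1])
        c_lo = min(pts[:, 1].min(), cols[0])
        c_hi = max(pts[:, 1].max(), cols[-1])
    else:
        r_lo, r_hi = pts[:, 0].min(), pts[:, 0].max()
        c_lo, c_hi = pts[:, 1].min(), pts[:, 1].max()
    r0 = max(0, int(r_lo) - 2)
    c0 = max(0, int(c_lo) - 2)
    r1 = min(skel_mask.shape[0], int(r_hi) + 3)
    c1 = min(skel_mask.shape[1], int(c_hi) + 3)

    cost_arr = np.where(skel_mask[r0:r1, c0:c1], 0.0, 1.0)
    mcp = MCP(cost_arr, fully_connected=True)
    local_goals = [(g[0] - r0, g[1] - c0) for g in goals]
    costs, _ = mcp.find_costs([(start[0] - r0, start[1] - c0)],
                              ends=local_goals, find_all_ends=True)
    out = {}
    for g, lg in zip(goals, local_goals):
        c = costs[lg]
        if not np.isfinite(c):
            continue
        route = [(p[0] + r0, p[1] + c0) for p in mcp.traceback(lg)]
        out[g] = (float(c), route)
    return out


def route_geometric_length(route, skel_mask=None,
                           resample_px: int = LENGTH_RESAMPLE_PX) -> float:
    """Geometric length (px) of an accepted pixel route.

    The route is measured as a polyline resampled every ``resample_px``
    pixels (endpoints kept), which removes the systematic overestimate of
    raw 8-connected chain-code lengths on digitised curves.  Short
    off-skeleton bridging steps (the previous tip sitting a pixel off the
    freshly thinned skeleton) are part of the root's path and are included;
    the resampling absorbs the lateral jog.
    """
    route = list(route)
    if len(route) < 2:
        return 0.0
    pts = route[::resample_px]
    if (len(route) - 1) % resample_px:
        pts = pts + [route[-1]]
    arr = np.array(pts, float)
    return float(np.hypot(*np.diff(arr, axis=0).T).sum())


# ---------------------------------------------------------------------------
# track construction


def _component_near(skel: SkeletonGraph, point, radius: float) -> int:
    """Skeleton component id at/near a point (0 if none within radius)."""
    if skel.labels is None or skel.n_pixels == 0:
        return 0
    comp = skel.component_of(point)
    if comp:
        return comp
    r = int(np.ceil(radius))
    H, W = skel.mask.shape
    r0, c0 = max(0, point[0] - r), max(0, point[1] - r)
    win = skel.labels[r0:min(H, point[0] + r + 1),
                      c0:min(W, point[1] + r + 1)]
    cand = np.argwhere(win > 0)
    if cand.size == 0:
        return 0
    d = np.hypot(cand[:, 0] + r0 - point[0], cand[:, 1] + c0 - point[1])
    i = int(np.argmin(d))
    if d[i] > radius:
        return 0
    return int(win[cand[i, 0], cand[i, 1]])


def init_track(seed_id: int, root_index: int, t_e: int, origin) -> TrackingGraph:
    """Open a root's graph: at frame ``t_e - 1`` it holds only the coat point."""
    return TrackingGraph(seed_id=seed_id, root_index=root_index, t_e=t_e,
                         origin=tuple(origin))


def extend_track(g: TrackingGraph, cands: TipCandidates,
                 skel: SkeletonGraph, cfg: TrackConfig,
                 regions: list[CrossingRegion] | None = None) -> bool:
    """Try to append one accepted tip for this frame; returns True if grown.

    Non-extension is a valid outcome (zero growth recorded for the frame).
    """
    if g.closed:
        return False
    last = np.array(g.last_vertex, float)
    last_dir = g.last_direction
    comp = _component_near(skel, g.last_vertex, cfg.component_radius_px)

    qualified = []   # (position, cos to last direction)
    tip_still_there = False
    for pos in cands.positions:
        pos = tuple(pos)
        if pos == tuple(g.last_vertex):
            tip_still_there = True  # root present but not growing: no miss
            continue
        if comp and skel.component_of(pos) != comp:
            continue  # a different root's skeleton (no crossing joins them)
        vec = np.array(pos, float) - last
        norm = np.linalg.norm(vec)
        if norm == 0:
            continue
        # a root tip cannot jump arbitrarily far in one interval; allow
        # proportionally more after missed detections
        if norm > cfg.max_step_px * (g.missed + 1):
            continue
        cosang = 1.0
        if last_dir is not None:
            cosang = float(np.dot(last_dir, vec / norm))
            if cosang < cfg.cos_min:
                continue
        qualified.append((pos, cosang))
    if not qualified:
        if tip_still_there:
            g.missed = 0
        else:
            g.missed += 1
            if g.missed > cfg.max_missed:
                g.closed = True
                g.close_frame = cands.frame
        return False

    window = skel.labels == comp if comp else None
    routes = route_costs(skel.mask, g.last_vertex, [p for p, _ in qualified],
                         window_mask=window)
    best = None
    for pos, cosang in qualified:
        if pos not in routes:
            continue
        cost, route = routes[pos]
        if cost > cfg.max_route_cost:
            continue  # too much off-skeleton bridging: not this root
        if regions and not route_respects_crossings(route, regions):
            continue
        eucl = float(np.hypot(pos[0] - last[0], pos[1] - last[1]))
        # min route weight first; at equal weight prefer the straightest
        # continuation (the 180-degree preference), then the nearest tip
        key = (cost, -cosang, eucl, pos)
        if best is None or key < best[0]:
            best = (key, pos, route)
    if best is None:
        if tip_still_there:
            g.missed = 0
        else:
            g.missed += 1
            if g.missed > cfg.max_missed:
                g.closed = True
                g.close_frame = cands.frame
        return False

    _, pos, route = best
    g.vertices.append((cands.frame, pos))
    g.route_lengths_px.append(route_geometric_length(
        route, skel.mask, cfg.length_resample_px))
    g.missed = 0
    return True


@dataclass
class SeedFrameObservation:
    """Per-frame detections for one seed, in crop-local coordinates."""

    frame: int
    skel: SkeletonGraph
    tips: list[tuple[int, int]]
    origins: dict[int, tuple[tuple[int, int], float]]
    regions: list[CrossingRegion]
    triplet: MaskTriplet
    own_seed_body: np.ndarray | None = None


def observe_seed_frame(frame_index: int, triplet: MaskTriplet,
                       cfg: TrackConfig,
                       own_seed_body=None) -> SeedFrameObservation:
    """Skeletonise a seed's root mask and detect tips and crossings."""
    skel = skeletonize_root(triplet, cfg)
    tips, origins = detect_root_tips(skel, triplet, cfg.dilation_px,
                                     own_seed_body=own_seed_body)
    regions = detect_crossing_regions(skel, cfg.arm_len_px)
    return SeedFrameObservation(frame_index, skel, tips, origins, regions,
                                triplet, own_seed_body=own_seed_body)


def skeletonize_root(triplet: MaskTriplet, cfg: TrackConfig) -> SkeletonGraph:
    from .skeleton import skeletonize_mask
    return skeletonize_mask(triplet.root, cfg.merge_radius)


def track_seed(seed_id: int, observations: list[SeedFrameObservation],
               cfg: TrackConfig | None = None,
               roi_local_box: tuple[int, int, int, int] | None = None
               ) -> list[TrackingGraph]:
    """Track all roots of one seed through its per-frame observations.

    ``roi_local_box`` is the seed's undilated ROI expressed in the crop's
    local coordinates; a track whose accepted tip leaves this box is closed.
    Up to ``cfg.max_roots`` graphs are opened; after the seed's first root
    crossing no further graphs are opened.
    """
    cfg = cfg or TrackConfig()
    tracks: list[TrackingGraph] = []
    crossed = False

    for obs in observations:
        t = obs.frame
        if obs.regions:
            for region in obs.regions:
                dirs = [tr.last_direction for tr in tracks
                        if tr.last_direction is not None]
                resolve_crossing(region, last_directions=dirs or None)
            crossed = True

        claimed: set[tuple[int, int]] = set()
        for tr in sorted([x for x in tracks if not x.closed],
                         key=lambda x: x.root_index):
            cands = TipCandidates(t, [p for p in obs.tips if p not in claimed])
            if extend_track(tr, cands, obs.skel, cfg, obs.regions):
                claimed.add(tuple(tr.last_vertex))
                if roi_local_box is not None:
                    r0, c0, r1, c1 = roi_local_box
                    r, c = tr.last_vertex
                    if not (r0 <= r < r1 and c0 <= c < c1):
                        tr.closed = True
                        tr.close_frame = t

        if not (crossed and cfg.no_new_tracks_after_crossing):
            _open_new_tracks(seed_id, tracks, obs, claimed, cfg)

        for tr in tracks:
            cum = tr.total_length_px()
            while len(tr.cumlen_px) <= t:
                tr.cumlen_px.append(0.0)
            tr.cumlen_px[t] = cum if tr.vertices else 0.0
            # frames before emergence stay 0
            for f in range(len(tr.cumlen_px) - 1):
                if f < tr.t_e:
                    tr.cumlen_px[f] = 0.0

    n_frames = len(observations)
    for tr in tracks:
        # forward-fill cumulative length to the series end
        while len(tr.cumlen_px) < n_frames:
            tr.cumlen_px.append(tr.total_length_px())
    return tracks


def _open_new_tracks(seed_id, tracks, obs: SeedFrameObservation, claimed,
                     cfg: TrackConfig):
    """Open graphs for skeleton components newly touching the seed coat.

    A graph opens on the first frame a root skeleton component reaches the
    seed coat, whether or not a tip is detectable yet (it may still sit in
    the dilated exclusion zone; the tip is then appended in a later frame).
    Components overlapping any existing track's recorded points belong to
    an already-tracked root and are skipped.
    """
    if len(tracks) >= cfg.max_roots:
        return
    skel = obs.skel
    if skel.n_pixels == 0:
        return
    coords = np.argwhere(skel.mask)
    comp_ids = skel.labels[coords[:, 0], coords[:, 1]]

    # every point any track has ever claimed (origin + accepted vertices)
    anchors = []
    for tr in tracks:
        anchors.append(tr.origin)
        anchors.extend(p for _, p in tr.vertices)
    anchors = np.array(anchors, float) if anchors else None

    new_entries = []
    for comp, (origin, dist) in sorted(obs.origins.items()):
        if dist > cfg.origin_max_dist_px:
            continue  # not rooted at this seed's coat (e.g. a neighbour's)
        sub = coords[comp_ids == comp]
        if anchors is not None:
            d = np.hypot(sub[:, 0, None] - anchors[None, :, 0],
                         sub[:, 1, None] - anchors[None, :, 1]).min()
            if d <= cfg.new_root_attach_px:
                continue  # part of an already-tracked root
        new_entries.append((comp, origin))

    if not new_entries:
        return
    body = (obs.own_seed_body if obs.own_seed_body is not None
            else obs.triplet.seed_body)
    if body.any():
        centroid = np.argwhere(body).mean(axis=0)
    else:
        centroid = np.array(obs.skel.mask.shape, float) / 2
    new_entries.sort(key=lambda e: clockwise_angle(e[1], centroid))
    for comp, origin in new_entries:
        if len(tracks) >= cfg.max_roots:
            break
        g = init_track(seed_id, len(tracks) + 1, obs.frame, origin)
        tracks.append(g)
        # try to accept a first tip right away
        cands = TipCandidates(obs.frame,
                              [p for p in obs.tips
                               if p not in claimed
                               and skel.component_of(p) == comp])
        if extend_track(g, cands, skel, cfg):
            claimed.add(tuple(g.last_vertex))


# ---------------------------------------------------------------------------
# derived quantities


def cumulative_length(g: TrackingGraph, upto_frame: int,
                      scale_mm_per_px: float) -> float:
    """Tracked root length in mm up to (and including) a frame."""
    if upto_frame < g.t_e:
        return 0.0
    if not g.cumlen_px:
        return 0.0
    idx = min(upto_frame, len(g.cumlen_px) - 1)
    return float(g.cumlen_px[idx]) * scale_mm_per_px


def length_series_mm(g: TrackingGraph, n_frames: int,
                     scale_mm_per_px: float) -> np.ndarray:
    out = np.zeros(n_frames)
    for f in range(n_frames):
        out[f] = cumulative_length(g, f, scale_mm_per_px)
    return out


def growth_rate_series(lengths_mm: np.ndarray, interval_h: float = 1.0,
                       smooth_window: int = 5) -> np.ndarray:
    """Growth rate (mm/h) as the centred derivative of smoothed lengths."""
    lengths_mm = np.asarray(lengths_mm, float)
    n = len(lengths_mm)
    w = smooth_window
    if w > n:
        warnings.warn(f"smoothing window {w} shrunk to series length {n}")
        w = n
    if w % 2 == 0:
        w = max(1, w - 1)
    if w > 1:
        pad = w // 2
        padded = np.pad(lengths_mm, pad, mode="edge")
        sm = np.convolve(padded, np.ones(w) / w, mode="valid")
    else:
        sm = lengths_mm
    return np.gradient(sm, interval_h)


def rate_change_series(lengths_mm: np.ndarray, interval_h: float = 1.0,
                       smooth_window: int = 5) -> np.ndarray:
    """Derivative of the growth-rate curve (mm/h^2)."""
    rate = growth_rate_series(lengths_mm, interval_h, smooth_window)
    return np.gradient(rate, interval_h)


def fastest_rate_change_frame(lengths_mm: np.ndarray, interval_h: float = 1.0,
                              smooth_window: int = 5) -> int:
    """Frame of the fastest change in growth rate (peak |d rate / dt|).

    The first and last ``smooth_window`` frames are excluded from the
    search: edge-padded smoothing inflates the second derivative there.
    """
    rc = np.abs(rate_change_series(lengths_mm, interval_h, smooth_window))
    w = smooth_window
    if len(rc) > 3 * w:
        return int(np.argmax(rc[w:-w])) + w
    return int(np.argmax(rc))
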