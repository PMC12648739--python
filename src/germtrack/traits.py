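"""Static and dynamic seed-level traits.

Morphology (area, length, width, perimeter, W/L ratio, roundness), coat
colour, change rates relative to the first frame, and the timing of
germination events: protrusion, reaching 2 mm (the "germinated" rule) and
10 mm (root-system establishment), coleoptile emergence, chloroplast
biogenesis (greening, via the excess-green index ExG = 2G - R - B), and the
lot-level phase times under the 75% rule.

Event times are reported on the frame grid (no sub-frame interpolation);
events never observed within the series are censored (returned as None).
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint
from skimage.measure import approximate_polygon, find_contours
from skimage.morphology import disk

from .series_io import ImageSeries, MaskTriplet

#: Douglas-Peucker tolerance (px) for perimeter measurement; smooths the
#: marching-squares staircase so rasterised circles measure round.
_CONTOUR_TOL = 1.0


def _largest_component(mask: np.ndarray) -> tuple[np.ndarray, bool]:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask, False
    sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                               index=np.arange(1, n + 1))
    keep = 1 + int(np.argmax(sizes))
    return labels == keep, True


def _boundary_polygon(mask: np.ndarray) -> np.ndarray | None:
    """Simplified sub-pixel boundary polygon (marching squares + DP)."""
    padded = np.pad(mask.astype(float), 1)
    contours = find_contours(padded, 0.5)
    if not contours:
        return None
    c = max(contours, key=len)
    return approximate_polygon(c, tolerance=_CONTOUR_TOL) - 1.0


def _polygon_length(poly: np.ndarray) -> float:
    d = np.diff(poly, axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def measure_seed_morphology(seed_body: np.ndarray, scale_mm_per_px: float
                            ) -> dict:
    """Morphological traits of a seed-body mask, in millimetres.

    Length and width are the side lengths of the minimum-area rotated
    bounding rectangle (length = longer side); roundness is the isoperimetric
    ratio 4*pi*area / perimeter^2.  An empty mask yields NaNs with
    ``flagged`` set; a fragmented mask keeps the largest component.
    """
    seed_body = np.asarray(seed_body, bool)
    out = {k: math.nan for k in ("area_mm2", "length_mm", "width_mm",
                                 "perimeter_mm", "wl_ratio", "roundness")}
    out["flagged"] = False
    if not seed_body.any():
        out["flagged"] = True
        return out
    mask, fragmented = _largest_component(seed_body)
    out["flagged"] = fragmented

    area_px = float(mask.sum())
    poly = _boundary_polygon(mask)
    perim_px = _polygon_length(poly) if poly is not None else 0.0
    coords = np.argwhere(mask)
    rect = (MultiPoint([tuple(p) for p in poly]).minimum_rotated_rectangle
            if poly is not None else None)
    if rect is not None and rect.geom_type == "Polygon":
        xy = np.asarray(rect.exterior.coords)
        sides = np.hypot(*(np.diff(xy, axis=0).T))
        length_px = float(np.max(sides[:2]))
        width_px = float(np.min(sides[:2]))
    else:  # degenerate (line or point) mask
        span = coords.max(axis=0) - coords.min(axis=0) + 1
        length_px, width_px = float(max(span)), float(min(span))

    s = scale_mm_per_px
    out.update(area_mm2=area_px * s * s,
               length_mm=length_px * s,
               width_mm=width_px * s,
               perimeter_mm=perim_px * s,
               wl_ratio=width_px / length_px if length_px else math.nan,
               roundness=(4 * math.pi * area_px / perim_px ** 2
                          if perim_px else math.nan))
    return out


def measure_seed_color(frame_pixels: np.ndarray, seed_body: np.ndarray):
    """Arithmetic per-channel mean of the coat pixels; None if mask empty."""
    seed_body = np.asarray(seed_body, bool)
    if not seed_body.any():
        return None
    px = frame_pixels[seed_body].astype(float)
    return tuple(px.mean(axis=0))


def change_rate_percent(values) -> np.ndarray:
    """Per-frame change relative to frame 0, in percent."""
    values = np.asarray(values, float)
    if values[0] == 0 or not np.isfinite(values[0]):
        return np.full_like(values, np.nan)
    return 100.0 * (values - values[0]) / values[0]


def exg(rgb) -> np.ndarray:
    """Excess-green index 2G - R - B on raw 8-bit channels (-510..510)."""
    rgb = np.asarray(rgb, dtype=float)
    return 2.0 * rgb[..., 1] - rgb[..., 0] - rgb[..., 2]


# ---------------------------------------------------------------------------
# event times


def chloroplast_time(series: ImageSeries,
                     seedling_masks_by_seed: dict[int, list[np.ndarray]],
                     rois=None,
                     ref_hour: float = 80.0,
                     lotwise: bool = True,
                     min_exceed_px: int = 5) -> dict[int, float | None]:
    """Hour of chloroplast biogenesis per seed, or None if censored.

    The greenness threshold is the mean ExG over seedling pixels at the
    reference frame (lot-wise over all seeds by default, per seed with
    ``lotwise=False``); a seed's greening time is the first hour at which at
    least ``min_exceed_px`` of its seedling pixels exceed that threshold
    (the small pixel count guards against salt noise).
    """
    hours = series.hours
    ref_idx = int(np.argmin(np.abs(hours - ref_hour)))
    if not np.isclose(hours[ref_idx], ref_hour):
        warnings.warn(f"reference hour {ref_hour} outside series; "
                      f"using hour {hours[ref_idx]}")

    def _roi_pixels(sid, f):
        px = series.frames[f].pixels
        if rois is not None:
            from .series_io import crop_roi
            px = crop_roi(px, rois[sid])
        return px

    ref_vals = {}
    for sid, masks in seedling_masks_by_seed.items():
        m = masks[ref_idx]
        if m is not None and m.any():
            ref_vals[sid] = exg(_roi_pixels(sid, ref_idx))[m]

    if not ref_vals:
        warnings.warn("no seedling pixels at the reference hour: "
                      "all greening times censored")
        return {sid: None for sid in seedling_masks_by_seed}

    lot_threshold = float(np.concatenate(list(ref_vals.values())).mean())

    out = {}
    for sid, masks in seedling_masks_by_seed.items():
        if lotwise:
            thr = lot_threshold
        elif sid in ref_vals:
            thr = float(ref_vals[sid].mean())
        else:
            out[sid] = None
            continue
        out[sid] = None
        for f, m in enumerate(masks):
            if m is None or not m.any():
                continue
            n_over = int((exg(_roi_pixels(sid, f))[m] > thr).sum())
            if n_over >= min(min_exceed_px, int(m.sum())):
                out[sid] = float(hours[f])
                break
    return out


def coleoptile_time(seedling_masks: list[np.ndarray],
                    seed_body_masks: list[np.ndarray],
                    interval_h: float = 1.0,
                    contact_px: int = 1) -> float | None:
    """First hour the seedling mask touches the seed body, or None.

    Label maps carry disjoint classes, so "overlap" is evaluated against the
    seed body dilated by ``contact_px`` (adjacency counts as contact);
    externally supplied, genuinely overlapping masks are caught directly.
    """
    for f, (sm, bm) in enumerate(zip(seedling_masks, seed_body_masks)):
        if sm is None or bm is None or not sm.any():
            continue
        grown = (ndimage.binary_dilation(bm, structure=disk(contact_px))
                 if contact_px else bm)
        if (sm & grown).any():
            return float(f * interval_h)
    return None


def time_to_length(lengths_mm, hours, target_mm: float) -> float | None:
    """First hour the (non-decreasing) length reaches the target, or None."""
    lengths_mm = np.asarray(lengths_mm, float)
    hours = np.asarray(hours, float)
    idx = np.nonzero(lengths_mm >= target_mm)[0]
    return float(hours[idx[0]]) if idx.size else None


def lot_phase_time(entry_hours: list[float | None], hours_grid,
                   threshold: float = 0.75,
                   n_sample: int | None = None,
                   rng: np.random.Generator | int | None = None
                   ) -> float | None:
    """Lot-level phase time: first hour >= ceil(threshold * n) seeds entered.

    ``entry_hours`` holds each seed's phase-entry hour (None = censored).
    With ``n_sample`` (the 15-seed standardisation), a seeded uniform sample
    without replacement is taken first.
    """
    entry = list(entry_hours)
    if n_sample is not None and n_sample < len(entry):
        gen = rng if isinstance(rng, np.random.Generator) \
            else np.random.default_rng(rng)
        idx = gen.choice(len(entry), size=n_sample, replace=False)
        entry = [entry[i] for i in sorted(idx)]
    n = len(entry)
    if n == 0:
        return None
    need = math.ceil(threshold * n)
    for h in np.asarray(hours_grid, float):
        count = sum(1 for e in entry if e is not None and e <= h)
        if count >= need:
            return float(h)
    return None


def seed_phase(triplet: MaskTriplet, radicle_len_mm: float) -> str:
    """Trait-derived germination phase of one seed at one frame."""
    from .segmentation import classify_phase_from_masks
    return classify_phase_from_masks(triplet, radicle_len_mm)
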