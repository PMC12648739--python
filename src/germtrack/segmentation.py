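"""Colour-threshold segmentation and rule-based phase calling.

A deterministic, training-free path from RGB frames to label maps so the
pipeline runs without externally supplied masks.  The paper-colour
background is matched in HSV space with per-colour presets; remaining
foreground is split into seedling (high excess-green), seed body (the
thick blob surviving a morphological opening) and root (everything thin).

Phase calling is trait-derived: IMB while no root is visible, PRO once a
root is visible but shorter than 2 mm, RE from 2 mm (the "germinated"
rule), SE as soon as a seedling mask is non-empty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.color import rgb2hsv
from skimage.morphology import disk

from .series_io import (BACKGROUND, ROOT, SEED_BODY, SEEDLING, Frame,
                        LabelMap, MaskTriplet, PHASES)
from .traits import exg

#: HSV ranges (each 0..1) matching the germination-paper background.
#: Hue ranges may wrap around 0.
PAPER_PRESETS = {
    "blue": {"h": (0.52, 0.75), "s": (0.35, 1.0), "v": (0.25, 1.0)},
    "black": {"h": (0.0, 1.0), "s": (0.0, 1.0), "v": (0.0, 0.25)},
    "dark_red": {"h": (0.93, 0.06), "s": (0.35, 1.0), "v": (0.15, 0.9)},
    "light_blue": {"h": (0.45, 0.68), "s": (0.12, 0.7), "v": (0.5, 1.0)},
}


@dataclass
class SegConfig:
    paper_color: str = "blue"
    paper_ranges: dict = field(default_factory=dict)  # overrides preset
    exg_seedling_min: float = 45.0     # ExG above this = seedling
    min_component_area_px: int = 20
    seed_opening_radius: int = 3       # removes thin roots, keeps the seed
    max_foreground_frac: float = 0.9

    def __post_init__(self):
        if self.min_component_area_px < 1:
            raise ValueError("min_component_area_px must be >= 1")
        if not self.paper_ranges:
            self.paper_ranges = PAPER_PRESETS[self.paper_color]


def _remove_small(mask: np.ndarray, min_area: int) -> np.ndarray:
    if min_area <= 1 or not mask.any():
        return mask
    lab, n = ndimage.label(mask)
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return (sizes >= min_area)[lab]


def _in_range(channel: np.ndarray, lo_hi, wrap: bool = False) -> np.ndarray:
    lo, hi = lo_hi
    if wrap and lo > hi:  # hue interval crossing 0
        return (channel >= lo) | (channel <= hi)
    return (channel >= lo) & (channel <= hi)


def segment_frame_classical(frame: Frame | np.ndarray,
                            cfg: SegConfig | None = None) -> LabelMap:
    """Segment one RGB frame into background / seed body / root / seedling."""
    cfg = cfg or SegConfig()
    pixels = frame.pixels if isinstance(frame, Frame) else np.asarray(frame)
    hsv = rgb2hsv(pixels)
    rng = cfg.paper_ranges
    background = (_in_range(hsv[..., 0], rng["h"], wrap=True)
                  & _in_range(hsv[..., 1], rng["s"])
                  & _in_range(hsv[..., 2], rng["v"]))
    fg = ~background
    fg = _remove_small(fg, cfg.min_component_area_px)
    fg = ndimage.binary_closing(fg, structure=disk(1))
    if fg.mean() > cfg.max_foreground_frac:
        warnings.warn("paper model mismatch: more than "
                      f"{cfg.max_foreground_frac:.0%} of pixels foreground")

    seedling = fg & (exg(pixels) >= cfg.exg_seedling_min)
    seedling = _remove_small(seedling, cfg.min_component_area_px)

    rest = fg & ~seedling
    core = ndimage.binary_opening(rest, structure=disk(cfg.seed_opening_radius))
    seed_body = rest & ndimage.binary_dilation(
        core, structure=disk(cfg.seed_opening_radius))
    seed_body = _remove_small(seed_body, cfg.min_component_area_px)
    root = rest & ~seed_body
    root = _remove_small(root, max(1, cfg.min_component_area_px // 4))

    labels = np.full(pixels.shape[:2], BACKGROUND, np.uint8)
    labels[root] = ROOT
    labels[seed_body] = SEED_BODY
    labels[seedling] = SEEDLING
    return LabelMap(labels)


def classify_phase_from_masks(triplet: MaskTriplet,
                              radicle_len_mm: float) -> str:
    """Germination phase of a seed from its masks and radicle length.

    Total on valid input: SE whenever the seedling mask is non-empty
    (coleoptile visible), otherwise IMB / PRO / RE by root presence and the
    2 mm germination threshold.
    """
    if radicle_len_mm < 0:
        raise ValueError("radicle length cannot be negative")
    if triplet.seedling.any():
        return "SE"
    has_root = triplet.root.any()
    if not has_root:
        return "IMB"
    return "PRO" if radicle_len_mm < 2.0 else "RE"


def phase_index(phase: str) -> int:
    return PHASES.index(phase)
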