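"""Loading, aligning and cropping time-lapse frame series and label maps.

Conventions used throughout the package:

* pixel coordinates are ``(row, col)``, origin at the top-left, 0-based;
* bounding boxes are half-open: ``(row0, col0, row1, col1)`` selects
  ``arr[row0:row1, col0:col1]``;
* frame order comes from lexicographic filename sort unless a manifest CSV
  (columns ``filename,hour``) overrides it;
* label maps are single-channel 8-bit PNGs with values
  0 = background, 1 = seed body, 2 = root, 3 = seedling.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate

BACKGROUND, SEED_BODY, ROOT, SEEDLING = 0, 1, 2, 3
VALID_LABELS = (BACKGROUND, SEED_BODY, ROOT, SEEDLING)

PAPER_COLORS = ("blue", "black", "dark_red", "light_blue")

#: seed-level germination phases, in developmental order
PHASES = ("IMB", "PRO", "RE", "SE")
PHASE_INDEX = {p: i for i, p in enumerate(PHASES)}

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


@dataclass
class Frame:
    """A single RGB frame of the time-lapse series."""

    index: int
    hour: float
    pixels: np.ndarray  # H x W x 3, uint8

    @property
    def shape(self):
        return self.pixels.shape[:2]


@dataclass
class ImageSeries:
    """Time-ordered RGB frames with acquisition metadata.

    ``interval_h`` is the time between consecutive frames in hours and
    ``scale_mm_per_px`` converts pixel distances to millimetres.
    """

    frames: list[Frame]
    interval_h: float
    scale_mm_per_px: float
    paper_color: str = "blue"
    shifts: list[tuple[float, float]] | None = None
    rotations: list[float] | None = None
    unaligned: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.interval_h <= 0:
            raise ValueError("interval_h must be positive")
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale_mm_per_px must be positive")
        if self.paper_color not in PAPER_COLORS:
            raise ValueError(f"unknown paper color {self.paper_color!r}")
        shapes = {f.shape for f in self.frames}
        if len(shapes) > 1:
            raise ValueError("shape mismatch: frames differ in size")

    def __len__(self):
        return len(self.frames)

    @property
    def shape(self):
        return self.frames[0].shape

    @property
    def hours(self):
        return np.array([f.hour for f in self.frames])


@dataclass
class LabelMap:
    """Per-frame segmentation raster with values in {0, 1, 2, 3}."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        bad = np.setdiff1d(np.unique(self.labels), VALID_LABELS)
        if bad.size:
            raise ValueError(f"invalid label value(s) {bad.tolist()}; "
                             f"expected subset of {list(VALID_LABELS)}")

    @property
    def shape(self):
        return self.labels.shape


@dataclass
class SeedROI:
    """One seed's region of interest and (optionally) per-frame phase calls."""

    seed_id: int
    box: tuple[int, int, int, int]  # row0, col0, row1, col1 (half-open)
    phase_by_frame: dict[int, str] | None = None
    confidence_by_frame: dict[int, float] | None = None

    def __post_init__(self):
        r0, c0, r1, c1 = self.box
        if not (r0 < r1 and c0 < c1):
            raise ValueError(f"degenerate ROI box {self.box}")

    @property
    def height(self):
        return self.box[2] - self.box[0]

    @property
    def width(self):
        return self.box[3] - self.box[1]

    def dilated(self, frac: float, bounds: tuple[int, int]) -> "SeedROI":
        """ROI grown by ``frac`` of its size on every side, clipped to frame."""
        r0, c0, r1, c1 = self.box
        dr = int(round(frac * (r1 - r0)))
        dc = int(round(frac * (c1 - c0)))
        H, W = bounds
        return SeedROI(self.seed_id,
                       (max(0, r0 - dr), max(0, c0 - dc),
                        min(H, r1 + dr), min(W, c1 + dc)))

    def contains(self, point) -> bool:
        r, c = point
        r0, c0, r1, c1 = self.box
        return r0 <= r < r1 and c0 <= c < c1


@dataclass
class MaskTriplet:
    """The three per-seed masks used everywhere downstream.

    ``seed_body``: seed without roots or seedling; ``full_plant``: seed plus
    roots plus seedling; ``seedling``: the emerging shoot.  Containment
    (seed_body, seedling within full_plant) is enforced by intersection.
    """

    seed_body: np.ndarray
    full_plant: np.ndarray
    seedling: np.ndarray

    def __post_init__(self):
        if not (self.seed_body.shape == self.full_plant.shape == self.seedling.shape):
            raise ValueError("mask shapes differ within triplet")
        self.seed_body = self.seed_body & self.full_plant
        self.seedling = self.seedling & self.full_plant

    @property
    def root(self) -> np.ndarray:
        """Root-only mask: plant minus seed body minus seedling."""
        return self.full_plant & ~self.seed_body & ~self.seedling


# ---------------------------------------------------------------------------
# loading


def load_series(directory, interval_h: float = 1.0,
                scale_mm_per_px: float = 0.05,
                paper_color: str = "blue",
                manifest: str | Path | None = None) -> ImageSeries:
    """Load an image directory as a time-ordered series.

    Frames are ordered by lexicographic filename sort; a ``manifest.csv``
    with columns ``filename,hour`` overrides both order and timing.
    """
    directory = Path(directory)
    if manifest is None:
        candidate = directory / "manifest.csv"
        manifest = candidate if candidate.exists() else None
    if manifest is not None:
        mf = pd.read_csv(manifest)
        names = list(mf["filename"])
        hours = list(mf["hour"].astype(float))
    else:
        names = sorted(p.name for p in directory.iterdir()
                       if p.suffix.lower() in _IMAGE_SUFFIXES
                       and not p.name.endswith("_labels.png"))
        hours = None

    if len(names) < 2:
        raise ValueError("no frames: need at least 2 image files for dynamics")

    frames = []
    for i, name in enumerate(names):
        px = np.asarray(iio.imread(directory / name))
        if px.ndim == 2:
            px = np.stack([px] * 3, axis=-1)
        px = px[..., :3].astype(np.uint8)
        hour = hours[i] if hours is not None else i * interval_h
        frames.append(Frame(index=i, hour=hour, pixels=px))

    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError("shape mismatch: frames differ in size")
    return ImageSeries(frames, interval_h, scale_mm_per_px, paper_color)


def write_label_map(path, label_map: LabelMap | np.ndarray) -> None:
    labels = label_map.labels if isinstance(label_map, LabelMap) else label_map
    iio.imwrite(Path(path), labels.astype(np.uint8))


def read_label_map(path) -> LabelMap:
    return LabelMap(np.asarray(iio.imread(Path(path))))


def load_label_maps(directory, n_frames: int) -> list[LabelMap]:
    """Read per-frame label maps named ``<frame>_labels.png`` (zero-padded)."""
    directory = Path(directory)
    out = []
    for i in range(n_frames):
        matches = sorted(directory.glob(f"*{i:04d}_labels.png"))
        if not matches:
            raise FileNotFoundError(f"missing label map for frame {i}")
        out.append(read_label_map(matches[0]))
    return out


def load_rois(csv_path) -> list[SeedROI]:
    df = pd.read_csv(csv_path)
    return [SeedROI(int(r.seed_id), (int(r.row0), int(r.col0),
                                     int(r.row1), int(r.col1)))
            for r in df.itertuples()]


def load_phases(csv_path, rois: list[SeedROI]) -> list[SeedROI]:
    """Attach externally supplied per-frame phase calls to ROIs.

    The CSV has columns ``seed_id, frame, phase, confidence`` (confidence
    optional).  ROIs are updated in place and returned.
    """
    df = pd.read_csv(csv_path)
    by_id = {r.seed_id: r for r in rois}
    for row in df.itertuples():
        roi = by_id.get(int(row.seed_id))
        if roi is None:
            continue
        if roi.phase_by_frame is None:
            roi.phase_by_frame = {}
        phase = str(row.phase)
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}")
        roi.phase_by_frame[int(row.frame)] = phase
        if hasattr(row, "confidence") and not pd.isna(row.confidence):
            if roi.confidence_by_frame is None:
                roi.confidence_by_frame = {}
            roi.confidence_by_frame[int(row.frame)] = float(row.confidence)
    return rois


def write_rois(csv_path, rois: list[SeedROI]) -> None:
    rows = [{"seed_id": r.seed_id, "row0": r.box[0], "col0": r.box[1],
             "row1": r.box[2], "col1": r.box[3]} for r in rois]
    pd.DataFrame(rows).to_csv(csv_path, index=False)


# ---------------------------------------------------------------------------
# alignment


def _to_gray(pixels: np.ndarray) -> np.ndarray:
    return pixels.astype(float).mean(axis=-1)


def _integer_shift(arr: np.ndarray, dr: int, dc: int, fill) -> np.ndarray:
    """Translate by whole pixels, filling uncovered area with ``fill``."""
    out = np.full_like(arr, fill)
    H, W = arr.shape[:2]
    src_r = slice(max(0, -dr), min(H, H - dr))
    dst_r = slice(max(0, dr), min(H, H + dr))
    src_c = slice(max(0, -dc), min(W, W - dc))
    dst_c = slice(max(0, dc), min(W, W + dc))
    out[dst_r, dst_c] = arr[src_r, src_c]
    return out


def _estimate_rotation(ref_gray, mov_gray, max_deg=2.0, step_deg=0.1):
    """Exhaustive search for the small rotation maximizing image agreement."""
    angles = np.arange(-max_deg, max_deg + step_deg / 2, step_deg)
    best_angle, best_err = 0.0, np.inf
    for a in angles:
        cand = rotate(mov_gray, a, preserve_range=True)
        err = float(np.mean((cand - ref_gray) ** 2))
        if err < best_err - 1e-12:
            best_angle, best_err = float(a), err
    return best_angle


def align_series(series: ImageSeries, mode: str = "translation",
                 label_maps: list[LabelMap] | None = None):
    """Register every frame to frame 0 by phase correlation.

    ``mode`` is one of ``translation``, ``translation+rotation`` or ``none``.
    Shifts larger than 10% of the frame size are treated as estimation
    failures: the frame is left untouched and flagged in ``unaligned``.
    Label maps, when given, receive the identical transform (nearest
    neighbour, background fill).

    Returns the aligned series, or ``(series, label_maps)`` when label maps
    are supplied.
    """
    if mode not in ("translation", "translation+rotation", "none"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    if len(series) < 2:
        raise ValueError("need at least 2 frames to align")
    if mode == "none":
        return series if label_maps is None else (series, label_maps)

    ref = _to_gray(series.frames[0].pixels)
    H, W = ref.shape
    max_dr, max_dc = 0.1 * H, 0.1 * W

    new_frames = [series.frames[0]]
    new_maps = [label_maps[0]] if label_maps is not None else None
    shifts = [(0.0, 0.0)]
    rotations = [0.0]
    unaligned = []

    for i, frame in enumerate(series.frames[1:], start=1):
        gray = _to_gray(frame.pixels)
        angle = 0.0
        if mode == "translation+rotation":
            angle = _estimate_rotation(ref, gray)
            if angle != 0.0:
                gray = rotate(gray, angle, preserve_range=True)
        shift, _, _ = phase_cross_correlation(ref, gray)
        # report the frame's content displacement relative to frame 0;
        # the registration correction is its negation
        dr, dc = -float(shift[0]), -float(shift[1])
        shifts.append((dr, dc))
        rotations.append(angle)
        if abs(dr) > max_dr or abs(dc) > max_dc:
            warnings.warn(f"frame {i}: estimated shift ({dr:.1f}, {dc:.1f}) "
                          "exceeds 10% of frame size; left unaligned")
            unaligned.append(i)
            new_frames.append(frame)
            if new_maps is not None:
                new_maps.append(label_maps[i])
            continue
        idr, idc = -int(round(dr)), -int(round(dc))
        px = frame.pixels
        if angle != 0.0:
            px = rotate(px, angle, preserve_range=True).astype(np.uint8)
        fill = np.median(px.reshape(-1, px.shape[-1]), axis=0).astype(np.uint8)
        aligned = np.stack([_integer_shift(px[..., k], idr, idc, fill[k])
                            for k in range(px.shape[-1])], axis=-1)
        new_frames.append(Frame(frame.index, frame.hour, aligned))
        if new_maps is not None:
            lab = label_maps[i].labels
            if angle != 0.0:
                lab = rotate(lab.astype(float), angle, order=0,
                             preserve_range=True).astype(lab.dtype)
            new_maps.append(LabelMap(_integer_shift(lab, idr, idc, BACKGROUND)))

    out = ImageSeries(new_frames, series.interval_h, series.scale_mm_per_px,
                      series.paper_color, shifts=shifts, rotations=rotations,
                      unaligned=unaligned)
    return out if new_maps is None else (out, new_maps)


# ---------------------------------------------------------------------------
# cropping and masks


def crop_roi(frame_or_map, roi: SeedROI) -> np.ndarray:
    """Crop a Frame, LabelMap or bare array to an ROI (half-open box)."""
    if isinstance(frame_or_map, Frame):
        arr = frame_or_map.pixels
    elif isinstance(frame_or_map, LabelMap):
        arr = frame_or_map.labels
    else:
        arr = np.asarray(frame_or_map)
    r0, c0, r1, c1 = roi.box
    H, W = arr.shape[:2]
    if r0 < 0 or c0 < 0 or r1 > H or c1 > W:
        raise ValueError(f"ROI box {roi.box} out of bounds for {H}x{W} raster")
    return arr[r0:r1, c0:c1]


def split_masks(label_map: LabelMap, roi: SeedROI) -> MaskTriplet:
    """Split a label map crop into the seed-body / full-plant / seedling masks."""
    labels = crop_roi(label_map, roi)
    return MaskTriplet(seed_body=labels == SEED_BODY,
                       full_plant=(labels == SEED_BODY) | (labels == ROOT)
                       | (labels == SEEDLING),
                       seedling=labels == SEEDLING)


# ---------------------------------------------------------------------------
# result tables


def write_tracks_jsonl(path, tracks) -> None:
    """One root per line: seed, root index, emergence frame, vertices, lengths."""
    with open(path, "w") as fh:
        for tr in tracks:
            rec = {
                "seed_id": tr.seed_id,
                "root_index": tr.root_index,
                "t_e": tr.t_e,
                "origin": [int(tr.origin[0]), int(tr.origin[1])],
                "vertices": [[int(f), int(p[0]), int(p[1])]
                             for f, p in tr.vertices],
                "cumulative_length_px": [float(v) for v in tr.cumlen_px],
            }
            fh.write(json.dumps(rec) + "\n")


def write_table(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.6g")
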