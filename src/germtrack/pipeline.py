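"""End-to-end orchestration: masks -> skeletons -> tracks -> traits -> vigor.

``process_lot`` works entirely on in-memory objects (an ImageSeries, its
label maps and seed ROIs) and returns the full set of result tables;
``run_from_config`` wraps it with file I/O for the command line.
"""

from __future__ import annotations

import json
import platform
import warnings
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import __version__
from .segmentation import SegConfig, classify_phase_from_masks, \
    segment_frame_classical
from .series_io import (ImageSeries, LabelMap, SeedROI, align_series,
                        crop_roi, load_label_maps, load_rois, load_series,
                        split_masks, write_table, write_tracks_jsonl)
from .tracking import (SeedFrameObservation, TrackConfig, TrackingGraph,
                       growth_rate_series, length_series_mm,
                       observe_seed_frame, track_seed)
from .traits import (change_rate_percent, chloroplast_time, coleoptile_time,
                     lot_phase_time, measure_seed_color,
                     measure_seed_morphology, time_to_length)
from .vigor import vigor_from_events


@dataclass
class RunConfig:
    """Flat run configuration; every field mirrors a CLI flag.

    Defaults follow the standard experimental protocol: hourly frames, the
    2 mm "germinated" and 10 mm "established" radicle thresholds, the 75%
    lot-phase rule, the 80-hour greenness reference, 60-degree tracking
    cone, and 15-seed standardised sampling.
    """

    frames_dir: str | None = None
    masks_dir: str | None = None
    rois_csv: str | None = None
    out_dir: str = "out"
    interval_h: float = 1.0
    scale_mm_per_px: float = 0.05
    paper_color: str = "blue"
    align: str = "none"                   # none | translation | translation+rotation
    segment: bool = False                 # classical fallback when no masks
    ref_hour: float = 80.0
    germinated_mm: float = 2.0
    established_mm: float = 10.0
    lot_threshold: float = 0.75
    n_sample: int | None = 15
    sample_seed: int = 0
    smooth_window: int = 5
    uniformity_coverage: float = 0.75
    track: TrackConfig = field(default_factory=TrackConfig)

    def validate(self):
        if self.scale_mm_per_px <= 0:
            raise ValueError("scale_mm_per_px must be positive")
        if self.interval_h <= 0:
            raise ValueError("interval_h must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        track = TrackConfig(**data.pop("track", {}))
        cfg = cls(**data, track=track)
        cfg.validate()
        return cfg


@dataclass
class LotResult:
    tracks: list[TrackingGraph]
    lengths: pd.DataFrame
    traits: pd.DataFrame
    events: pd.DataFrame
    lot: pd.DataFrame
    vigor: pd.DataFrame | None = None
    profiles: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)


def _own_seed_body(seed_body: np.ndarray, crop_box, base_box) -> np.ndarray:
    """The connected seed-body component belonging to this ROI's seed."""
    labels, n = ndimage.label(seed_body)
    if n <= 1:
        return seed_body
    # pick the component overlapping the base ROI the most
    r0, c0 = base_box[0] - crop_box[0], base_box[1] - crop_box[1]
    r1, c1 = base_box[2] - crop_box[0], base_box[3] - crop_box[1]
    counts = np.bincount(labels[r0:r1, c0:c1].ravel(), minlength=n + 1)
    counts[0] = 0
    if counts.max() == 0:
        return np.zeros_like(seed_body)
    return labels == int(np.argmax(counts))


def process_lot(series: ImageSeries | None,
                label_maps: list[LabelMap],
                rois: list[SeedROI],
                cfg: RunConfig,
                genotype_of_seed: dict[int, str] | None = None) -> LotResult:
    """Run tracking, trait extraction and (optionally) vigor scoring.

    ``series`` may be None when only mask-derived quantities are needed
    (colour traits and greening times are then skipped / censored).
    """
    cfg.validate()
    n_frames = len(label_maps)
    frame_shape = label_maps[0].shape
    hours = np.arange(n_frames) * cfg.interval_h
    scale = cfg.scale_mm_per_px
    caught: list[str] = []

    all_tracks: list[TrackingGraph] = []
    length_rows, trait_rows, event_rows = [], [], []
    seedling_masks_by_seed: dict[int, list] = {}
    phase_entry: dict[str, list] = {p: [] for p in ("PRO", "RE", "SE")}

    for roi in rois:
        crop = roi.dilated(cfg.track.roi_dilate_frac, frame_shape)
        base_local = (roi.box[0] - crop.box[0], roi.box[1] - crop.box[1],
                      roi.box[2] - crop.box[0], roi.box[3] - crop.box[1])

        observations: list[SeedFrameObservation] = []
        own_bodies, seedlings = [], []
        prev_crop = None
        for f in range(n_frames):
            lab_crop = crop_roi(label_maps[f], crop)
            if prev_crop is not None and np.array_equal(lab_crop, prev_crop):
                # nothing changed in this seed's crop: reuse the detections
                obs = replace(observations[-1], frame=f)
                observations.append(obs)
                own_bodies.append(own_bodies[-1])
                seedlings.append(seedlings[-1])
                continue
            prev_crop = lab_crop.copy()
            triplet = split_masks(label_maps[f], crop)
            own = _own_seed_body(triplet.seed_body, crop.box, roi.box)
            obs = observe_seed_frame(f, triplet, cfg.track, own_seed_body=own)
            observations.append(obs)
            own_bodies.append(own)
            # seedling events are per seed: ignore neighbours' seedlings
            # reaching into the dilated crop
            sl = np.zeros_like(triplet.seedling)
            b = base_local
            sl[b[0]:b[2], b[1]:b[3]] = triplet.seedling[b[0]:b[2], b[1]:b[3]]
            seedlings.append(sl)

        tracks = track_seed(roi.seed_id, observations, cfg.track,
                            roi_local_box=base_local)
        all_tracks.extend(tracks)
        seedling_masks_by_seed[roi.seed_id] = seedlings

        # --- per-frame lengths/rates ---------------------------------------
        radicle_lengths = np.zeros(n_frames)
        for tr in tracks:
            lengths = length_series_mm(tr, n_frames, scale)
            if tr.root_index == 1:
                radicle_lengths = lengths
            rates = growth_rate_series(lengths, cfg.interval_h,
                                       cfg.smooth_window)
            for f in range(n_frames):
                length_rows.append({
                    "seed_id": roi.seed_id, "root_index": tr.root_index,
                    "frame": f, "hour": hours[f],
                    "length_mm": lengths[f], "rate_mm_per_h": rates[f]})

        # --- per-frame morphology / colour ---------------------------------
        area = np.full(n_frames, np.nan)
        morphs = []
        for f in range(n_frames):
            if f > 0 and own_bodies[f] is own_bodies[f - 1]:
                m = dict(morphs[-1])  # unchanged mask: reuse measurements
            else:
                m = measure_seed_morphology(own_bodies[f], scale)
            morphs.append(m)
            area[f] = m["area_mm2"]
        for key in ("area_mm2", "length_mm", "width_mm", "perimeter_mm"):
            vals = np.array([m[key] for m in morphs])
            rates = change_rate_percent(vals) if np.isfinite(vals[0]) \
                else np.full(n_frames, np.nan)
            for f in range(n_frames):
                morphs[f][f"change_{key.split('_')[0]}_pct"] = rates[f]
        for f, m in enumerate(morphs):
            row = {"seed_id": roi.seed_id, "frame": f, "hour": hours[f], **m}
            if series is not None:
                color = measure_seed_color(
                    crop_roi(series.frames[f].pixels, crop), own_bodies[f])
                row["r_mean"], row["g_mean"], row["b_mean"] = (
                    color if color else (np.nan,) * 3)
            trait_rows.append(row)

        # --- events ---------------------------------------------------------
        radicle = next((t for t in tracks if t.root_index == 1), None)
        prot_h = None if radicle is None else float(radicle.t_e
                                                    * cfg.interval_h)
        t2 = time_to_length(radicle_lengths, hours, cfg.germinated_mm)
        t10 = time_to_length(radicle_lengths, hours, cfg.established_mm)
        col_h = coleoptile_time(seedlings, own_bodies, cfg.interval_h)
        event_rows.append({
            "seed_id": roi.seed_id,
            "genotype": (genotype_of_seed or {}).get(roi.seed_id, "lot"),
            "protrusion_h": prot_h, "t2mm_h": t2, "t10mm_h": t10,
            "coleoptile_h": col_h, "chloroplast_h": None})
        phase_entry["PRO"].append(prot_h)
        phase_entry["RE"].append(t2)
        phase_entry["SE"].append(col_h)

    # --- greening (needs RGB) ----------------------------------------------
    events = pd.DataFrame(event_rows)
    if series is not None:
        crops = {roi.seed_id: roi.dilated(cfg.track.roi_dilate_frac,
                                          frame_shape) for roi in rois}
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            green = chloroplast_time(series, seedling_masks_by_seed,
                                     rois=crops, ref_hour=cfg.ref_hour)
            caught.extend(str(x.message) for x in w)
        events["chloroplast_h"] = events["seed_id"].map(green)

    lengths = pd.DataFrame(length_rows)
    traits = pd.DataFrame(trait_rows)

    # --- lot-level phase times (75% rule, standardised sampling) ------------
    lot_rows = []
    for phase, entry in phase_entry.items():
        h = lot_phase_time(entry, hours, cfg.lot_threshold,
                           n_sample=cfg.n_sample, rng=cfg.sample_seed)
        lot_rows.append({"phase": phase, "hour": h,
                         "n_seeds": len(entry),
                         "threshold": cfg.lot_threshold,
                         "n_sample": cfg.n_sample,
                         "sample_seed": cfg.sample_seed})
    lot = pd.DataFrame(lot_rows)

    vig = prof = None
    genos = set(events["genotype"])
    if genotype_of_seed and len(genos) >= 2:
        vig = vigor_from_events(events,
                                coverage=cfg.uniformity_coverage,
                                bin_width=cfg.interval_h)
    if genotype_of_seed:
        from .vigor import build_profiles, profiles_table
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            profs = build_profiles(lengths, genotype_of_seed,
                                   cfg.interval_h, cfg.smooth_window)
            caught.extend(str(x.message) for x in w)
        prof = profiles_table(profs)

    return LotResult(all_tracks, lengths, traits, events, lot, vig, prof,
                     caught)


# ---------------------------------------------------------------------------
# file-level entry points


def write_outputs(out_dir, result: LotResult, cfg: RunConfig) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_table(out / "lengths.csv", result.lengths)
    write_table(out / "traits.csv", result.traits)
    write_table(out / "events.csv", result.events)
    write_table(out / "lot.csv", result.lot)
    if result.vigor is not None:
        write_table(out / "vigor.csv", result.vigor)
    if result.profiles is not None:
        write_table(out / "profiles.csv", result.profiles)
    write_tracks_jsonl(out / "tracks.jsonl", result.tracks)
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config": {k: (asdict(v) if isinstance(v, TrackConfig) else v)
                   for k, v in asdict(cfg).items()},
        "warnings": result.warnings,
        "n_tracks": len(result.tracks),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out


def run_from_config(cfg: RunConfig,
                    genotype_of_seed: dict[int, str] | None = None) -> Path:
    """Load inputs per the config, process the lot and write all outputs."""
    cfg.validate()
    if cfg.frames_dir is None and cfg.masks_dir is None:
        raise ValueError("need frames_dir and/or masks_dir")
    series = None
    if cfg.frames_dir is not None:
        series = load_series(cfg.frames_dir, cfg.interval_h,
                             cfg.scale_mm_per_px, cfg.paper_color)
    if cfg.masks_dir is not None:
        n = len(series) if series is not None else _count_maps(cfg.masks_dir)
        label_maps = load_label_maps(cfg.masks_dir, n)
    elif cfg.segment and series is not None:
        seg = SegConfig(paper_color=cfg.paper_color)
        label_maps = [segment_frame_classical(f, seg) for f in series.frames]
    else:
        raise ValueError("no masks available: supply masks_dir or enable "
                         "classical segmentation")
    if series is not None and cfg.align != "none":
        series, label_maps = align_series(series, cfg.align, label_maps)
    if cfg.rois_csv is None:
        raise ValueError("rois_csv is required")
    rois = load_rois(cfg.rois_csv)
    result = process_lot(series, label_maps, rois, cfg, genotype_of_seed)
    return write_outputs(cfg.out_dir, result, cfg)


def _count_maps(masks_dir) -> int:
    return len(list(Path(masks_dir).glob("*_labels.png")))
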