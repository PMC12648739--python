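"""Growth profiles, speed grouping, uniformity scoring and the vigor matrix.

Genotypes are compared on three axes:

* *speed* — either agglomerative (Ward) clustering of mean radicle-length
  curves, or affinity-propagation clustering of phase-entry-time summaries,
  in both cases ordered into quick / medium / slow;
* *uniformity* — a 0-1 score per genotype and phase: the modal-bin fraction
  of the event-hour distribution (its "peak") divided by the width of the
  central 75% of the data measured in bins; 1 means every uncensored seed
  reached the phase within one time bin;
* the *vigor matrix* — speed points (quick 3, medium 2, slow 1) multiplied
  by the uniformity score per phase, summed over the protrusion, radicle
  emergence and seedling phases, and the sums grouped into high / medium /
  low overall vigor classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import AffinityPropagation, AgglomerativeClustering

SPEED_LABELS = ("quick", "medium", "slow")
SPEED_POINTS = {"quick": 3, "medium": 2, "slow": 1}
VIGOR_CLASSES = ("high", "medium", "low")
PHASES_SCORED = ("PRO", "RE", "SE")


@dataclass
class GrowthProfile:
    genotype: str
    hours: np.ndarray
    mean_length_mm: np.ndarray
    mean_rate_mm_per_h: np.ndarray
    band_lo: np.ndarray                 # central-75% band (12.5th pct)
    band_hi: np.ndarray                 # 87.5th pct
    n_seeds: int
    n_censored: int
    low_support: bool = False


@dataclass
class UniformityScore:
    phase: str
    value: float | None
    n_total: int
    n_censored: int


# ---------------------------------------------------------------------------
# profiles and speed groups


def build_profiles(lengths: pd.DataFrame, genotype_of_seed: dict[int, str],
                   interval_h: float = 1.0,
                   smooth_window: int = 5) -> dict[str, GrowthProfile]:
    """Mean radicle-length and growth-rate curves per genotype.

    ``lengths`` follows the pipeline schema (seed_id, root_index, frame,
    hour, length_mm); only the radicle (root 1) enters the profile.  Seeds
    whose radicle never emerged are counted as censored and excluded from
    the means.
    """
    from .tracking import growth_rate_series

    radicle = lengths[lengths["root_index"] == 1]
    out = {}
    genos = sorted(set(genotype_of_seed.values()))
    for geno in genos:
        sids = [s for s, g in genotype_of_seed.items() if g == geno]
        curves, censored = [], 0
        hours = None
        for sid in sids:
            sub = radicle[radicle["seed_id"] == sid].sort_values("frame")
            if sub.empty or sub["length_mm"].max() <= 0:
                censored += 1
                continue
            curves.append(sub["length_mm"].to_numpy())
            hours = sub["hour"].to_numpy()
        low_support = len(curves) < 3
        if low_support:
            warnings.warn(f"genotype {geno}: only {len(curves)} uncensored "
                          "seeds; profile flagged low-support")
        if not curves:
            continue
        arr = np.vstack(curves)
        mean = arr.mean(axis=0)
        rate = growth_rate_series(mean, interval_h, smooth_window)
        out[geno] = GrowthProfile(
            genotype=geno, hours=hours, mean_length_mm=mean,
            mean_rate_mm_per_h=rate,
            band_lo=np.percentile(arr, 12.5, axis=0),
            band_hi=np.percentile(arr, 87.5, axis=0),
            n_seeds=len(sids), n_censored=censored,
            low_support=low_support)
    return out


def _order_speed_labels(cluster_of, order_stat):
    """Map cluster ids -> quick/medium/slow by ascending order statistic."""
    ids = sorted(set(cluster_of.values()),
                 key=lambda c: (order_stat[c], c))
    k = len(ids)
    if k == 1:
        label_of = {ids[0]: "medium"}
    elif k == 2:
        label_of = {ids[0]: "quick", ids[1]: "slow"}
    else:
        label_of = {cid: SPEED_LABELS[i] for i, cid in enumerate(ids)}
    return {g: label_of[c] for g, c in cluster_of.items()}


def cluster_speed_groups(profiles: dict[str, GrowthProfile], k: int = 3
                         ) -> dict[str, str]:
    """Ward clustering of length curves into quick / medium / slow.

    Clusters are labelled by ascending mean time-to-2-mm, so the quick
    group germinates earliest.  ``k=1`` returns a single "medium" group.
    """
    genos = sorted(profiles)
    if k > len(genos):
        raise ValueError(f"k={k} exceeds {len(genos)} genotypes")
    # resample to the common hour grid (intersection of horizons)
    n = min(len(profiles[g].mean_length_mm) for g in genos)
    X = np.vstack([profiles[g].mean_length_mm[:n] for g in genos])
    if k == 1:
        return {g: "medium" for g in genos}
    if len(set(map(tuple, X))) == 1:
        warnings.warn("all genotype profiles identical; degenerate grouping")
        return {g: "medium" for g in genos}
    model = AgglomerativeClustering(n_clusters=k, linkage="ward")
    labels = model.fit_predict(X)
    cluster_of = dict(zip(genos, labels))

    def t2mm(curve):
        idx = np.nonzero(curve >= 2.0)[0]
        return float(idx[0]) if idx.size else float(n)

    stat = {}
    for cid in set(labels):
        members = [g for g in genos if cluster_of[g] == cid]
        stat[cid] = float(np.mean([t2mm(profiles[g].mean_length_mm[:n])
                                   for g in members]))
    return _order_speed_labels(cluster_of, stat)


def _kmedoids_1d(values: np.ndarray, k: int, n_iter: int = 50):
    """Small deterministic PAM on a feature matrix (fallback clustering)."""
    X = np.atleast_2d(values)
    if X.shape[0] == 1:
        X = X.T
    n = X.shape[0]
    D = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    order = np.argsort(X[:, 0], kind="stable")
    medoids = list(order[np.linspace(0, n - 1, k).astype(int)])
    for _ in range(n_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new = []
        for j in range(k):
            members = np.nonzero(assign == j)[0]
            if members.size == 0:
                new.append(medoids[j])
                continue
            costs = D[np.ix_(members, members)].sum(axis=0)
            new.append(int(members[np.argmin(costs)]))
        if new == medoids:
            break
        medoids = new
    return np.argmin(D[:, medoids], axis=1)


def cluster_event_times(event_hours: dict[str, list[float | None]],
                        max_iter: int = 1000) -> dict[str, str]:
    """Affinity-propagation grouping of genotypes by phase-entry times.

    Each genotype is summarised by (median hour, IQR, censored fraction)
    over its seeds; clusters are ordered by median hour into quick / medium
    / slow, merging by median-hour adjacency when more than three emerge.
    Non-convergence falls back to a deterministic k-medoids with k=3.
    """
    genos = sorted(event_hours)
    if len(genos) < 2:
        return {g: "medium" for g in genos}
    feats = []
    for g in genos:
        vals = [h for h in event_hours[g] if h is not None]
        n = len(event_hours[g])
        if vals:
            feats.append([float(np.median(vals)),
                          float(np.subtract(*np.percentile(vals, [75, 25]))),
                          1.0 - len(vals) / n])
        else:
            feats.append([np.inf, 0.0, 1.0])
    X = np.array(feats)
    finite = np.isfinite(X[:, 0])
    X[~finite, 0] = (X[finite, 0].max() if finite.any() else 0.0) + 50.0

    if len(set(map(tuple, X))) == 1:
        return {g: "medium" for g in genos}

    ap = AffinityPropagation(damping=0.5, max_iter=max_iter, random_state=0)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        labels = ap.fit_predict(X)
        failed = any("did not converge" in str(w.message).lower()
                     for w in caught) or len(set(labels)) == len(genos) == 0
    if failed or ap.cluster_centers_indices_ is None or len(
            ap.cluster_centers_indices_) == 0:
        warnings.warn("affinity propagation did not converge; "
                      "falling back to k-medoids (k=3)")
        labels = _kmedoids_1d(X, min(3, len(genos)))

    cluster_of = dict(zip(genos, (int(v) for v in labels)))
    med = {}
    for cid in set(cluster_of.values()):
        members = [g for g in genos if cluster_of[g] == cid]
        med[cid] = float(np.median([X[genos.index(g), 0] for g in members]))

    # merge to at most 3 clusters by median-hour adjacency
    while len(med) > 3:
        cids = sorted(med, key=lambda c: med[c])
        gaps = [(med[cids[i + 1]] - med[cids[i]], i)
                for i in range(len(cids) - 1)]
        _, i = min(gaps)
        keep, drop = cids[i], cids[i + 1]
        for g in genos:
            if cluster_of[g] == drop:
                cluster_of[g] = keep
        members = [g for g in genos if cluster_of[g] == keep]
        med[keep] = float(np.median([X[genos.index(g), 0] for g in members]))
        del med[drop]

    return _order_speed_labels(cluster_of, med)


# ---------------------------------------------------------------------------
# uniformity


def uniformity_score(event_hours: list[float | None], phase: str = "",
                     coverage: float = 0.75,
                     bin_width: float = 1.0) -> UniformityScore:
    """Peak-to-span uniformity of an event-time distribution, in [0, 1].

    Over the uncensored hours, ``peak`` is the fraction of seeds in the
    modal histogram bin and ``span`` the central-coverage width (12.5th to
    87.5th percentile at the default 75% coverage) measured in bins, floored
    at one bin.  The score is ``min(1, peak / span)``: it is 1 exactly when
    every uncensored event falls in a single bin and decreases as the
    distribution spreads.  Censored seeds are counted and reported but do
    not enter the ratio.
    """
    vals = np.array([h for h in event_hours if h is not None], float)
    n_cens = sum(1 for h in event_hours if h is None)
    if vals.size == 0:
        return UniformityScore(phase, None, len(event_hours), n_cens)
    # extend one bin past the max so the largest value sits inside its own
    # half-open bin rather than being absorbed into the previous one
    edges = np.arange(np.floor(vals.min() / bin_width) * bin_width,
                      vals.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(vals, bins=edges)
    peak = counts.max() / vals.size
    lo, hi = (1 - coverage) / 2 * 100, (1 + coverage) / 2 * 100
    span_bins = max(1.0, (np.percentile(vals, hi) - np.percentile(vals, lo))
                    / bin_width)
    value = float(min(1.0, peak / span_bins))
    return UniformityScore(phase, value, len(event_hours), n_cens)


# ---------------------------------------------------------------------------
# the vigor matrix


def _overall_classes(scores: dict[str, float]) -> dict[str, str]:
    """Partition overall scores into high / medium / low.

    Affinity propagation on the log-scale scores, merged (or completed via
    k-medoids when fewer than three clusters emerge) to exactly three
    classes ordered by descending score.  The peak-over-span uniformity
    construction makes scores span orders of magnitude, so the log scale is
    what separates the tiers.
    """
    genos = sorted(scores)
    vals = np.array([[np.log10(max(scores[g], 0.0) + 1e-2)] for g in genos])
    if len(genos) < 3 or len(set(vals[:, 0])) < 3:
        order = sorted(genos, key=lambda g: -scores[g])
        out = {}
        for i, g in enumerate(order):
            out[g] = VIGOR_CLASSES[min(i, 2)] if len(genos) >= 3 else "medium"
        return out
    ap = AffinityPropagation(damping=0.5, max_iter=1000, random_state=0)
    labels = ap.fit_predict(vals)
    k = len(set(labels))
    if k < 3 or ap.cluster_centers_indices_ is None:
        labels = _kmedoids_1d(vals, 3)
        k = len(set(labels))
    cluster_of = dict(zip(genos, (int(v) for v in labels)))
    lscore = dict(zip(genos, vals[:, 0]))
    mean = {cid: float(np.mean([lscore[g] for g in genos
                                if cluster_of[g] == cid]))
            for cid in set(cluster_of.values())}
    while len(mean) > 3:
        cids = sorted(mean, key=lambda c: mean[c])
        gaps = [(mean[cids[i + 1]] - mean[cids[i]], i)
                for i in range(len(cids) - 1)]
        _, i = min(gaps)
        keep, drop = cids[i], cids[i + 1]
        for g in genos:
            if cluster_of[g] == drop:
                cluster_of[g] = keep
        mean[keep] = float(np.mean([lscore[g] for g in genos
                                    if cluster_of[g] == keep]))
        del mean[drop]
    ordered = sorted(mean, key=lambda c: -mean[c])
    label_of = {cid: VIGOR_CLASSES[i] for i, cid in enumerate(ordered)}
    return {g: label_of[c] for g, c in cluster_of.items()}


def vigor_matrix(speed_groups: dict[str, dict[str, str]],
                 uniformity: dict[str, dict[str, UniformityScore | float]]
                 ) -> pd.DataFrame:
    """Assemble the speed x uniformity vigor matrix.

    ``speed_groups[genotype][phase]`` is quick/medium/slow and
    ``uniformity[genotype][phase]`` the matching score.  Phase score =
    points x uniformity; the overall score sums the three phases (0..9) and
    overall classes partition the genotypes into high / medium / low vigor.
    A missing phase contributes 0 and is flagged.
    """
    genos = sorted(speed_groups)
    rows = []
    overall = {}
    for g in genos:
        total = 0.0
        for phase in PHASES_SCORED:
            group = speed_groups[g].get(phase)
            u = uniformity.get(g, {}).get(phase)
            if isinstance(u, UniformityScore):
                n_cens = u.n_censored
                u = u.value
            else:
                n_cens = 0
            missing = group is None or u is None
            points = SPEED_POINTS.get(group, 0)
            score = 0.0 if missing else points * u
            total += score
            rows.append({"genotype": g, "phase": phase,
                         "group": group or "missing",
                         "points": points,
                         "uniformity": np.nan if u is None else u,
                         "phase_score": score,
                         "n_censored": n_cens,
                         "flagged": missing})
        overall[g] = total
    classes = _overall_classes(overall)
    df = pd.DataFrame(rows)
    df["overall_score"] = df["genotype"].map(overall)
    df["overall_class"] = df["genotype"].map(classes)
    return df


def vigor_from_events(events: pd.DataFrame, coverage: float = 0.75,
                      bin_width: float = 1.0) -> pd.DataFrame:
    """Vigor matrix straight from a per-seed events table.

    The table needs ``genotype``, ``protrusion_h`` and ``t2mm_h`` columns;
    the seedling phase uses ``chloroplast_h`` when any greening time was
    observed, falling back to ``coleoptile_h``.  Missing hours are treated
    as censored seeds.
    """
    if events.empty:
        raise ValueError("empty events table")
    required = {"genotype", "protrusion_h", "t2mm_h"}
    missing = required - set(events.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    se_col = "coleoptile_h"
    if "chloroplast_h" in events.columns and \
            events["chloroplast_h"].notna().any():
        se_col = "chloroplast_h"
    phase_col = {"PRO": "protrusion_h", "RE": "t2mm_h", "SE": se_col}

    genos = sorted(set(events["genotype"]))
    speed_groups: dict[str, dict[str, str]] = {g: {} for g in genos}
    uniformity: dict[str, dict[str, UniformityScore]] = {g: {} for g in genos}
    for phase, col in phase_col.items():
        hours_by_geno = {}
        for g in genos:
            vals = events.loc[events["genotype"] == g, col]
            hours_by_geno[g] = [None if pd.isna(v) else float(v)
                                for v in vals]
        groups = cluster_event_times(hours_by_geno)
        for g in genos:
            speed_groups[g][phase] = groups[g]
            uniformity[g][phase] = uniformity_score(
                hours_by_geno[g], phase, coverage, bin_width)
    return vigor_matrix(speed_groups, uniformity)


def profiles_table(profiles: dict[str, GrowthProfile]) -> pd.DataFrame:
    rows = []
    for g in sorted(profiles):
        p = profiles[g]
        for i, h in enumerate(p.hours):
            rows.append({"genotype": g, "hour": float(h),
                         "mean_length_mm": float(p.mean_length_mm[i]),
                         "mean_rate_mm_per_h": float(p.mean_rate_mm_per_h[i]),
                         "band_lo": float(p.band_lo[i]),
                         "band_hi": float(p.band_hi[i])})
    return pd.DataFrame(rows)


def plot_event_distributions(event_hours: dict[str, list[float | None]],
                             path=None):
    """Quick strip/histogram inspection plot of phase-entry hours."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    genos = sorted(event_hours)
    fig, ax = plt.subplots(figsize=(8, 0.5 + 0.4 * len(genos)))
    for i, g in enumerate(genos):
        vals = [h for h in event_hours[g] if h is not None]
        ax.plot(vals, np.full(len(vals), i), "o", ms=3, alpha=0.6)
    ax.set_yticks(range(len(genos)), genos)
    ax.set_xlabel("hour")
    if path:
        fig.savefig(path, dpi=100)
        plt.close(fig)
        return None
    return fig
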