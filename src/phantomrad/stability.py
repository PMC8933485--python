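"""Feature stability and discriminative power over a grouped study design.

The comparison statistic W is the absolute value of the tie-corrected
normal-approximation standardisation of the Mann-Whitney rank-sum
statistic (average ranks for ties, no continuity correction).  A pairwise
comparison of two samples is

* *stable* when W < 1 (the repetitions are indistinguishable), and
* *discriminative* when W > 1 (the samples separate).

Stability pools per-ROI group-pair comparisons; discriminative power pools
per-group tissue-class-pair comparisons.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from phantomrad.radiomics.manifest import CANONICAL_NAMES

#: Threshold convention: a comparison is "same distribution" iff W < 1.
W_THRESHOLD = 1.0


@dataclass
class WilcoxonResult:
    """Standardised rank-sum magnitude for one two-sample comparison."""

    W: float
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.W) or self.W < 0:
            raise ValueError("W must be finite and nonnegative")


def wilcoxon_W(sample_a, sample_b) -> WilcoxonResult:
    """|z| of the tie-corrected Mann-Whitney normal approximation.

    Identical pooled values (zero rank variance) give W = 0.
    """
    a = np.asarray(sample_a, dtype=np.float64).ravel()
    b = np.asarray(sample_b, dtype=np.float64).ravel()
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError(f"both samples need >= 2 values, got {n1} and {n2}")
    n = n1 + n2
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # average ranks for ties
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return WilcoxonResult(W=0.0, n_a=n1, n_b=n2)
    z = (u1 - n1 * n2 / 2.0) / math.sqrt(var_u)
    return WilcoxonResult(W=abs(z), n_a=n1, n_b=n2)


@dataclass
class StudyDesign:
    """Grouped acquisition design (group id, algorithm, projection count)."""

    groups: list[tuple[str, str, int]]  # (group id, algorithm, n_projections)
    noise_A: float = 1e-4
    repetitions: int = 10
    base_seed: int = 0
    #: optional per-group noise override (group id -> A), e.g. for the
    #: multi-center preset where noise varies across groups
    group_noise: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ValueError("a study design needs at least 2 groups")
        if self.repetitions < 2:
            raise ValueError("a study design needs at least 2 repetitions per group")
        ids = [g[0] for g in self.groups]
        if len(set(ids)) != len(ids):
            raise ValueError("group ids must be unique")

    @property
    def group_ids(self) -> list[str]:
        return [g[0] for g in self.groups]

    def seeds_for_group(self, group_index: int) -> list[int]:
        # repetitions within a group differ only by the noise seed
        return [self.base_seed + rep for rep in range(self.repetitions)]


@dataclass
class StabilityReport:
    """Per-feature stability and discriminative-power percentages."""

    stability: pd.Series  # % in [0, 100], indexed by feature
    discriminative: pd.Series
    stability_breakdown: pd.DataFrame  # feature x ROI
    discriminative_breakdown: pd.DataFrame  # feature x group
    n_stability_comparisons: int = 0
    n_discriminative_comparisons: int = 0
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for s in (self.stability, self.discriminative):
            vals = s.to_numpy(dtype=float)
            if np.any((vals < 0) | (vals > 100)):
                raise ValueError("percentages must lie in [0, 100]")

    def ranking(self, axis: str) -> list[str]:
        return rank_features(self, axis)


def _feature_columns(table: pd.DataFrame, features) -> list[str]:
    if features is None:
        features = [c for c in table.columns if c in CANONICAL_NAMES]
    missing = [f for f in features if f not in table.columns]
    if missing:
        raise ValueError(f"features missing from table: {missing[:5]}...")
    return list(features)


def stability_percentage(
    table: pd.DataFrame,
    features: list[str] | None = None,
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Intra-class stability: for every feature and ROI, compare all group
    pairs; a comparison succeeds iff W < 1.  The percentage is the fraction
    of successful comparisons pooled over all ROIs and group pairs.

    ``table`` needs columns ``group``, ``roi`` and the feature columns,
    one row per (group, repetition, ROI).
    """
    features = _feature_columns(table, features)
    rois = sorted(table["roi"].unique())
    groups = sorted(table["group"].unique())
    if len(groups) < 2:
        raise ValueError("stability needs at least 2 groups")

    success = {f: 0 for f in features}
    per_roi = {f: {r: [] for r in rois} for f in features}
    total = 0
    excluded: list[str] = []
    for roi in rois:
        sub = table[table["roi"] == roi]
        samples = {}
        for g in groups:
            vals = sub[sub["group"] == g]
            if len(vals) < 2:
                excluded.append(f"roi={roi} group={g}: {len(vals)} repetitions")
                continue
            samples[g] = vals
        for ga, gb in itertools.combinations(sorted(samples), 2):
            total += 1
            for f in features:
                w = wilcoxon_W(samples[ga][f], samples[gb][f]).W
                ok = w < W_THRESHOLD
                success[f] += ok
                per_roi[f][roi].append(ok)
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} incomplete cells: {excluded[:3]}",
            stacklevel=2,
        )
    if total == 0:
        raise ValueError("no valid group pairs to compare")
    pct = pd.Series(
        {f: 100.0 * success[f] / total for f in features}, name="stability"
    )
    breakdown = pd.DataFrame(
        {
            f: {
                r: (100.0 * np.mean(v) if v else np.nan)
                for r, v in per_roi[f].items()
            }
            for f in features
        }
    ).T
    return pct, breakdown, total


def discriminative_percentage(
    table: pd.DataFrame,
    features: list[str] | None = None,
) -> tuple[pd.Series, pd.DataFrame, int]:
    """Inter-class discriminative power: for every feature and group,
    compare all tissue-class pairs; a comparison succeeds iff W > 1.

    Values of a class within a group pool the class's ROIs across
    repetitions.
    """
    features = _feature_columns(table, features)
    groups = sorted(table["group"].unique())
    classes = sorted(table["tissue_class"].unique())
    if len(classes) < 2:
        raise ValueError("discriminative power needs at least 2 tissue classes")

    success = {f: 0 for f in features}
    per_group = {f: {g: [] for g in groups} for f in features}
    total = 0
    excluded: list[str] = []
    for g in groups:
        sub = table[table["group"] == g]
        samples = {}
        for cls in classes:
            vals = sub[sub["tissue_class"] == cls]
            if len(vals) < 2:
                excluded.append(f"group={g} class={cls}: {len(vals)} values")
                continue
            samples[cls] = vals
        for ca, cb in itertools.combinations(sorted(samples), 2):
            total += 1
            for f in features:
                w = wilcoxon_W(samples[ca][f], samples[cb][f]).W
                ok = w > W_THRESHOLD
                success[f] += ok
                per_group[f][g].append(ok)
    if excluded:
        warnings.warn(
            f"excluded {len(excluded)} incomplete cells: {excluded[:3]}",
            stacklevel=2,
        )
    if total == 0:
        raise ValueError("no valid class pairs to compare")
    pct = pd.Series(
        {f: 100.0 * success[f] / total for f in features}, name="discriminative"
    )
    breakdown = pd.DataFrame(
        {
            f: {
                g: (100.0 * np.mean(v) if v else np.nan)
                for g, v in per_group[f].items()
            }
            for f in features
        }
    ).T
    return pct, breakdown, total


def compute_stability_report(
    table: pd.DataFrame, features: list[str] | None = None
) -> StabilityReport:
    """Full stability + discriminative-power report for a feature table."""
    stab, stab_break, n_stab = stability_percentage(table, features)
    disc, disc_break, n_disc = discriminative_percentage(table, features)
    return StabilityReport(
        stability=stab,
        discriminative=disc,
        stability_breakdown=stab_break,
        discriminative_breakdown=disc_break,
        n_stability_comparisons=n_stab,
        n_discriminative_comparisons=n_disc,
    )


def rank_features(report: StabilityReport, axis: str) -> list[str]:
    """Features sorted descending by percentage on the given axis
    (``stability`` or ``discriminative``); ties break by canonical
    feature-name order."""
    if axis == "stability":
        s = report.stability
    elif axis == "discriminative":
        s = report.discriminative
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return sorted(s.index, key=lambda f: (-s[f], f))


def topk_count(fraction: float, n_features: int) -> int:
    """Top-group size at an ascending fraction, rounded half-up
    (10% of 86 -> 9)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return max(1, math.floor(fraction * n_features + 0.5))


def topk_overlap(
    rank_a: list[str],
    rank_b: list[str],
    fractions=None,
) -> pd.DataFrame:
    """Overlap curve between two rankings of the same feature universe.

    For each fraction f, the top k(f) features of each ranking are
    intersected; the overlap percentage is |intersection| / k x 100.  The
    random-expectation baseline is f x 100.
    """
    if sorted(rank_a) != sorted(rank_b):
        raise ValueError("rankings must cover the same feature universe")
    if fractions is None:
        fractions = np.arange(0.05, 1.0001, 0.05)
    n = len(rank_a)
    rows = []
    for f in fractions:
        k = topk_count(float(f), n)
        shared = len(set(rank_a[:k]) & set(rank_b[:k]))
        rows.append(
            {
                "fraction": float(f),
                "k": k,
                "overlap_pct": 100.0 * shared / k,
                "random_baseline_pct": 100.0 * float(f),
            }
        )
    return pd.DataFrame(rows)
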