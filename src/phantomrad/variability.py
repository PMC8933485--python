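"""PCA-based comparison of feature variability between acquisition sets.

A 2-component PCA is fitted on the reference feature table (features
z-scored by reference mean/sd; constant features dropped); any other table
is projected into the same plane.  Per-ROI comparison reports centroid
offsets, component-wise spread ratios, and whether the test centroid lies
within the reference 95% covariance ellipse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from phantomrad.radiomics.manifest import CANONICAL_NAMES

#: 95% quantile of chi-squared with 2 degrees of freedom.
_CHI2_95_2D = float(chi2.ppf(0.95, df=2))


@dataclass
class PCATransform:
    """Reference standardisation + first-two-component loadings."""

    feature_names: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray  # (2, n_features), orthonormal rows
    explained_variance_ratio: np.ndarray  # (2,)
    dropped: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(2), atol=1e-8):
            raise ValueError("loadings must be orthonormal")
        if np.any(self.sds <= 0):
            raise ValueError("retained features must have positive sd")


def _feature_matrix(table: pd.DataFrame, names) -> np.ndarray:
    missing = [f for f in names if f not in table.columns]
    if missing:
        raise ValueError(f"unknown features absent from table: {missing[:5]}")
    return table[list(names)].to_numpy(dtype=np.float64)


def fit_pca(
    reference: pd.DataFrame,
    features: list[str] | None = None,
    standardize: bool = True,
) -> PCATransform:
    """Fit the 2-component PCA on the reference table.

    Deterministic up to sign; the sign of each loading is fixed by making
    its largest-magnitude element positive.
    """
    if features is None:
        features = [c for c in reference.columns if c in CANONICAL_NAMES]
    if len(reference) < 3:
        raise ValueError("PCA needs at least 3 reference rows")
    X = _feature_matrix(reference, features)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)

    keep = sds > 1e-12
    dropped = [f for f, k in zip(features, keep) if not k]
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant features: {dropped[:5]}",
            stacklevel=2,
        )
    features = [f for f, k in zip(features, keep) if k]
    if len(features) < 2:
        raise ValueError("PCA needs at least 2 non-constant features")
    X = X[:, keep]
    means = means[keep]
    sds = sds[keep]

    Z = (X - means) / sds if standardize else X - means
    if not standardize:
        sds = np.ones_like(sds)

    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[:2]
    # sign convention for cross-platform reproducibility
    for k in range(2):
        idx = np.argmax(np.abs(loadings[k]))
        if loadings[k, idx] < 0:
            loadings[k] = -loadings[k]
    var = s**2
    evr = var[:2] / var.sum() if var.sum() > 0 else np.zeros(2)
    return PCATransform(
        feature_names=features,
        means=means,
        sds=sds,
        loadings=loadings,
        explained_variance_ratio=evr,
        dropped=dropped,
    )


def project(table: pd.DataFrame, transform: PCATransform) -> np.ndarray:
    """(n, 2) coordinates of each row in the fitted component plane."""
    X = _feature_matrix(table, transform.feature_names)
    Z = (X - transform.means) / transform.sds
    return Z @ transform.loadings.T


def compare_variability(
    ref_coords: np.ndarray,
    test_coords: np.ndarray,
    ref_labels,
    test_labels,
) -> dict[str, dict]:
    """Per-ROI comparison of projected clouds.

    Returns, per label present in both sets: the centroid offset and its
    norm, component-wise spread (sd) ratios test/ref, and whether the test
    centroid lies inside the reference 95% covariance ellipse.
    """
    ref_labels = np.asarray(ref_labels)
    test_labels = np.asarray(test_labels)
    ref_coords = np.asarray(ref_coords, dtype=np.float64)
    test_coords = np.asarray(test_coords, dtype=np.float64)
    report: dict[str, dict] = {}
    ref_set = set(ref_labels.tolist())
    test_set = set(test_labels.tolist())
    for lbl in sorted(ref_set ^ test_set):
        warnings.warn(f"ROI {lbl!r} absent from one set; excluded", stacklevel=2)
    for lbl in sorted(ref_set & test_set):
        r = ref_coords[ref_labels == lbl]
        t = test_coords[test_labels == lbl]
        offset = t.mean(axis=0) - r.mean(axis=0)
        ref_sd = r.std(axis=0, ddof=1) if len(r) > 1 else np.zeros(2)
        test_sd = t.std(axis=0, ddof=1) if len(t) > 1 else np.zeros(2)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(ref_sd > 0, test_sd / ref_sd, np.nan)
        inside = None
        if len(r) > 2:
            cov = np.cov(r.T)
            try:
                d2 = float(offset @ np.linalg.solve(cov, offset))
                inside = bool(d2 <= _CHI2_95_2D)
            except np.linalg.LinAlgError:
                inside = None
        report[str(lbl)] = {
            "centroid_offset": offset.tolist(),
            "centroid_distance": float(np.linalg.norm(offset)),
            "spread_ratio": ratio.tolist(),
            "inside_95_ellipse": inside,
            "n_ref": int(len(r)),
            "n_test": int(len(t)),
        }
    return report


def plot_projection(
    ref_coords: np.ndarray,
    test_coords: np.ndarray,
    ref_labels,
    test_labels,
    path,
) -> None:
    """Optional scatter plot of both projected sets (PNG/SVG by suffix)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ref_labels = np.asarray(ref_labels)
    test_labels = np.asarray(test_labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for lbl in sorted(set(ref_labels.tolist())):
        pts = np.asarray(ref_coords)[ref_labels == lbl]
        ax.scatter(pts[:, 0], pts[:, 1], c="k", marker="o", s=12, alpha=0.5)
    for lbl in sorted(set(test_labels.tolist())):
        pts = np.asarray(test_coords)[test_labels == lbl]
        ax.scatter(pts[:, 0], pts[:, 1], marker="x", s=14, label=str(lbl))
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
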