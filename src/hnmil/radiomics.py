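"""Handcrafted radiomics: IBSI-style features, selection chain, logistic model.

A documented subset of IBSI feature families is computed from the GTVp on the
base image: morphology (volume, face-area surface, sphericity, maximum 3D
diameter), first-order statistics (fixed-bin-width histogram entropy among
them), and gray-level co-occurrence (GLCM) texture aggregated over the thirteen
unique 3D direction offsets at distance 1.

The selection chain is: near-zero-variance filtering, z-score standardization,
average-linkage hierarchical clustering on 1 - |Spearman rho| cut at 0.20,
cluster representatives by highest mean absolute Spearman correlation to
co-members, minimum-redundancy-maximum-relevance ranking (difference form:
relevance = |point-biserial with the label|, redundancy = mean |Spearman| with
already-selected features), keeping k = floor(n_minority / 10), minimum 1.
Selected features feed an unpenalized logistic model on frozen training
z-scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import squareform
from sklearn.linear_model import LogisticRegression

ENTROPY_BIN_WIDTH_HU = 25.0
GLCM_DEFAULT_BINS = 32
VARIANCE_EPS = 1e-12

#: the 13 unique 3D direction offsets at Chebyshev distance 1
GLCM_OFFSETS_3D = [
    off
    for off in itertools.product((-1, 0, 1), repeat=3)
    if off > (0, 0, 0)
]


@dataclass
class SelectionTrace:
    variance_dropped: list
    clusters: list  # list of (member names, representative name)
    mrmr_order: list
    k_selected: int
    selected: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------


def compute_shape_features(mask: np.ndarray, spacing: Sequence[float]) -> dict:
    """Volume, face-area surface, sphericity, maximum 3D diameter (mm units)."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    sx, sy, sz = (float(s) for s in spacing)
    voxel_volume = sx * sy * sz
    volume = float(mask.sum() * voxel_volume)

    # exposed voxel faces per axis; face area = product of the other spacings
    area = 0.0
    face_areas = (sy * sz, sx * sz, sx * sy)
    for axis, fa in enumerate(face_areas):
        pad = np.pad(mask, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        diff = np.diff(pad.astype(np.int8), axis=axis)
        area += float(np.abs(diff).sum()) * fa

    sphericity = float((36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area)

    eroded = ndimage.binary_erosion(mask)
    boundary = mask & ~eroded
    pts = np.argwhere(boundary if boundary.any() else mask) * np.array([sx, sy, sz])
    if len(pts) == 1:
        max_diam = 0.0  # single voxel, center-to-center convention
    else:
        try:
            hull = pts[ConvexHull(pts).vertices]
        except (QhullError, ValueError):  # degenerate (coplanar/collinear) masks
            hull = pts
        d2 = ((hull[:, None, :] - hull[None, :, :]) ** 2).sum(axis=-1)
        max_diam = float(np.sqrt(d2.max()))
    return {
        "shape_volume_mm3": volume,
        "shape_surface_area_mm2": float(area),
        "shape_sphericity": sphericity,
        "shape_max_diameter_mm": max_diam,
    }


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------


def compute_firstorder_features(
    ct: np.ndarray, mask: np.ndarray, bin_width: float = ENTROPY_BIN_WIDTH_HU
) -> dict:
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = np.asarray(ct, dtype=float)[mask]
    mean = float(x.mean())
    var = float(x.var())
    if var < VARIANCE_EPS:
        skew, kurt = 0.0, 0.0  # degenerate distribution convention
    else:
        skew = float(sps.skew(x))
        kurt = float(sps.kurtosis(x))  # excess kurtosis
    # fixed-bin-width histogram entropy, edges anchored at multiples of bin_width
    lo = np.floor(x.min() / bin_width) * bin_width
    nbins = max(int(np.ceil((x.max() - lo) / bin_width)), 1)
    counts, _ = np.histogram(x, bins=nbins, range=(lo, lo + nbins * bin_width))
    p = counts[counts > 0] / x.size
    entropy = float(-(p * np.log2(p)).sum())
    return {
        "fo_mean": mean,
        "fo_variance": var,
        "fo_skewness": skew,
        "fo_kurtosis": kurt,
        "fo_energy": float((x**2).sum()),
        "fo_entropy": entropy,
        "fo_p10": float(np.percentile(x, 10)),
        "fo_p90": float(np.percentile(x, 90)),
        "fo_min": float(x.min()),
        "fo_max": float(x.max()),
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------


def glcm_matrix(
    levels: np.ndarray,
    mask: np.ndarray,
    n_levels: int,
    offsets: Sequence[tuple[int, int, int]],
) -> np.ndarray:
    """Symmetric normalized co-occurrence matrix; out-of-mask neighbors skipped."""
    P = np.zeros((n_levels, n_levels), dtype=float)
    for off in offsets:
        src = [slice(max(-o, 0), levels.shape[a] - max(o, 0)) for a, o in enumerate(off)]
        dst = [slice(max(o, 0), levels.shape[a] - max(-o, 0)) for a, o in enumerate(off)]
        valid = mask[tuple(src)] & mask[tuple(dst)]
        a = levels[tuple(src)][valid]
        b = levels[tuple(dst)][valid]
        np.add.at(P, (a, b), 1.0)
        np.add.at(P, (b, a), 1.0)
    total = P.sum()
    if total > 0:
        P /= total
    return P


def _glcm_stats(P: np.ndarray) -> dict:
    n = P.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    contrast = float((P * (i - j) ** 2).sum())
    dissimilarity = float((P * np.abs(i - j)).sum())
    homogeneity = float((P / (1.0 + (i - j) ** 2)).sum())
    nz = P[P > 0]
    joint_entropy = float(-(nz * np.log2(nz)).sum()) if nz.size else 0.0
    px = P.sum(axis=1)
    mu = float((np.arange(n) * px).sum())
    sigma2 = float(((np.arange(n) - mu) ** 2 * px).sum())
    if sigma2 < VARIANCE_EPS:
        correlation = 1.0  # single-level region convention
    else:
        correlation = float((P * (i - mu) * (j - mu)).sum() / sigma2)
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": correlation,
        "glcm_joint_entropy": joint_entropy,
        "glcm_dissimilarity": dissimilarity,
        "glcm_homogeneity": homogeneity,
    }


def compute_glcm_features(
    ct: np.ndarray,
    mask: np.ndarray,
    bins: int = GLCM_DEFAULT_BINS,
    offsets: Optional[Sequence[tuple[int, int, int]]] = None,
) -> dict:
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty mask")
    x = np.asarray(ct, dtype=float)
    inside = x[mask]
    lo, hi = inside.min(), inside.max()
    if hi - lo < VARIANCE_EPS:
        levels = np.zeros_like(x, dtype=np.intp)
        n_levels = 1
    else:
        edges = np.linspace(lo, hi, bins + 1)
        levels = np.clip(np.digitize(x, edges[1:-1]), 0, bins - 1)
        n_levels = bins
    offs = GLCM_OFFSETS_3D if offsets is None else list(offsets)
    P = glcm_matrix(levels, mask, n_levels, offs)
    return _glcm_stats(P)


def extract_feature_table(
    patients: Sequence, glcm_bins: int = GLCM_DEFAULT_BINS
) -> pd.DataFrame:
    """Patients x features table from PatientRecord-like objects."""
    rows = {}
    for p in patients:
        feats = {}
        feats.update(compute_shape_features(p.gtvp_mask, p.spacing))
        feats.update(compute_firstorder_features(p.ct, p.gtvp_mask))
        feats.update(compute_glcm_features(p.ct, p.gtvp_mask, bins=glcm_bins))
        rows[p.patient_id] = feats
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "patient_id"
    if table.isna().any().any():
        raise ValueError("feature extraction produced missing values")
    return table


# ---------------------------------------------------------------------------
# selection chain
# ---------------------------------------------------------------------------


def minority_count(labels: Sequence[int]) -> int:
    labels = np.asarray(labels, dtype=int)
    return int(min((labels == 1).sum(), (labels == 0).sum()))


def select_features(
    table: pd.DataFrame,
    labels: Sequence[int],
    seed: int = 0,
    cutoff: float = 0.20,
    k: Optional[int] = None,
) -> SelectionTrace:
    labels = np.asarray(labels, dtype=int)
    if table.shape[1] < 1:
        raise ValueError("need at least one feature")

    variances = table.var(axis=0, ddof=0)
    dropped = list(table.columns[variances <= VARIANCE_EPS])
    kept = table.drop(columns=dropped)
    if kept.shape[1] == 0:
        raise ValueError("all features are (near-)constant")
    z = (kept - kept.mean()) / kept.std(ddof=0)
    names = list(z.columns)

    if len(names) == 1:
        rho = np.ones((1, 1))
        assignments = np.array([1])
    else:
        rho = sps.spearmanr(z.to_numpy()).statistic
        if np.isscalar(rho) or np.ndim(rho) == 0:  # spearmanr collapses 2 columns
            r = float(rho)
            rho = np.array([[1.0, r], [r, 1.0]])
        np.fill_diagonal(rho, 1.0)
        dist = np.clip(1.0 - np.abs(rho), 0.0, None)
        Z = linkage(squareform(dist, checks=False), method="average")
        assignments = fcluster(Z, t=cutoff, criterion="distance")

    clusters = []
    representatives = []
    for cid in np.unique(assignments):
        members = [names[i] for i in np.where(assignments == cid)[0]]
        if len(members) == 1:
            rep = members[0]
        else:
            idx = [names.index(m) for m in members]
            sub = np.abs(rho[np.ix_(idx, idx)])
            mean_abs = (sub.sum(axis=1) - 1.0) / (len(members) - 1)
            order = np.lexsort((members, -mean_abs))  # ties -> alphabetical
            rep = members[order[0]]
        clusters.append((members, rep))
        representatives.append(rep)

    # mRMR, difference form, on cluster representatives
    relevance = {
        name: abs(sps.pointbiserialr(labels, z[name].to_numpy()).statistic)
        for name in representatives
    }
    remaining = sorted(representatives)
    mrmr_order: list[str] = []
    while remaining:
        if not mrmr_order:
            scores = {n: relevance[n] for n in remaining}
        else:
            scores = {}
            for n in remaining:
                red = np.mean(
                    [abs(sps.spearmanr(z[n], z[m]).statistic) for m in mrmr_order]
                )
                scores[n] = relevance[n] - red
        best = max(remaining, key=lambda n: (scores[n], n))
        mrmr_order.append(best)
        remaining.remove(best)

    if k is None:
        k = max(1, minority_count(labels) // 10)
    selected = mrmr_order[: min(k, len(mrmr_order))]
    return SelectionTrace(
        variance_dropped=dropped,
        clusters=clusters,
        mrmr_order=mrmr_order,
        k_selected=int(k),
        selected=selected,
    )


# ---------------------------------------------------------------------------
# logistic model on frozen training z-scores
# ---------------------------------------------------------------------------


class RadiomicsModel:
    """Unpenalized logistic model; standardization learned on training data."""

    def __init__(self, feature_names: Sequence[str]):
        self.feature_names = list(feature_names)
        self._mean: Optional[np.ndarray] = None
        self._std: Optional[np.ndarray] = None
        self._clf: Optional[LogisticRegression] = None

    def _design(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.feature_names].to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        return X

    def fit(self, table: pd.DataFrame, labels: Sequence[int]) -> "RadiomicsModel":
        X = self._design(table)
        self._mean = X.mean(axis=0)
        self._std = X.std(axis=0, ddof=0)
        self._std[self._std < VARIANCE_EPS] = 1.0
        Xz = (X - self._mean) / self._std
        self._clf = LogisticRegression(C=np.inf, max_iter=5000)
        self._clf.fit(Xz, np.asarray(labels, dtype=int))
        return self

    def predict_proba(self, table: pd.DataFrame) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("model not fitted")
        Xz = (self._design(table) - self._mean) / self._std
        return self._clf.predict_proba(Xz)[:, 1]


def fit_radiomics_classifier(
    table: pd.DataFrame, labels: Sequence[int], selected: Sequence[str]
) -> RadiomicsModel:
    if len(selected) < 1:
        raise ValueError("need at least one selected feature")
    return RadiomicsModel(selected).fit(table, labels)
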