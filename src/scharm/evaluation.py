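"""Distance, fingerprinting, and embedding analyses for harmonization quality.

The workhorse distance is the mean absolute difference between two
connectomes' edge vectors (mean L1 over the upper triangle, in fibers).
From it are built:

* cross distance matrices between two connectome sets (e.g. a subject's
  scan at one setting vs. everyone's scan at another);
* within-subject (IS) vs. between-subject (InterS) distance
  distributions, the core of harmonization-quality assessment;
* fingerprinting: a subject is identified when their own scan is the
  strict nearest neighbor across settings, summarized by accuracy and by
  the identifiability gap I_diff = mean(off-diagonal) - mean(diagonal);
* a two-sample Kolmogorov-Smirnov test comparing distance distributions;
* a train/test PCA embedding of edge vectors (z-scored with training
  statistics only) into two components.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from scharm.core_io import (
    AcquisitionSetting,
    Cohort,
    Connectome,
    upper_triangle_index,
    vectorize,
)
from scharm.errors import DesignError, DimensionError

__all__ = [
    "DistanceMatrix",
    "FingerprintResult",
    "EmbeddingResult",
    "mean_abs_difference",
    "cross_distance_matrix",
    "intra_inter_distributions",
    "identification_accuracy",
    "ks_two_sample",
    "pca_embed",
    "rescan_outlier_report",
]


def _edge_vectors(connectomes: list[Connectome]) -> np.ndarray:
    parc = connectomes[0].parcellation
    for c in connectomes:
        if c.parcellation != parc:
            raise DimensionError("connectomes have mismatched parcellations")
    index = upper_triangle_index(parc.n_regions)
    return np.stack([vectorize(c, index) for c in connectomes]).astype(float)


def mean_abs_difference(c1: Connectome, c2: Connectome) -> float:
    """Mean L1 difference over the upper-triangle edges, in fibers."""
    v = _edge_vectors([c1, c2])
    return float(np.abs(v[0] - v[1]).mean())


@dataclass
class DistanceMatrix:
    """Pairwise mean-L1 distances between two ordered connectome sets."""

    row_subjects: list[str]
    col_subjects: list[str]
    values: np.ndarray

    @property
    def is_square_aligned(self) -> bool:
        return self.row_subjects == self.col_subjects

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_subjects,
                            columns=self.col_subjects)


def cross_distance_matrix(set_a: list[Connectome],
                          set_b: list[Connectome]) -> DistanceMatrix:
    """All pairwise mean-L1 distances between two connectome sets.

    When both sets contain the same subjects, align them by subject_id
    first so the diagonal holds within-subject distances.
    """
    if not set_a or not set_b:
        raise DesignError("cannot build a distance matrix from an empty set")
    subjects_a = [c.subject_id for c in set_a]
    subjects_b = [c.subject_id for c in set_b]
    if set(subjects_a) == set(subjects_b) and len(set(subjects_a)) == len(subjects_a):
        by_id = {c.subject_id: c for c in set_b}
        set_b = [by_id[s] for s in subjects_a]
        subjects_b = subjects_a[:]
    va = _edge_vectors(set_a)
    vb = _edge_vectors(list(set_b))
    if va.shape[1] != vb.shape[1]:
        raise DimensionError("sets have different parcellations")
    # broadcasted |a_i - b_j| mean over edges
    values = np.abs(va[:, None, :] - vb[None, :, :]).mean(axis=2)
    return DistanceMatrix(row_subjects=subjects_a, col_subjects=list(subjects_b),
                          values=values)


def intra_inter_distributions(cohort: Cohort, setting_a: AcquisitionSetting,
                              setting_b: AcquisitionSetting,
                              session: str = "1") -> tuple[np.ndarray, np.ndarray]:
    """Within-subject cross-setting vs. between-subject distances.

    IS: for each subject, distance between their scans at ``setting_a``
    and ``setting_b`` (n values).  InterS: distances between distinct
    subjects' scans at ``setting_a`` (n(n-1)/2 values).  Subject order
    follows the cohort.
    """
    subjects = cohort.subjects
    scans_a, scans_b = [], []
    for s in subjects:
        ca = cohort.get(s, session, setting_a)
        cb = cohort.get(s, session, setting_b)
        if ca is None or cb is None:
            raise DesignError(
                f"subject {s!r} missing a scan at {setting_a} or {setting_b}"
            )
        scans_a.append(ca)
        scans_b.append(cb)
    va = _edge_vectors(scans_a)
    vb = _edge_vectors(scans_b)
    intra = np.abs(va - vb).mean(axis=1)
    n = len(subjects)
    iu = np.triu_indices(n, k=1)
    inter = np.abs(va[:, None, :] - va[None, :, :]).mean(axis=2)[iu]
    return intra, inter


@dataclass
class FingerprintResult:
    """Identification accuracy and identifiability gap for a distance matrix."""

    accuracy: float
    i_diff: float
    direction: str
    n_subjects: int


def identification_accuracy(dist: DistanceMatrix,
                            direction: str = "row") -> FingerprintResult:
    """Nearest-neighbor subject identification on a square distance matrix.

    Row-wise (default): each row's subject is identified iff the diagonal
    entry is the strict minimum of that row; ties count as failure.
    I_diff is mean(off-diagonal) - mean(diagonal) of the same matrix.
    """
    d = np.asarray(dist.values, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DesignError(f"distance matrix must be square, got shape {d.shape}")
    if dist.row_subjects != dist.col_subjects:
        raise DesignError("distance matrix rows and columns are not subject-aligned")
    if direction not in ("row", "column"):
        raise DesignError(f"direction must be 'row' or 'column', got {direction!r}")
    if direction == "column":
        d = d.T
    n = d.shape[0]
    diag = np.diag(d)
    off = d + np.where(np.eye(n, dtype=bool), np.inf, 0.0)
    hits = diag < off.min(axis=1)  # strict minimum; ties fail
    off_mean = d[~np.eye(n, dtype=bool)].mean() if n > 1 else 0.0
    return FingerprintResult(
        accuracy=float(hits.mean()),
        i_diff=float(off_mean - diag.mean()),
        direction=direction,
        n_subjects=n,
    )


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided two-sample Kolmogorov-Smirnov test (D statistic, p-value)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DesignError("KS test requires two nonempty samples")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    return float(res.statistic), float(res.pvalue)


def rescan_outlier_report(cohort: Cohort, setting: AcquisitionSetting,
                          session_a: str, session_b: str) -> pd.DataFrame:
    """Flag subjects whose same-setting rescan distance rivals strangers'.

    For every subject with scans in both sessions at ``setting``, reports
    the within-subject rescan distance against the median between-subject
    distance (session A scans); ``flagged`` marks subjects at or above
    that median.  Advisory only — nothing is dropped.
    """
    scans_a, scans_b, subjects = [], [], []
    for s in cohort.subjects:
        ca = cohort.get(s, session_a, setting)
        cb = cohort.get(s, session_b, setting)
        if ca is not None and cb is not None:
            subjects.append(s)
            scans_a.append(ca)
            scans_b.append(cb)
    if not subjects:
        raise DesignError(
            f"no subject has scans in both sessions at {setting}"
        )
    va = _edge_vectors(scans_a)
    vb = _edge_vectors(scans_b)
    rescan = np.abs(va - vb).mean(axis=1)
    n = len(subjects)
    if n > 1:
        iu = np.triu_indices(n, k=1)
        inter_median = float(np.median(
            np.abs(va[:, None, :] - va[None, :, :]).mean(axis=2)[iu]))
    else:
        inter_median = np.inf
    return pd.DataFrame({
        "subject_id": subjects,
        "rescan_distance": rescan,
        "inter_subject_median": inter_median,
        "flagged": rescan >= inter_median,
    })


@dataclass
class EmbeddingResult:
    """Train/test coordinates in the first two principal components."""

    train_coords: np.ndarray
    test_coords: np.ndarray
    feature_mask: np.ndarray
    explained_variance: np.ndarray
    components: np.ndarray


def pca_embed(train_vectors: np.ndarray, test_vectors: np.ndarray
              ) -> EmbeddingResult:
    """Two-component PCA fitted on training edge vectors only.

    Each edge is z-scored by the training mean and standard deviation;
    zero-variance training edges are dropped (recorded in
    ``feature_mask``).  Component signs are fixed by making each
    component's largest-magnitude loading positive.
    """
    train = np.asarray(train_vectors, dtype=float)
    test = np.asarray(test_vectors, dtype=float)
    if train.ndim != 2 or train.shape[0] < 3:
        raise DesignError("PCA embedding needs at least 3 training vectors")
    if test.ndim != 2 or test.shape[1] != train.shape[1]:
        raise DimensionError("train and test vectors must share the edge index")
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    mask = sd > 0
    if mask.sum() < 2:
        raise DesignError("fewer than 2 non-degenerate features for PCA")
    z_train = (train[:, mask] - mean[mask]) / sd[mask]
    z_test = (test[:, mask] - mean[mask]) / sd[mask]
    pca = PCA(n_components=2)
    train_coords = pca.fit_transform(z_train)
    components = pca.components_.copy()
    for k in range(components.shape[0]):
        j = np.argmax(np.abs(components[k]))
        if components[k, j] < 0:
            components[k] *= -1
            train_coords[:, k] *= -1
    test_coords = (z_test - pca.mean_) @ components.T
    return EmbeddingResult(
        train_coords=train_coords,
        test_coords=test_coords,
        feature_mask=mask,
        explained_variance=pca.explained_variance_ratio_.copy(),
        components=components,
    )
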