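"""AA Sig / No-AA Sig subtype assignment.

Tumor cohorts are subtyped by hierarchical clustering of per-sample merged
signature exposures (the counts attributable to each etiology group), cut
at two clusters; the cluster with the larger mean AA exposure is "AA Sig".
Single samples -- in particular urinary cell-free DNA screened at low
coverage -- are subtyped by thresholds on the AA-attributed proportion:
above 15% calls AA Sig in cfDNA, below 5% calls No-AA Sig, the band in
between is flagged indeterminate; tumors use a single 50% cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

AA_SIG = "AA Sig"
NO_AA_SIG = "No-AA Sig"


@dataclass(frozen=True)
class ScreeningThresholds:
    """AA-proportion cutoffs for threshold-mode subtype calls."""

    cfdna_high: float = 0.15
    cfdna_low: float = 0.05
    tumor_high: float = 0.50

    def __post_init__(self) -> None:
        if not (0 < self.cfdna_low < self.cfdna_high <= self.tumor_high):
            raise ValueError(
                "require 0 < cfdna_low < cfdna_high <= tumor_high, got "
                f"{self.cfdna_low}/{self.cfdna_high}/{self.tumor_high}"
            )


@dataclass
class SubtypeCall:
    """One sample's subtype label and the rule that produced it."""

    sample_id: str
    label: str
    aa_proportion: float
    method: str  # "clustering" or "threshold"
    threshold_used: float | None = None
    indeterminate: bool = False

    def __post_init__(self) -> None:
        if self.label not in (AA_SIG, NO_AA_SIG):
            raise ValueError(f"invalid label {self.label!r}")
        if self.method == "threshold" and self.threshold_used is None:
            raise ValueError("threshold method requires threshold_used")


def classify_threshold(
    aa_prop: float,
    context: str,
    thresholds: ScreeningThresholds | None = None,
    sample_id: str = "sample",
) -> SubtypeCall:
    """Threshold-mode subtype call on a single AA proportion.

    cfDNA: > cfdna_high -> AA Sig; < cfdna_low -> No-AA Sig; the
    intermediate band gets a No-AA Sig label flagged indeterminate (only
    the extremes are validated).  Tumor: > tumor_high -> AA Sig.
    """
    t = thresholds or ScreeningThresholds()
    if not 0.0 <= aa_prop <= 1.0:
        raise ValueError(f"aa_prop={aa_prop} outside [0, 1]")
    if context == "cfdna":
        if aa_prop > t.cfdna_high:
            return SubtypeCall(sample_id, AA_SIG, aa_prop, "threshold", t.cfdna_high)
        if aa_prop < t.cfdna_low:
            return SubtypeCall(sample_id, NO_AA_SIG, aa_prop, "threshold", t.cfdna_low)
        return SubtypeCall(
            sample_id, NO_AA_SIG, aa_prop, "threshold", t.cfdna_high,
            indeterminate=True,
        )
    if context == "tumor":
        label = AA_SIG if aa_prop > t.tumor_high else NO_AA_SIG
        return SubtypeCall(sample_id, label, aa_prop, "threshold", t.tumor_high)
    raise ValueError(f"context must be 'tumor' or 'cfdna', got {context!r}")


class ThresholdSubtypeClassifier(BaseEstimator):
    """Threshold-mode subtype calls on per-sample AA proportions.

    A stateless sklearn-style classifier over a 1-d feature (the
    AA-attributed proportion of total exposure): ``predict`` returns
    "AA Sig" / "No-AA Sig" labels under the context's cutoffs, and
    ``predict_calls`` the full :class:`SubtypeCall` records including the
    indeterminate flag for the unvalidated cfDNA band.
    """

    def __init__(self, context: str = "cfdna",
                 thresholds: ScreeningThresholds | None = None):
        self.context = context
        self.thresholds = thresholds

    def fit(self, X=None, y=None):
        if self.context not in ("tumor", "cfdna"):
            raise ValueError(f"context must be 'tumor' or 'cfdna', got {self.context!r}")
        self.thresholds_ = self.thresholds or ScreeningThresholds()
        return self

    def _props(self, X) -> np.ndarray:
        props = np.asarray(X, dtype=float).reshape(-1)
        if np.any((props < 0) | (props > 1)):
            raise ValueError("AA proportions must lie in [0, 1]")
        return props

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "thresholds_")
        return np.array([
            classify_threshold(p, self.context, self.thresholds_).label
            for p in self._props(X)
        ])

    def predict_calls(self, X, sample_ids=None) -> list[SubtypeCall]:
        check_is_fitted(self, "thresholds_")
        props = self._props(X)
        ids = sample_ids if sample_ids is not None else [f"sample{i}" for i in range(len(props))]
        return [
            classify_threshold(p, self.context, self.thresholds_, sample_id=sid)
            for sid, p in zip(ids, props)
        ]


class SubtypeClusterer(BaseEstimator, ClusterMixin):
    """Two-cluster hierarchical subtyping of merged exposure profiles.

    Rows of ``X`` are samples, columns the merged etiology groups, values
    the mutation counts attributed to each group.  Counts are log1p
    transformed (the attributed-count scale is heavy tailed), clustered
    with Ward linkage on Euclidean distances, and the tree is cut at two
    clusters.  The cluster with the larger mean AA-group exposure is
    labeled "AA Sig".

    Parameters
    ----------
    aa_index : int
        Column of X holding the AA group (default 0, the default merge
        map's first group).
    metric, linkage_method : str
        Distance metric and linkage; defaults "euclidean" / "ward".
    transform : {"log1p", "none", "proportion"}
        Row representation handed to the linkage.

    Attributes
    ----------
    labels_ : ndarray of "AA Sig" / "No-AA Sig"
    aa_proportions_ : per-sample AA proportion of total exposure
    linkage_matrix_ : scipy linkage matrix
    dendrogram_order_ : leaf order for plotting
    """

    def __init__(self, aa_index=0, metric="euclidean", linkage_method="ward",
                 transform="log1p"):
        self.aa_index = aa_index
        self.metric = metric
        self.linkage_method = linkage_method
        self.transform = transform

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=1)
        if X.shape[0] < 2:
            raise ValueError(
                "clustering needs at least 2 samples; use threshold mode "
                "(classify_threshold) for single samples"
            )
        if np.any(X < 0):
            raise ValueError("exposure counts must be non-negative")
        if self.transform == "log1p":
            Z = np.log1p(X)
        elif self.transform == "proportion":
            totals = X.sum(axis=1, keepdims=True)
            if np.any(totals <= 0):
                raise ValueError("zero-total sample cannot be represented as proportions")
            Z = X / totals
        elif self.transform == "none":
            Z = X.astype(float)
        else:
            raise ValueError(f"unknown transform {self.transform!r}")
        if np.unique(Z, axis=0).shape[0] == 1:
            raise ValueError("all samples identical: dendrogram is degenerate")
        dists = pdist(Z, metric=self.metric)
        self.linkage_matrix_ = hierarchy.linkage(dists, method=self.linkage_method)
        assignments = hierarchy.fcluster(self.linkage_matrix_, 2, criterion="maxclust")
        aa_col = X[:, self.aa_index]
        means = {c: aa_col[assignments == c].mean() for c in np.unique(assignments)}
        aa_cluster = max(means, key=lambda c: means[c])
        self.labels_ = np.where(assignments == aa_cluster, AA_SIG, NO_AA_SIG)
        totals = X.sum(axis=1)
        with np.errstate(invalid="ignore"):
            self.aa_proportions_ = np.where(totals > 0, aa_col / totals, 0.0)
        self.dendrogram_order_ = hierarchy.leaves_list(self.linkage_matrix_)
        self.n_features_in_ = X.shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict_calls(self, sample_ids=None) -> list[SubtypeCall]:
        check_is_fitted(self, "labels_")
        n = len(self.labels_)
        ids = sample_ids if sample_ids is not None else [f"sample{i}" for i in range(n)]
        return [
            SubtypeCall(sid, lab, float(prop), "clustering")
            for sid, lab, prop in zip(ids, self.labels_, self.aa_proportions_)
        ]


def cluster_subtypes(exposure_matrix, sample_ids=None, aa_index=0,
                     **clusterer_kwargs) -> list[SubtypeCall]:
    """Functional wrapper over :class:`SubtypeClusterer`.

    ``exposure_matrix`` may be a pandas DataFrame (samples x merged groups;
    an "AA" column is located by name) or an array with ``aa_index``.
    """
    ids = sample_ids
    if hasattr(exposure_matrix, "columns"):  # DataFrame
        if "AA" in exposure_matrix.columns:
            aa_index = list(exposure_matrix.columns).index("AA")
        if ids is None:
            ids = list(exposure_matrix.index.astype(str))
        exposure_matrix = exposure_matrix.to_numpy()
    clusterer = SubtypeClusterer(aa_index=aa_index, **clusterer_kwargs)
    clusterer.fit(exposure_matrix)
    return clusterer.predict_calls(ids)
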