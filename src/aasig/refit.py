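"""Signature refitting: non-negative attribution of catalogs to reference signatures.

Given a 96-class catalog ``m`` and a column-stochastic reference matrix
``P`` (96 x K), the exposure vector solves

    e* = argmin_{e >= 0} || m - P e ||_2

by non-negative least squares (Lawson-Hanson active set).  Exposures are in
mutation-count units; they are subsequently merged by shared etiology into
10 groups, of which "AA" (aristolochic acid) contains exactly signature 22,
and summarized as the AA proportion -- the screening statistic.

The sklearn-style entry point is :class:`SignatureRefitter`; the
module-level functions operate on single catalogs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .reference import SignatureMatrix, default_merge_map, synthetic_signature_matrix
from .spectrum import MutationCatalog

# scipy.optimize.nnls terminates on its own machine-precision criterion


@dataclass
class ExposureVector:
    """Per-sample attribution of mutation counts to (raw or merged) signatures."""

    sample_id: str
    names: list[str]
    exposures: np.ndarray
    residual_norm: float = 0.0
    reconstruction_cosine: float = 1.0

    def __post_init__(self) -> None:
        self.exposures = np.asarray(self.exposures, dtype=float)
        if self.exposures.shape != (len(self.names),):
            raise ValueError("exposures length must match names")
        if np.any(self.exposures < -1e-12):
            raise ValueError("exposures must be non-negative")
        self.exposures = np.clip(self.exposures, 0.0, None)

    @property
    def total(self) -> float:
        return float(self.exposures.sum())

    def __getitem__(self, name: str) -> float:
        return float(self.exposures[self.names.index(name)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.exposures, index=self.names, name=self.sample_id)


@dataclass
class MergeMap:
    """Mapping from reference-signature label to etiology group."""

    mapping: dict[str, str]

    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.mapping.values():
            if g not in seen:
                seen.append(g)
        return seen

    def validate_covers(self, signature_names: list[str]) -> None:
        unmapped = [n for n in signature_names if n not in self.mapping]
        if unmapped:
            raise ValueError(
                "merge map does not cover signature(s): " + ", ".join(unmapped)
            )

    @classmethod
    def default(cls, signature_names: list[str]) -> "MergeMap":
        return cls(default_merge_map(signature_names))

    @classmethod
    def from_file(cls, path) -> "MergeMap":
        """Read ``signature: group`` lines (blank lines and # comments skipped)."""
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sig, _, group = line.partition(":")
                if not group:
                    raise ValueError(f"malformed merge-map line: {line!r}")
                mapping[sig.strip()] = group.strip()
        return cls(mapping)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for sig, group in self.mapping.items():
                fh.write(f"{sig}: {group}\n")


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


def fit_exposures(
    catalog: MutationCatalog,
    signatures: SignatureMatrix,
    allow_zero: bool = False,
) -> ExposureVector:
    """Refit one catalog against the reference signatures by NNLS.

    An all-zero catalog is an error by default; with ``allow_zero`` it
    yields a zero exposure vector (useful when thinning empties a sample).
    """
    counts = catalog.counts.astype(float)
    if catalog.total == 0:
        if allow_zero:
            return ExposureVector(
                catalog.sample_id,
                list(signatures.names),
                np.zeros(signatures.n_signatures),
                residual_norm=0.0,
                reconstruction_cosine=0.0,
            )
        raise ValueError(
            f"catalog {catalog.sample_id!r} has zero total; nothing to refit"
        )
    exposures, residual = nnls(signatures.probs, counts)
    recon = signatures.probs @ exposures
    return ExposureVector(
        catalog.sample_id,
        list(signatures.names),
        exposures,
        residual_norm=float(residual),
        reconstruction_cosine=_cosine(counts, recon),
    )


def merge_exposures(exposure: ExposureVector, merge_map: MergeMap) -> ExposureVector:
    """Sum exposures by etiology group; total is preserved exactly."""
    merge_map.validate_covers(exposure.names)
    groups = merge_map.group_names()
    idx = {g: i for i, g in enumerate(groups)}
    merged = np.zeros(len(groups))
    for name, value in zip(exposure.names, exposure.exposures):
        merged[idx[merge_map.mapping[name]]] += value
    return ExposureVector(
        exposure.sample_id,
        groups,
        merged,
        residual_norm=exposure.residual_norm,
        reconstruction_cosine=exposure.reconstruction_cosine,
    )


def aa_proportion(exposure: ExposureVector, aa_group: str = "AA") -> float:
    """Fraction of total exposure attributed to the AA group."""
    total = exposure.total
    if total <= 0:
        raise ValueError(
            f"sample {exposure.sample_id!r} has zero total exposure"
        )
    if aa_group in exposure.names:
        aa = exposure[aa_group]
    else:  # raw (unmerged) vector: fall back to signature 22
        aa = exposure["Signature 22"]
    return aa / total


class SignatureRefitter(BaseEstimator, TransformerMixin):
    """Refit samples x 96 catalogs to reference signatures (NNLS exposures).

    Parameters
    ----------
    signatures : SignatureMatrix, optional
        Reference set; defaults to the package's synthetic 30-signature
        matrix (see :mod:`aasig.reference` -- a stand-in, not real COSMIC).
    merge_map : MergeMap, optional
        Etiology merge; defaults to the 10-group map anchored by
        AA = {signature 22}.
    allow_zero : bool
        Return zero exposures for all-zero rows instead of raising.

    Attributes
    ----------
    signatures_ : SignatureMatrix
    merge_map_ : MergeMap
    group_names_ : list of merged group labels
    """

    def __init__(self, signatures=None, merge_map=None, allow_zero=False):
        self.signatures = signatures
        self.merge_map = merge_map
        self.allow_zero = allow_zero

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_features=96)
        if X.shape[1] != 96:
            raise ValueError(f"X must have 96 columns, got {X.shape[1]}")
        self.signatures_ = self.signatures or synthetic_signature_matrix()
        self.merge_map_ = self.merge_map or MergeMap.default(self.signatures_.names)
        self.merge_map_.validate_covers(self.signatures_.names)
        self.group_names_ = self.merge_map_.group_names()
        self.n_features_in_ = 96
        return self

    def _exposure_vectors(self, X) -> list[ExposureVector]:
        check_is_fitted(self, "signatures_")
        X = check_array(X)
        if X.shape[1] != 96:
            raise ValueError(f"X must have 96 columns, got {X.shape[1]}")
        return [
            fit_exposures(
                MutationCatalog(f"sample{i}", row),
                self.signatures_,
                allow_zero=self.allow_zero,
            )
            for i, row in enumerate(X)
        ]

    def transform(self, X) -> np.ndarray:
        """Raw exposures, shape (n_samples, K)."""
        return np.vstack([e.exposures for e in self._exposure_vectors(X)])

    def transform_merged(self, X) -> np.ndarray:
        """Etiology-merged exposures, shape (n_samples, n_groups)."""
        return np.vstack(
            [
                merge_exposures(e, self.merge_map_).exposures
                for e in self._exposure_vectors(X)
            ]
        )

    def aa_proportion(self, X, aa_group: str = "AA") -> np.ndarray:
        """Per-sample AA-attributed proportion of total exposure."""
        merged = self.transform_merged(X)
        totals = merged.sum(axis=1)
        if np.any(totals <= 0):
            if not self.allow_zero:
                raise ValueError("zero total exposure in at least one sample")
            totals = np.where(totals > 0, totals, np.nan)
        return merged[:, self.group_names_.index(aa_group)] / totals
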