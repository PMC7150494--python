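"""Reference mutational-signature matrices and the canonical 96-class layout.

The 96 single-base-substitution classes are ordered substitution-major
(C>A, C>G, C>T, T>A, T>C, T>G), then 5' flank, then 3' flank, both
alphabetical -- the same row order as the COSMIC v2 probability file, so a
catalog built here can be refit against a downloaded matrix without any
permutation.  ``load_signature_matrix`` validates and reorders on load in
case a file ships rows in a different order.

Because the genuine COSMIC v2 probabilities are an external download, this
module also provides :func:`synthetic_signature_matrix`, a SYNTHETIC
stand-in reference set: 30 column-stochastic signatures generated from a
fixed seed, with the field-known character of several etiologies built in
(signature 22, the aristolochic-acid signature, is dominated by T>A
transversions peaking at C[T>A]G; signature 1 by C>T at NpCpG; the APOBEC
pair 2/13 by C>T / C>G at TpCpN; and so on).  It is suitable for
simulation and method validation, not for attributing real cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

#: Canonical 96 context labels, e.g. "A[C>A]A", in COSMIC row order.
CONTEXT_LABELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)

CONTEXT_INDEX: dict[str, int] = {lab: i for i, lab in enumerate(CONTEXT_LABELS)}

_COLUMN_SUM_TOL = 1e-6


@dataclass
class SignatureMatrix:
    """A 96 x K column-stochastic matrix of reference signature probabilities."""

    names: list[str]
    probs: np.ndarray  # shape (96, K)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (96, len(self.names)):
            raise ValueError(
                f"probs must be 96 x {len(self.names)}, got {self.probs.shape}"
            )
        if np.any(self.probs < 0):
            raise ValueError("signature probabilities must be non-negative")
        colsums = self.probs.sum(axis=0)
        bad = np.abs(colsums - 1.0) > _COLUMN_SUM_TOL
        if np.any(bad):
            names = [self.names[i] for i in np.flatnonzero(bad)]
            raise ValueError(f"signature columns do not sum to 1: {names}")

    @property
    def n_signatures(self) -> int:
        return len(self.names)

    def column(self, name: str) -> np.ndarray:
        try:
            k = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown signature label: {name!r}") from None
        return self.probs[:, k]

    def subset(self, names: list[str]) -> "SignatureMatrix":
        cols = [self.names.index(n) for n in names]
        return SignatureMatrix(list(names), self.probs[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.probs, index=list(CONTEXT_LABELS), columns=self.names
        )


def load_signature_matrix(path) -> SignatureMatrix:
    """Read a tab-delimited signature matrix (96 labeled rows x K labeled columns).

    Rows may appear in any order; they are validated against the canonical
    96 labels and reordered.  Extra annotation columns (the COSMIC download
    carries "Substitution Type" and "Trinucleotide") are dropped; the row
    label is taken from a "Somatic Mutation Type" column when present,
    otherwise from the index column.
    """
    df = pd.read_csv(path, sep="\t")
    if "Somatic Mutation Type" in df.columns:
        df = df.set_index("Somatic Mutation Type")
        df = df.drop(
            columns=[c for c in ("Substitution Type", "Trinucleotide") if c in df],
        )
    else:
        df = df.set_index(df.columns[0])
    df = df.select_dtypes("number")
    missing = set(CONTEXT_LABELS) - set(df.index)
    if missing:
        raise ValueError(
            f"signature matrix is missing {len(missing)} context rows, "
            f"e.g. {sorted(missing)[:3]}"
        )
    df = df.loc[list(CONTEXT_LABELS)]
    return SignatureMatrix(list(df.columns), df.to_numpy())


def write_signature_matrix(matrix: SignatureMatrix, path) -> None:
    matrix.to_frame().rename_axis("Somatic Mutation Type").to_csv(path, sep="\t")


def _context_mask(sub: str, five: str | None = None, three: str | None = None) -> np.ndarray:
    """Boolean mask over the 96 classes for one substitution and optional flanks."""
    mask = np.zeros(96, dtype=bool)
    for i, lab in enumerate(CONTEXT_LABELS):
        if lab[2:5] != sub:
            continue
        if five is not None and lab[0] not in five:
            continue
        if three is not None and lab[6] not in three:
            continue
        mask[i] = True
    return mask


# (substitution, 5' flanks, 3' flanks, weight of the motif component)
_MOTIFS: dict[int, list[tuple[str, str | None, str | None, float]]] = {
    1: [("C>T", None, "G", 0.75), ("C>T", None, None, 0.10)],     # 5mC deamination
    2: [("C>T", "T", None, 0.85)],                                # APOBEC
    4: [("C>A", None, None, 0.65), ("C>G", None, None, 0.10)],    # tobacco
    5: [("T>C", None, None, 0.35), ("C>T", None, None, 0.25)],    # flat clock-like
    6: [("C>T", None, "G", 0.50), ("C>T", None, None, 0.25)],     # MMR deficiency
    7: [("C>T", "CT", None, 0.80)],                               # UV dipyrimidine
    10: [("C>A", "T", "T", 0.55), ("C>T", "T", "G", 0.25)],       # POLE exo
    11: [("C>T", None, None, 0.75)],                              # alkylating
    13: [("C>G", "T", None, 0.85)],                               # APOBEC C>G
    17: [("T>G", "CT", "T", 0.75)],
    22: [("T>A", "C", "G", 0.55), ("T>A", None, None, 0.30)],     # aristolochic acid
    24: [("C>A", None, None, 0.60), ("C>T", None, None, 0.10)],   # aflatoxin
    26: [("T>C", None, None, 0.60)],
    29: [("C>A", None, None, 0.60)],
}


def synthetic_signature_matrix(n_signatures: int = 30, seed: int = 20200304) -> SignatureMatrix:
    """Generate a SYNTHETIC 30-signature reference matrix (COSMIC v2 layout).

    Each column mixes a sparse seeded Dirichlet background with, for the
    signatures whose etiology has a well-known spectral motif, concentrated
    mass on that motif (see module docstring).  Deterministic for a fixed
    seed.  The labels follow the COSMIC v2 convention "Signature 1" ..
    "Signature 30".
    """
    if not 1 <= n_signatures <= 30:
        raise ValueError("n_signatures must be in [1, 30]")
    rng = np.random.default_rng(seed)
    cols = []
    names = []
    for k in range(1, n_signatures + 1):
        background = rng.dirichlet(np.full(96, 0.12))
        col = background
        for sub, five, three, weight in _MOTIFS.get(k, []):
            mask = _context_mask(sub, five, three)
            motif = np.zeros(96)
            motif[mask] = rng.dirichlet(np.full(mask.sum(), 2.0))
            col = (1.0 - weight) * col + weight * motif
        cols.append(col / col.sum())
        names.append(f"Signature {k}")
    return SignatureMatrix(names, np.column_stack(cols))


#: Default etiology merge map: COSMIC signature label -> merged group.
#: "AA" (aristolochic acid) contains exactly signature 22; remaining
#: signatures fall into "other".  Overridable from a config file.
DEFAULT_MERGE_GROUPS: dict[str, list[int]] = {
    "AA": [22],
    "clock": [1, 5],
    "APOBEC": [2, 13],
    "MMR": [6, 15, 20, 21, 26],
    "tobacco": [4, 29],
    "UV": [7],
    "POLE": [10],
    "alkylating": [11],
    "aflatoxin": [24],
}


def default_merge_map(signature_names: list[str]) -> dict[str, str]:
    """Map every signature label to its etiology group (10 groups incl. 'other').

    The mapping is emitted group-major so the merged-exposure column order
    is stable with "AA" first.
    """
    mapping: dict[str, str] = {}
    for group, nums in DEFAULT_MERGE_GROUPS.items():
        for num in nums:
            name = f"Signature {num}"
            if name in signature_names:
                mapping[name] = group
    for name in signature_names:
        mapping.setdefault(name, "other")
    return mapping
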