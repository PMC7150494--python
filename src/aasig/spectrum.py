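"""96-trinucleotide-context mutation catalogs.

Substitutions are strand-collapsed so the mutated reference base is a
pyrimidine: a purine substitution and its flanks are reverse-complemented
(which swaps the flanks).  The catalog layout follows the canonical order
in :mod:`aasig.reference`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reference import BASES, CONTEXT_INDEX, CONTEXT_LABELS, SUBSTITUTIONS
from .variants import VariantRecord

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_PYRIMIDINES = frozenset("CT")


@dataclass(frozen=True)
class TrinucleotideClass:
    """One of the 96 strand-collapsed substitution classes."""

    substitution: str  # e.g. "T>A"
    five_prime: str
    three_prime: str

    def __post_init__(self) -> None:
        if self.substitution not in SUBSTITUTIONS:
            raise ValueError(f"invalid substitution {self.substitution!r}")
        for b in (self.five_prime, self.three_prime):
            if b not in BASES:
                raise ValueError(f"invalid flanking base {b!r}")

    @property
    def label(self) -> str:
        return f"{self.five_prime}[{self.substitution}]{self.three_prime}"

    @property
    def index(self) -> int:
        return CONTEXT_INDEX[self.label]


@dataclass
class MutationCatalog:
    """Per-sample counts over the 96 trinucleotide substitution classes."""

    sample_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (96,):
            raise ValueError(f"counts must have shape (96,), got {self.counts.shape}")
        if np.any(self.counts < 0):
            raise ValueError("catalog counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXT_LABELS), name=self.sample_id)


def classify_context(ref: str, alt: str, flank5: str, flank3: str) -> TrinucleotideClass:
    """Map an SNV plus flanks to its strand-collapsed 96-class.

    If ``ref`` is a purine the whole trinucleotide and the alternate allele
    are reverse-complemented, so the returned class always has a pyrimidine
    reference and applying the function to a variant and to its full
    reverse complement yields the same class.
    """
    for b in (ref, alt, flank5, flank3):
        if b not in _COMPLEMENT:
            raise ValueError(f"invalid base {b!r}; expected one of A, C, G, T")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref not in _PYRIMIDINES:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        flank5, flank3 = _COMPLEMENT[flank3], _COMPLEMENT[flank5]
    return TrinucleotideClass(f"{ref}>{alt}", flank5, flank3)


def normalize_chrom(chrom: str, style: str | None) -> str:
    """Normalize chromosome naming ("chr1" vs "1"); style None leaves it alone."""
    if style is None:
        return chrom
    bare = chrom[3:] if chrom.startswith("chr") else chrom
    if style == "ucsc":
        return f"chr{bare}"
    if style == "ensembl":
        return bare
    raise ValueError(f"unknown chromosome naming style {style!r}")


def build_catalog(
    variants: list[VariantRecord],
    reference,
    sample_id: str = "sample",
    chrom_style: str | None = None,
) -> MutationCatalog:
    """Tally filtered SNVs into a 96-class catalog using an indexed FASTA.

    ``reference`` is a mapping of chromosome name to sequence supporting
    slicing, e.g. ``pyfaidx.Fasta(path)``.  Coordinates are 1-based (VCF
    convention); flanks are pos-1 and pos+1.  The reference base at each
    variant position must match the record's ``ref`` field, and positions at
    contig edges (no flank on one side) are an error.
    """
    counts = np.zeros(96, dtype=np.int64)
    for v in variants:
        chrom = normalize_chrom(v.chrom, chrom_style)
        if chrom not in reference:
            raise ValueError(f"variant {v.key_str()}: chromosome {chrom!r} not in reference")
        seq = reference[chrom]
        if v.pos < 2 or v.pos > len(seq) - 1:
            raise ValueError(
                f"variant {v.key_str()}: position at contig edge, no flanking base"
            )
        tri = str(seq[v.pos - 2 : v.pos + 1]).upper()
        if tri[1] != v.ref:
            raise ValueError(
                f"variant {v.key_str()}: reference base mismatch "
                f"(FASTA has {tri[1]!r}, record says {v.ref!r})"
            )
        counts[classify_context(v.ref, v.alt, tri[0], tri[2]).index] += 1
    return MutationCatalog(sample_id, counts)


def downsample_catalog(
    catalog: MutationCatalog, fraction: float, seed: int
) -> MutationCatalog:
    """Binomially thin a catalog: each mutation kept independently w.p. ``fraction``.

    Emulates the reduced SNV yield of low-coverage sequencing while leaving
    the expected spectrum shape unchanged.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    thinned = rng.binomial(catalog.counts.astype(np.int64), fraction)
    return MutationCatalog(catalog.sample_id, thinned)


def write_catalogs(path, catalogs: list[MutationCatalog]) -> None:
    """Write catalogs as a tab-delimited 96-row matrix (samples as columns)."""
    df = pd.concat([c.to_series() for c in catalogs], axis=1)
    df.rename_axis("Somatic Mutation Type").to_csv(path, sep="\t")


def read_catalogs(path) -> list[MutationCatalog]:
    """Read a tab-delimited catalog matrix, validating the 96 row labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CONTEXT_LABELS) - set(df.index)
    if missing:
        raise ValueError(
            f"catalog file is missing {len(missing)} context rows, "
            f"e.g. {sorted(missing)[:3]}"
        )
    df = df.loc[list(CONTEXT_LABELS)]
    return [MutationCatalog(col, df[col].to_numpy()) for col in df.columns]
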