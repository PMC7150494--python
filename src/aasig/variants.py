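"""Post-calling somatic SNV filters.

Candidate somatic SNVs arrive annotated with read-level summary statistics
(computed upstream by the caller / pileup machinery).  The engine here
applies, in order:

1. caller intersection (variants reported by both callers),
2. eight read-level removal rules (read-end distance, mapping and base
   quality, strand bias, adjacent repeats, clustered variants),
3. an allele-frequency window (0.25, 0.75) that strips likely germline
   variants (AF ~ 0.5 germline het looks somatic in impure tumors only
   above 0.75 / below 0.25 after purity; the window also removes
   low-AF FFPE artifacts),
4. a population-frequency filter (any database frequency >= 0.001) with a
   pathogenicity rescue: ClinVar-pathogenic or COSMIC urinary-annotated
   variants are kept regardless of population frequency.

A variant failing several rules is *removed* on OR-over-rules semantics but
*counted* under the lowest-numbered failing rule, so the per-rule rejection
counts partition the removed set deterministically.

In low-coverage mode (urinary cell-free DNA) the allele-frequency window is
disabled: AF estimates at ~1x coverage are meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Mapping

_VALID_BASES = frozenset("ACGT")

#: Databases consulted for population allele frequency.  "panel" models a
#: local panel of normals (variants seen in healthy individuals).
POPULATION_DATABASES = ("1000g", "exac", "esp6500", "hrc", "kaviar", "panel")

#: Read-level rule ids in application order; used as keys of rejection counts.
READ_LEVEL_RULES = (
    "rule1_dist_end_median",
    "rule2_dist_end_mad",
    "rule3_frac_low_mapq",
    "rule4_mapq_median",
    "rule5_baseq_median",
    "rule6_strand_bias",
    "rule7_repeat_len",
    "rule8_nearby_variants",
)

AF_RULE = "af_window"
POP_RULE = "pop_freq"

#: Fields a record must carry for the read-level rules (rule order).
_RULE_FIELDS = (
    "dist_to_end_median",
    "dist_to_end_mad",
    "frac_low_mapq",
    "mapq_median_varreads",
    "baseq_median_varreads",
    "strand_frac_varreads",
    "repeat_len_adjacent",
    "nearby_variant_max",
)


@dataclass
class VariantRecord:
    """One candidate somatic SNV with read-level summaries and annotations.

    Strand-bias fields hold the *minority*-strand fraction, i.e. the smaller
    of the forward/reverse read fractions, so both lie in [0, 0.5] and the
    0.02 / 0.2 cutoffs act on the under-represented strand.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    dist_to_end_median: float | None = None
    dist_to_end_mad: float | None = None
    frac_low_mapq: float | None = None
    mapq_median_varreads: float | None = None
    baseq_median_varreads: float | None = None
    strand_frac_varreads: float | None = None
    strand_frac_allreads: float | None = None
    repeat_len_adjacent: int | None = None
    nearby_variant_max: int | None = None
    allele_freq: float | None = None
    pop_freqs: dict[str, float] = field(default_factory=dict)
    clinvar_pathogenic: bool = False
    cosmic_urinary: bool = False
    callers: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.ref not in _VALID_BASES or self.alt not in _VALID_BASES:
            raise ValueError(
                f"{self.key_str()}: ref/alt must be single bases in ACGT, "
                f"got {self.ref!r}>{self.alt!r}"
            )
        if self.ref == self.alt:
            raise ValueError(f"{self.key_str()}: ref == alt")
        if self.pos < 1:
            raise ValueError(f"{self.key_str()}: pos must be 1-based positive")
        for name in ("strand_frac_varreads", "strand_frac_allreads"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 0.5:
                raise ValueError(
                    f"{self.key_str()}: {name}={v} outside [0, 0.5] "
                    "(minority-strand fraction)"
                )
        if self.allele_freq is not None and not 0.0 <= self.allele_freq <= 1.0:
            raise ValueError(
                f"{self.key_str()}: allele_freq={self.allele_freq} outside [0, 1]"
            )
        for db, f in self.pop_freqs.items():
            if f < 0:
                raise ValueError(
                    f"{self.key_str()}: negative population frequency {f} in {db}"
                )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"

    def require(self, field_names: Iterable[str]) -> None:
        missing = [n for n in field_names if getattr(self, n) is None]
        if missing:
            raise ValueError(
                f"variant {self.key_str()} is missing feature field(s): "
                + ", ".join(missing)
            )


@dataclass(frozen=True)
class FilterThresholds:
    """Removal cutoffs for the post-calling filters (defaults as published)."""

    dist_end_median_min: float = 10.0   # removed if median dist < this
    dist_end_mad_min: float = 3.0       # removed if MAD < this
    frac_low_mapq_max: float = 0.10     # removed if fraction MQ<1 reads > this
    mapq_median_min: float = 40.0       # removed if median MQ < this
    baseq_median_min: float = 20.0      # removed if median BQ < this
    strand_frac_var_min: float = 0.02   # rule 6, with the all-reads exception
    strand_frac_all_min: float = 0.2
    repeat_len_max: int = 12            # removed at >= this
    window_bp: int = 50
    nearby_variant_max_allowed: int = 2  # removed if > this
    af_low: float = 0.25                 # retain iff af_low < AF < af_high
    af_high: float = 0.75
    pop_freq_max: float = 0.001          # removed if any db freq >= this

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"threshold {f.name} must be strictly positive")
        if self.af_low >= self.af_high:
            raise ValueError("af_low must be < af_high")


@dataclass
class FilterReport:
    """Outcome of one filtering pass: retained records plus an audit trail."""

    retained: list[VariantRecord]
    rejections: dict[str, int]
    rescued_count: int = 0

    @property
    def n_removed(self) -> int:
        return sum(self.rejections.values())


def intersect_callsets(
    set_a: list[VariantRecord], set_b: list[VariantRecord]
) -> list[VariantRecord]:
    """Variants reported by both callers, keyed on (chrom, pos, ref, alt).

    Feature annotations are taken from ``set_a`` (one caller is designated
    the annotation source; reconciling per-caller read statistics is not
    attempted).  Duplicate keys within either input are an error.
    """
    for name, records in (("set_a", set_a), ("set_b", set_b)):
        seen: set = set()
        for r in records:
            if r.key in seen:
                raise ValueError(f"duplicate variant key in {name}: {r.key_str()}")
            seen.add(r.key)
    keys_b = {r.key for r in set_b}
    return [r for r in set_a if r.key in keys_b]


def failing_rule(v: VariantRecord, t: FilterThresholds) -> str | None:
    """Lowest-numbered read-level rule the variant fails, or None if clean."""
    v.require(_RULE_FIELDS)
    if v.dist_to_end_median < t.dist_end_median_min:
        return READ_LEVEL_RULES[0]
    if v.dist_to_end_mad < t.dist_end_mad_min:
        return READ_LEVEL_RULES[1]
    if v.frac_low_mapq > t.frac_low_mapq_max:
        return READ_LEVEL_RULES[2]
    if v.mapq_median_varreads < t.mapq_median_min:
        return READ_LEVEL_RULES[3]
    if v.baseq_median_varreads < t.baseq_median_min:
        return READ_LEVEL_RULES[4]
    if v.strand_frac_varreads < t.strand_frac_var_min:
        # exception clause: tolerated when all reads are similarly skewed
        v.require(("strand_frac_allreads",))
        if v.strand_frac_allreads >= t.strand_frac_all_min:
            return READ_LEVEL_RULES[5]
    if v.repeat_len_adjacent >= t.repeat_len_max:
        return READ_LEVEL_RULES[6]
    if v.nearby_variant_max > t.nearby_variant_max_allowed:
        return READ_LEVEL_RULES[7]
    return None


def apply_read_level_filters(
    variants: list[VariantRecord], thresholds: FilterThresholds | None = None
) -> FilterReport:
    """Apply removal rules 1-8; removal is OR-over-rules, counts first-failing."""
    t = thresholds or FilterThresholds()
    retained: list[VariantRecord] = []
    rejections = {rule: 0 for rule in READ_LEVEL_RULES}
    for v in variants:
        rule = failing_rule(v, t)
        if rule is None:
            retained.append(v)
        else:
            rejections[rule] += 1
    return FilterReport(retained, rejections)


def apply_af_window(
    variants: list[VariantRecord], thresholds: FilterThresholds | None = None
) -> FilterReport:
    """Retain iff af_low < AF < af_high (strict both sides)."""
    t = thresholds or FilterThresholds()
    retained: list[VariantRecord] = []
    removed = 0
    for v in variants:
        v.require(("allele_freq",))
        if t.af_low < v.allele_freq < t.af_high:
            retained.append(v)
        else:
            removed += 1
    return FilterReport(retained, {AF_RULE: removed})


def apply_population_filter(
    variants: list[VariantRecord],
    thresholds: FilterThresholds | None = None,
    rescue: bool = True,
) -> FilterReport:
    """Remove variants common in any population database, with pathogenicity rescue.

    A variant whose frequency is >= ``pop_freq_max`` in any database is
    removed unless (``rescue``) it is ClinVar-pathogenic or carries a COSMIC
    urinary-cancer annotation, in which case it is retained and counted in
    ``rescued_count``.
    """
    t = thresholds or FilterThresholds()
    retained: list[VariantRecord] = []
    removed = 0
    rescued = 0
    for v in variants:
        common = any(f >= t.pop_freq_max for f in v.pop_freqs.values())
        if not common:
            retained.append(v)
        elif rescue and (v.clinvar_pathogenic or v.cosmic_urinary):
            retained.append(v)
            rescued += 1
        else:
            removed += 1
    return FilterReport(retained, {POP_RULE: removed}, rescued_count=rescued)


def filter_variants(
    variants: list[VariantRecord],
    thresholds: FilterThresholds | None = None,
    af_window: bool = True,
    rescue: bool = True,
) -> FilterReport:
    """Full post-calling filter: rules 1-8, then the AF window, then population.

    ``af_window=False`` is low-coverage mode (cell-free DNA): the AF window
    stage becomes the identity.  The combined report's rejection counts
    cover all stages and still partition the removed set.
    """
    t = thresholds or FilterThresholds()
    rep1 = apply_read_level_filters(variants, t)
    if af_window:
        rep2 = apply_af_window(rep1.retained, t)
    else:
        rep2 = FilterReport(rep1.retained, {AF_RULE: 0})
    rep3 = apply_population_filter(rep2.retained, t, rescue=rescue)
    rejections = {**rep1.rejections, **rep2.rejections, **rep3.rejections}
    return FilterReport(rep3.retained, rejections, rescued_count=rep3.rescued_count)
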