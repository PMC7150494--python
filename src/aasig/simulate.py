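"""Synthetic-data generators for every pipeline stage.

Everything here is seed-deterministic and returns its ground truth
alongside the data, so filtering, catalog construction, refitting,
subtyping and the clinical statistics can all be validated without any
external download.  Defaults mirror the study conditions: tumor catalogs
of ~20,000 SNVs from mixtures of reference signatures, cell-free DNA as
binomial thinning of the matched tumor catalog, cohorts of AA Sig /
No-AA Sig patients with subtype-dependent covariates and exponential
survival under independent exponential censoring.

Artifact variant records are drawn *just beyond* the corresponding filter
threshold (uniform in a narrow violating band) so strict-versus-inclusive
boundary semantics are genuinely exercised; true records are drawn
comfortably inside every passing band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clin_stats import SurvivalRecord
from .reference import CONTEXT_LABELS, SignatureMatrix
from .spectrum import MutationCatalog, classify_context, downsample_catalog
from .subtype import AA_SIG, NO_AA_SIG
from .variants import READ_LEVEL_RULES, VariantRecord

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: Artifact categories the variant generator can inject, beyond the eight
#: read-level rules: germline-like AF, FFPE-like low AF, and population-
#: database presence (germline het contaminants carry AF ~ 0.5 but a
#: database frequency above the removal cutoff).
ARTIFACT_KINDS = READ_LEVEL_RULES + ("af_germline", "af_ffpe", "pop_freq")

TRUE_LABEL = "true"


@dataclass
class SimCatalogConfig:
    """Signature-mixture catalog: n_mutations drawn from sum_k w_k P[:,k]."""

    n_mutations: int
    weights: dict[str, float]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mutations <= 0:
            raise ValueError("n_mutations must be positive")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")
        if any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative")


@dataclass
class AFModel:
    """Allele-frequency distributions for true and contaminant variants."""

    somatic_beta: tuple[float, float] = (20.0, 20.0)  # mean 0.5
    germline_low: float = 0.76   # germline-like AF band (hom / high purity)
    ffpe_high: float = 0.24      # FFPE-artifact AF band upper edge


@dataclass
class SimVariantConfig:
    """Read-level variant fixture: n_true clean records plus labeled artifacts."""

    n_true: int
    n_artifact: int
    artifact_profile: dict[str, float] = field(
        default_factory=lambda: {k: 1.0 / len(ARTIFACT_KINDS) for k in ARTIFACT_KINDS}
    )
    af_model: AFModel = field(default_factory=AFModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true < 0 or self.n_artifact < 0:
            raise ValueError("counts must be non-negative")
        if self.n_true + self.n_artifact == 0:
            raise ValueError("empty config: n_true + n_artifact must be positive")
        for k, p in self.artifact_profile.items():
            if k not in ARTIFACT_KINDS:
                raise ValueError(f"unknown artifact kind {k!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"artifact probability {p} outside [0, 1]")


@dataclass
class SimCohortConfig:
    """Clinical cohort: subtype-dependent binary covariates + exponential survival."""

    n_per_group: int
    covariate_effects: dict[str, float] = field(default_factory=dict)
    hazard_ratio: float = 3.0          # No-AA Sig vs AA Sig event hazard
    censor_rate: float = 0.3
    seed: int = 0
    baseline_hazard: float = 0.02      # AA Sig events per month
    baseline_prevalence: float = 0.3   # covariate prevalence in the No-AA group

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.hazard_ratio <= 0 or self.baseline_hazard <= 0:
            raise ValueError("hazards must be positive")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        for cov, odds in self.covariate_effects.items():
            if odds <= 0:
                raise ValueError(f"odds ratio for {cov!r} must be positive")


def simulate_catalog(config: SimCatalogConfig, signatures: SignatureMatrix) -> MutationCatalog:
    """Multinomial catalog from a signature mixture; deterministic under seed."""
    probs = np.zeros(96)
    for name, w in config.weights.items():
        probs += w * signatures.column(name)  # KeyError-style error on unknown label
    probs /= probs.sum()
    rng = np.random.default_rng(config.seed)
    counts = rng.multinomial(config.n_mutations, probs)
    return MutationCatalog(f"sim_n{config.n_mutations}_s{config.seed}", counts)


def simulate_tumor_cfdna_pair(
    tumor_config: SimCatalogConfig,
    cfdna_fraction: float,
    seed: int,
    signatures: SignatureMatrix,
) -> tuple[MutationCatalog, MutationCatalog]:
    """Matched tumor / cell-free DNA pair sharing one ground-truth AA weight.

    The cfDNA catalog is a binomial thinning of the tumor catalog --
    low-coverage calling loses mutations at random but leaves the expected
    spectrum shape unchanged.
    """
    if not 0.0 < cfdna_fraction <= 1.0:
        raise ValueError(f"cfdna_fraction must be in (0, 1], got {cfdna_fraction}")
    tumor = simulate_catalog(tumor_config, signatures)
    cfdna = downsample_catalog(tumor, cfdna_fraction, seed)
    cfdna.sample_id = tumor.sample_id + "_cfdna"
    return tumor, cfdna


def _passing_stats(rng: np.random.Generator) -> dict:
    """Read-level statistics comfortably inside every passing band."""
    return dict(
        dist_to_end_median=float(rng.uniform(15, 60)),
        dist_to_end_mad=float(rng.uniform(5, 20)),
        frac_low_mapq=float(rng.uniform(0.0, 0.05)),
        mapq_median_varreads=float(rng.uniform(50, 60)),
        baseq_median_varreads=float(rng.uniform(25, 40)),
        strand_frac_varreads=float(rng.uniform(0.3, 0.5)),
        strand_frac_allreads=float(rng.uniform(0.3, 0.5)),
        repeat_len_adjacent=int(rng.integers(0, 7)),
        nearby_variant_max=int(rng.integers(0, 3)),  # 2 is still allowed
    )


def _somatic_af(rng: np.random.Generator, af_model: AFModel) -> float:
    a, b = af_model.somatic_beta
    for _ in range(1000):
        af = float(rng.beta(a, b))
        if 0.25 < af < 0.75:
            return af
    raise RuntimeError("somatic AF distribution barely overlaps the window")


def _violate(stats: dict, kind: str, rng: np.random.Generator, af_model: AFModel) -> dict:
    """Overwrite exactly the statistic(s) that make the record fail ``kind``."""
    if kind == "rule1_dist_end_median":
        stats["dist_to_end_median"] = float(rng.uniform(0, 9.99))
    elif kind == "rule2_dist_end_mad":
        stats["dist_to_end_mad"] = float(rng.uniform(0, 2.99))
    elif kind == "rule3_frac_low_mapq":
        stats["frac_low_mapq"] = float(rng.uniform(0.101, 0.5))
    elif kind == "rule4_mapq_median":
        stats["mapq_median_varreads"] = float(rng.uniform(20, 39.9))
    elif kind == "rule5_baseq_median":
        stats["baseq_median_varreads"] = float(rng.uniform(5, 19.9))
    elif kind == "rule6_strand_bias":
        stats["strand_frac_varreads"] = float(rng.uniform(0.0, 0.019))
        stats["strand_frac_allreads"] = float(rng.uniform(0.21, 0.5))
    elif kind == "rule7_repeat_len":
        stats["repeat_len_adjacent"] = int(rng.integers(12, 21))
    elif kind == "rule8_nearby_variants":
        stats["nearby_variant_max"] = int(rng.integers(3, 11))
    elif kind == "af_germline":
        stats["allele_freq"] = float(rng.uniform(af_model.germline_low, 1.0))
    elif kind == "af_ffpe":
        stats["allele_freq"] = float(rng.uniform(0.01, af_model.ffpe_high))
    elif kind == "pop_freq":
        db = rng.choice(["1000g", "exac", "kaviar"])
        stats["pop_freqs"] = {str(db): float(rng.uniform(0.001, 0.5))}
    else:
        raise ValueError(f"unknown artifact kind {kind!r}")
    return stats


def simulate_variant_records(
    config: SimVariantConfig,
) -> tuple[list[VariantRecord], list[str]]:
    """Variant fixture with ground truth: returns (records, labels).

    ``labels[i]`` is ``"true"`` for records built to pass every filter, or
    the artifact kind the record was built to fail (and, by construction,
    the only one it fails).  Records are deterministically shuffled.
    """
    rng = np.random.default_rng(config.seed)
    bases = "ACGT"
    records: list[VariantRecord] = []
    labels: list[str] = []

    kinds = list(config.artifact_profile)
    probs = np.array([config.artifact_profile[k] for k in kinds], dtype=float)
    if config.n_artifact > 0:
        if probs.sum() <= 0:
            raise ValueError("artifact_profile has zero total probability")
        probs = probs / probs.sum()

    plan = [TRUE_LABEL] * config.n_true + [
        kinds[i]
        for i in rng.choice(len(kinds), size=config.n_artifact, p=probs if config.n_artifact else None)
    ]
    order = rng.permutation(len(plan))
    # spread variants >50bp apart so fixtures never interact through rule 8
    for i, j in enumerate(order):
        label = plan[j]
        stats = _passing_stats(rng)
        stats["allele_freq"] = _somatic_af(rng, config.af_model)
        stats["pop_freqs"] = {}
        if label != TRUE_LABEL:
            stats = _violate(stats, label, rng, config.af_model)
        ref = bases[rng.integers(4)]
        alt = rng.choice([b for b in bases if b != ref])
        records.append(
            VariantRecord(
                chrom="chr1",
                pos=1000 + 100 * i,
                ref=ref,
                alt=str(alt),
                callers=frozenset({"varscan2", "vardict"}),
                **stats,
            )
        )
        labels.append(label)
    return records, labels


def simulate_cohort(
    config: SimCohortConfig,
) -> tuple[pd.DataFrame, list[SurvivalRecord]]:
    """Clinical cohort with subtype-linked covariates and exponential survival.

    Binary covariates are Bernoulli per subtype: prevalence in the No-AA
    group is ``baseline_prevalence``; the AA-group odds are multiplied by
    the covariate's odds ratio.  Event times are exponential with the
    AA-group hazard ``baseline_hazard`` and the No-AA hazard scaled by
    ``hazard_ratio``; censoring is independent exponential with its rate
    set per group so the expected censored fraction equals ``censor_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_per_group
    subtypes = [AA_SIG] * n + [NO_AA_SIG] * n
    hazards = {AA_SIG: config.baseline_hazard,
               NO_AA_SIG: config.baseline_hazard * config.hazard_ratio}
    rows = []
    survival: list[SurvivalRecord] = []
    p0 = config.baseline_prevalence
    odds0 = p0 / (1 - p0)
    for i, subtype in enumerate(subtypes):
        sid = f"P{i:04d}"
        row: dict = {"sample_id": sid, "subtype": subtype}
        for cov, oratio in config.covariate_effects.items():
            odds = odds0 * oratio if subtype == AA_SIG else odds0
            p = odds / (1 + odds)
            row[cov] = "Present" if rng.random() < p else "Absent"
        lam = hazards[subtype]
        t_event = float(rng.exponential(1.0 / lam))
        if config.censor_rate > 0:
            c_rate = lam * config.censor_rate / (1 - config.censor_rate)
            t_cens = float(rng.exponential(1.0 / c_rate))
        else:
            t_cens = np.inf
        time = max(min(t_event, t_cens), 1e-6)
        event = t_event <= t_cens
        row["time"] = time
        row["event"] = event
        rows.append(row)
        survival.append(SurvivalRecord(sid, time, event, subtype))
    return pd.DataFrame(rows), survival


# ---------------------------------------------------------------------------
# Sequence-level fixtures: a synthetic genome plus variants whose flanking
# context realizes a requested signature mixture, for exercising catalog
# construction from VCF + FASTA.
# ---------------------------------------------------------------------------

def simulate_genome(length: int, seed: int = 0, gc: float = 0.4) -> str:
    """Random genome sequence with the given GC content."""
    if length < 3:
        raise ValueError("genome must be at least 3 bases")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _revcomp(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def simulate_wgs_sample(
    n_mutations: int,
    weights: dict[str, float],
    signatures: SignatureMatrix,
    genome: str,
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[list[VariantRecord], np.ndarray]:
    """Place signature-mixture SNVs onto a genome; returns (records, class tally).

    Each drawn 96-class is realized at a genome position whose trinucleotide
    matches the class on either strand (the alternate allele is
    complemented on the reverse strand), so rebuilding the catalog from the
    emitted VCF plus the genome must reproduce the returned tally exactly.
    Read-level statistics are drawn from the all-passing bands.
    """
    cfg = SimCatalogConfig(n_mutations, weights, seed)
    catalog = simulate_catalog(cfg, signatures)
    rng = np.random.default_rng(seed + 1)
    # index genome positions by trinucleotide (1-based center position)
    by_tri: dict[str, list[int]] = {}
    for i in range(1, len(genome) - 1):
        by_tri.setdefault(genome[i - 1 : i + 2], []).append(i + 1)
    used: set[int] = set()
    records: list[VariantRecord] = []
    for idx in np.flatnonzero(catalog.counts):
        label = CONTEXT_LABELS[idx]  # e.g. "A[C>T]G"
        five, ref, alt, three = label[0], label[2], label[4], label[6]
        fwd = five + ref + three
        rev = _revcomp(fwd)
        candidates = [(p, alt) for p in by_tri.get(fwd, [])]
        if rev != fwd:
            candidates += [(p, _COMPLEMENT[alt]) for p in by_tri.get(rev, [])]
        candidates = [(p, a) for p, a in candidates if p not in used]
        need = int(catalog.counts[idx])
        if len(candidates) < need:
            raise ValueError(
                f"genome too short to place {need} mutations of class {label}; "
                "increase genome length"
            )
        chosen = rng.choice(len(candidates), size=need, replace=False)
        for c in chosen:
            pos, alt_here = candidates[c]
            used.add(pos)
            stats = _passing_stats(rng)
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=pos,
                    ref=genome[pos - 1],
                    alt=alt_here,
                    allele_freq=_somatic_af(rng, AFModel()),
                    callers=frozenset({"varscan2", "vardict"}),
                    **stats,
                )
            )
    records.sort(key=lambda r: r.pos)
    return records, catalog.counts.copy()
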