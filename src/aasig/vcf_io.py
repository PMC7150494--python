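"""VCF input/output for annotated somatic SNV candidates.

Per-variant read-level features travel as INFO keys (all required unless
noted).  Key dictionary:

===========  =============================================================
INFO key     VariantRecord field
===========  =============================================================
DEM          dist_to_end_median (Float, bases)
DEMAD        dist_to_end_mad (Float, bases)
FLMQ         frac_low_mapq (Float)
MQM          mapq_median_varreads (Float, Phred)
BQM          baseq_median_varreads (Float, Phred)
SBV          strand_frac_varreads (Float, minority-strand fraction)
SBA          strand_frac_allreads (Float, minority-strand fraction)
REPLEN       repeat_len_adjacent (Integer, bases)
NBVAR        nearby_variant_max (Integer)
VAF          allele_freq (Float)
PF_<DB>      population frequency in <DB>, optional; DB one of
             1000G, EXAC, ESP6500, HRC, KAVIAR, PANEL
CLNPATH      clinvar_pathogenic (Flag, optional)
COSURI       cosmic_urinary (Flag, optional)
CALLERS      pipe-joined caller names (String, optional)
===========  =============================================================
"""

from __future__ import annotations

import os
from typing import Iterable

import pysam

from .variants import POPULATION_DATABASES, VariantRecord

_REQUIRED_INFO = {
    "DEM": "dist_to_end_median",
    "DEMAD": "dist_to_end_mad",
    "FLMQ": "frac_low_mapq",
    "MQM": "mapq_median_varreads",
    "BQM": "baseq_median_varreads",
    "SBV": "strand_frac_varreads",
    "SBA": "strand_frac_allreads",
    "REPLEN": "repeat_len_adjacent",
    "NBVAR": "nearby_variant_max",
    "VAF": "allele_freq",
}

_INFO_HEADER = [
    ('DEM', '1', 'Float', 'Median shortest distance of variant position to either aligned read end'),
    ('DEMAD', '1', 'Float', 'MAD of shortest distance of variant position to either aligned read end'),
    ('FLMQ', '1', 'Float', 'Fraction of reads at the position with mapping quality < 1'),
    ('MQM', '1', 'Float', 'Median mapping quality of variant-supporting reads'),
    ('BQM', '1', 'Float', 'Median base quality at the variant position over variant reads'),
    ('SBV', '1', 'Float', 'Minority-strand fraction of variant reads'),
    ('SBA', '1', 'Float', 'Minority-strand fraction of all covering reads'),
    ('REPLEN', '1', 'Integer', 'Length of adjacent 1-4mer repeat tract in bases'),
    ('NBVAR', '1', 'Integer', 'Largest number of other variant positions in any surrounding 50bp window'),
    ('VAF', '1', 'Float', 'Variant allele frequency'),
    ('CLNPATH', '0', 'Flag', 'ClinVar pathogenic'),
    ('COSURI', '0', 'Flag', 'COSMIC urinary-cancer annotated'),
    ('CALLERS', '1', 'String', 'Pipe-joined caller names reporting this variant'),
] + [
    (f'PF_{db.upper()}', '1', 'Float', f'Population allele frequency in {db}')
    for db in POPULATION_DATABASES
]


def read_variants(path: str | os.PathLike) -> list[VariantRecord]:
    """Parse a VCF of annotated SNV candidates into VariantRecords.

    Raises ``ValueError`` on the first record missing any required INFO key,
    listing every missing key for that record.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"{rec.chrom}:{rec.pos}: expected exactly one ALT allele"
                )
            info = rec.info
            missing = [k for k in _REQUIRED_INFO if k not in info]
            if missing:
                raise ValueError(
                    f"{rec.chrom}:{rec.pos} {rec.ref}>{rec.alts[0]}: "
                    "missing required INFO key(s): " + ", ".join(missing)
                )
            kwargs = {field: _scalar(info[key]) for key, field in _REQUIRED_INFO.items()}
            kwargs["repeat_len_adjacent"] = int(kwargs["repeat_len_adjacent"])
            kwargs["nearby_variant_max"] = int(kwargs["nearby_variant_max"])
            pop = {}
            for db in POPULATION_DATABASES:
                key = f"PF_{db.upper()}"
                if key in info:
                    pop[db] = float(_scalar(info[key]))
            callers = frozenset()
            if "CALLERS" in info:
                callers = frozenset(str(_scalar(info["CALLERS"])).split("|"))
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    pop_freqs=pop,
                    clinvar_pathogenic=bool(info.get("CLNPATH", False)),
                    cosmic_urinary=bool(info.get("COSURI", False)),
                    callers=callers,
                    **kwargs,
                )
            )
    return records


def _scalar(value):
    if isinstance(value, tuple):
        (value,) = value
    return value


def _build_header(contigs: Iterable[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for contig in contigs:
        header.contigs.add(contig)
    for key, number, vtype, desc in _INFO_HEADER:
        header.info.add(key, number, vtype, desc)
    return header


def write_variants(path: str | os.PathLike, variants: list[VariantRecord]) -> None:
    """Write VariantRecords as an uncompressed VCF with the documented INFO keys."""
    contigs: list[str] = []
    for v in variants:
        if v.chrom not in contigs:
            contigs.append(v.chrom)
    header = _build_header(contigs)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in variants:
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos,
                alleles=(v.ref, v.alt),
            )
            for key, field in _REQUIRED_INFO.items():
                value = getattr(v, field)
                if value is None:
                    raise ValueError(
                        f"variant {v.key_str()} is missing feature field(s): {field}"
                    )
                rec.info[key] = value
            for db, f in v.pop_freqs.items():
                rec.info[f"PF_{db.upper()}"] = f
            if v.clinvar_pathogenic:
                rec.info["CLNPATH"] = True
            if v.cosmic_urinary:
                rec.info["COSURI"] = True
            if v.callers:
                rec.info["CALLERS"] = "|".join(sorted(v.callers))
            out.write(rec)


def write_rejection_summary(path: str | os.PathLike, rejections: dict[str, int]) -> None:
    """Tab-delimited per-rule rejection counts (rule id, count)."""
    with open(path, "w") as fh:
        fh.write("rule\tcount\n")
        for rule, count in rejections.items():
            fh.write(f"{rule}\t{count}\n")
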