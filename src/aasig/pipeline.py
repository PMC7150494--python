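"""End-to-end orchestration: filter -> catalog -> refit -> merge -> subtype -> stats.

A run is described by a single :class:`RunConfig` (loadable from YAML),
executes stage by stage with per-stage logging, writes every intermediate
artifact under stable filenames, and ends with a JSON manifest recording
the seed, thresholds and per-stage counters.  Re-running an identical
config reproduces identical outputs (all stochastic stages are seeded).

Modes: ``tumor`` (full filters, cohort clustering when >= 2 samples),
``cfdna`` and ``low_coverage`` (the allele-frequency window is disabled --
AF estimates at ~1x coverage are uninformative -- and subtype calls use
the screening thresholds instead of clustering).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clin_stats import SurvivalRecord, build_table_one, km_estimate, logrank_test
from .refit import MergeMap, SignatureRefitter
from .reference import load_signature_matrix, synthetic_signature_matrix
from .spectrum import build_catalog, read_catalogs, write_catalogs
from .subtype import ScreeningThresholds, SubtypeClusterer, classify_threshold
from .variants import FilterThresholds, filter_variants
from .vcf_io import read_variants, write_rejection_summary, write_variants

logger = logging.getLogger("aasig")

MODES = ("tumor", "cfdna", "low_coverage")


@dataclass
class RunConfig:
    """Inputs, thresholds and options for one pipeline run."""

    output_dir: str
    mode: str = "tumor"
    seed: int = 0
    vcfs: dict[str, str] = field(default_factory=dict)   # sample_id -> VCF path
    fasta: str | None = None
    catalogs: str | None = None            # catalog TSV, alternative to vcfs+fasta
    signature_matrix: str | None = None    # COSMIC-layout TSV; default synthetic
    merge_map: str | None = None
    clinical: str | None = None            # CSV with covariates (+ time/event)
    covariates: list[str] | None = None
    filter_thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    screening_thresholds: ScreeningThresholds = field(default_factory=ScreeningThresholds)
    clustering: dict = field(default_factory=dict)  # SubtypeClusterer kwargs
    chrom_style: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    @property
    def af_window_enabled(self) -> bool:
        return self.mode == "tumor"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "filter_thresholds" in raw:
            raw["filter_thresholds"] = FilterThresholds(**raw["filter_thresholds"])
        if "screening_thresholds" in raw:
            raw["screening_thresholds"] = ScreeningThresholds(**raw["screening_thresholds"])
        return cls(**raw)

    def validate(self) -> None:
        if not self.vcfs and not self.catalogs:
            raise ValueError("config lists no samples: provide 'vcfs' or 'catalogs'")
        if self.vcfs and not self.fasta:
            raise ValueError("VCF input requires a reference 'fasta'")
        for label, path in [
            *((f"vcf[{s}]", p) for s, p in self.vcfs.items()),
            ("fasta", self.fasta),
            ("catalogs", self.catalogs),
            ("signature_matrix", self.signature_matrix),
            ("merge_map", self.merge_map),
            ("clinical", self.clinical),
        ]:
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{label}: {path} does not exist")


class StageError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured run; returns (and writes) the manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "mode": config.mode,
        "seed": config.seed,
        "thresholds": {
            "filter": dataclasses.asdict(config.filter_thresholds),
            "screening": dataclasses.asdict(config.screening_thresholds),
        },
        "stages": {},
        "outputs": [],
    }

    def record(stage: str, **counters) -> None:
        manifest["stages"][stage] = counters
        logger.info("stage %s: %s", stage, counters)

    def emit(path: Path) -> Path:
        manifest["outputs"].append(str(path.relative_to(out)))
        return path

    # --- filter + catalog ---------------------------------------------------
    if config.vcfs:
        import pyfaidx

        reference = pyfaidx.Fasta(config.fasta)
        catalogs = []
        for sample_id, vcf_path in config.vcfs.items():
            try:
                variants = read_variants(vcf_path)
                report = filter_variants(
                    variants,
                    config.filter_thresholds,
                    af_window=config.af_window_enabled,
                )
                write_variants(emit(out / f"{sample_id}.filtered.vcf"), report.retained)
                write_rejection_summary(
                    emit(out / f"{sample_id}.rejections.tsv"), report.rejections
                )
                catalogs.append(
                    build_catalog(
                        report.retained, reference, sample_id,
                        chrom_style=config.chrom_style,
                    )
                )
            except Exception as exc:  # abort naming stage and sample
                raise StageError("filter", f"sample {sample_id}: {exc}") from exc
            record(
                f"filter[{sample_id}]",
                variants_in=len(variants),
                variants_out=len(report.retained),
                rescued=report.rescued_count,
            )
        write_catalogs(emit(out / "catalogs.tsv"), catalogs)
        record("catalog", samples=len(catalogs),
               totals={c.sample_id: c.total for c in catalogs})
    else:
        try:
            catalogs = read_catalogs(config.catalogs)
        except Exception as exc:
            raise StageError("catalog", str(exc)) from exc
        record("catalog", samples=len(catalogs),
               totals={c.sample_id: c.total for c in catalogs})

    if not catalogs:
        raise StageError("catalog", "no samples to process")

    # --- refit + merge ------------------------------------------------------
    try:
        signatures = (
            load_signature_matrix(config.signature_matrix)
            if config.signature_matrix
            else synthetic_signature_matrix()
        )
        merge_map = (
            MergeMap.from_file(config.merge_map)
            if config.merge_map
            else MergeMap.default(signatures.names)
        )
        sample_ids = [c.sample_id for c in catalogs]
        X = np.vstack([c.counts for c in catalogs])
        refitter = SignatureRefitter(signatures=signatures, merge_map=merge_map).fit(X)
        raw = refitter.transform(X)
        merged = refitter.transform_merged(X)
        aa_props = refitter.aa_proportion(X)
    except Exception as exc:
        raise StageError("refit", str(exc)) from exc
    pd.DataFrame(raw, index=sample_ids, columns=signatures.names).rename_axis(
        "sample_id"
    ).to_csv(emit(out / "exposures_raw.tsv"), sep="\t")
    merged_df = pd.DataFrame(
        merged, index=sample_ids, columns=refitter.group_names_
    ).rename_axis("sample_id")
    merged_df.to_csv(emit(out / "exposures_merged.tsv"), sep="\t")
    record("refit", samples=len(sample_ids),
           total_exposure=float(raw.sum()))

    # --- subtype ------------------------------------------------------------
    try:
        if config.mode == "tumor" and len(catalogs) >= 2:
            clusterer = SubtypeClusterer(
                aa_index=refitter.group_names_.index("AA"), **config.clustering
            ).fit(merged)
            calls = clusterer.predict_calls(sample_ids)
            pd.Series(
                np.array(sample_ids)[clusterer.dendrogram_order_], name="sample_id"
            ).to_csv(emit(out / "dendrogram_order.tsv"), sep="\t", index=False)
        else:
            context = "tumor" if config.mode == "tumor" else "cfdna"
            calls = [
                classify_threshold(
                    float(p), context, config.screening_thresholds, sample_id=sid
                )
                for sid, p in zip(sample_ids, aa_props)
            ]
    except Exception as exc:
        raise StageError("subtype", str(exc)) from exc
    subtype_df = pd.DataFrame(
        {
            "sample_id": [c.sample_id for c in calls],
            "label": [c.label for c in calls],
            "aa_proportion": [round(c.aa_proportion, 6) for c in calls],
            "method": [c.method for c in calls],
            "indeterminate": [c.indeterminate for c in calls],
        }
    )
    subtype_df.to_csv(emit(out / "subtypes.tsv"), sep="\t", index=False)
    record("subtype", n_aa=int((subtype_df["label"] == "AA Sig").sum()),
           n_no_aa=int((subtype_df["label"] == "No-AA Sig").sum()))

    # --- clinical statistics ------------------------------------------------
    if config.clinical:
        try:
            cohort = pd.read_csv(config.clinical)
            if "subtype" not in cohort.columns:
                cohort = cohort.merge(
                    subtype_df[["sample_id", "label"]].rename(columns={"label": "subtype"}),
                    on="sample_id",
                )
            covs = config.covariates or [
                c for c in cohort.columns
                if c not in ("sample_id", "subtype", "time", "event")
            ]
            table_one = build_table_one(cohort, covariates=covs)
            table_one.to_csv(emit(out / "table_one.tsv"), sep="\t", index=False)
            counters = {"covariates": len(covs)}
            if {"time", "event"} <= set(cohort.columns):
                records = [
                    SurvivalRecord(str(r.sample_id), float(r.time), bool(r.event),
                                   str(r.subtype))
                    for r in cohort.itertuples()
                ]
                for group in sorted({r.group for r in records}):
                    km = km_estimate([r for r in records if r.group == group])
                    safe = group.replace(" ", "_").replace("/", "_")
                    km.to_frame().to_csv(
                        emit(out / f"km_{safe}.tsv"), sep="\t", index=False
                    )
                stat, p = logrank_test(records)
                counters.update(logrank_statistic=round(stat, 6),
                                logrank_p=round(p, 6))
            record("clin_stats", **counters)
        except Exception as exc:
            raise StageError("clin_stats", str(exc)) from exc

    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
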