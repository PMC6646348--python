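"""End-to-end pipeline: load -> QC -> association -> reports.

Deterministic given inputs and seed; every stage failure aborts with a
stage-labelled message and a distinct exit status.  Reports are plain
TSV; run provenance (config hash, seed, package version) goes into a
JSON manifest so the TSVs themselves stay byte-stable across reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .assoc import assoc_table
from .io import read_bed, read_long_export, read_pedmap
from .qc import (
    QCThresholds,
    apply_qc,
    diff_missing_test,
    freq_report_frame,
    hwe_report_frame,
    hwe_table,
    missing_report_frame,
    sex_allele_freq_test,
)

logger = logging.getLogger(__name__)

EXIT_OK = 0
EXIT_INPUT_ERROR = 2
EXIT_EMPTY_PANEL = 3
EXIT_INTERNAL = 4


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    input_path: str  # bed/ped prefix or long-format export file
    input_format: str = "bed"  # bed | pedmap | long
    out_dir: str = "xchrom_out"
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    xci_model: str = "inactivation"
    phenotypes: list[str] | None = None
    phenotype_file: str | None = None  # TSV: sample_id + trait columns
    seed: int = 0
    log_level: str = "INFO"

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str, exit_code: int):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = exit_code


def _load(config: RunConfig):
    readers = {"bed": read_bed, "pedmap": read_pedmap, "long": read_long_export}
    if config.input_format not in readers:
        raise StageError("load", f"unknown input format {config.input_format!r}", EXIT_INPUT_ERROR)
    try:
        cohort = readers[config.input_format](config.input_path)
    except (OSError, ValueError) as exc:
        raise StageError("load", str(exc), EXIT_INPUT_ERROR) from exc
    if config.phenotype_file:
        try:
            table = pd.read_csv(config.phenotype_file, sep="\t").set_index("sample_id")
            cohort.quantitative_phenotypes = table.reindex(cohort.sample_ids)
        except (OSError, KeyError, ValueError) as exc:
            raise StageError("load", f"phenotype file: {exc}", EXIT_INPUT_ERROR) from exc
    return cohort


def pipeline_run(config: RunConfig) -> tuple[int, dict]:
    """Run convert -> QC -> associate -> report; returns (exit code, manifest)."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": [],
    }
    try:
        cohort = _load(config)
        manifest["stages"].append({"stage": "load", "n_samples": cohort.n_samples, "n_snps": cohort.n_snps})
        logger.info("[load] %d samples x %d SNPs", cohort.n_samples, cohort.n_snps)

        try:
            missing_report_frame(diff_missing_test(cohort)).to_csv(
                out / "qc_missing.tsv", sep="\t", index=False
            )
            freq_report_frame(sex_allele_freq_test(cohort)).to_csv(
                out / "qc_freq.tsv", sep="\t", index=False
            )
            hwe_report_frame(hwe_table(cohort)).to_csv(out / "qc_hwe.tsv", sep="\t", index=False)
            filtered, report = apply_qc(cohort, config.thresholds)
            report.decisions.to_csv(out / "qc_decisions.tsv", sep="\t", index=False)
        except ValueError as exc:
            raise StageError("qc", str(exc), EXIT_INPUT_ERROR) from exc
        manifest["stages"].append(
            {
                "stage": "qc",
                "excluded_snps": report.excluded_snps,
                "male_het_incidents": len(report.male_het_incidents),
            }
        )
        logger.info("[qc] excluded %d SNP(s)", len(report.excluded_snps))

        if filtered.n_snps == 0:
            manifest["stages"].append({"stage": "assoc", "status": "skipped: QC removed all SNPs"})
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
            logger.warning("[assoc] skipped: QC emptied the SNP panel")
            return EXIT_EMPTY_PANEL, manifest

        table = assoc_table(filtered, config.phenotypes, config.xci_model)
        table.to_csv(out / "assoc.tsv", sep="\t", index=False, float_format="%.6g")
        manifest["stages"].append({"stage": "assoc", "n_results": len(table)})
        logger.info("[assoc] %d (SNP, phenotype) results", len(table))

        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return EXIT_OK, manifest
    except StageError as exc:
        logger.error("%s", exc)
        manifest["stages"].append({"stage": exc.stage, "error": str(exc)})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return exc.exit_code, manifest
    except Exception as exc:  # pragma: no cover - defensive
        logger.exception("internal error")
        manifest["stages"].append({"stage": "internal", "error": str(exc)})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return EXIT_INTERNAL, manifest
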