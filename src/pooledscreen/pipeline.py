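"""End-to-end orchestration: per-patient screens → QC gate → pooled re-analysis.

The pipeline mirrors the screen's analysis path: every patient's Day 0/Day
20 pair is analyzed on its own; screens are gated on positive-control
depletion; the surviving screens are re-analyzed together, restarting from
the raw read counts with joint normalization and pooled per-gene grouping;
candidate dependencies are nominated at q < 0.05 and log2 FC < −0.2 and a
volcano-format table (gene, log2 FC, −log10 q) is exported.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .counts import CountTable
from .errors import InvalidConfigError, InvalidInputError
from .genestats import AnalysisConfig, analyze_screen, call_hits, pooled_analyze
from .manifest import LibraryManifest
from .qc import ScreenQCReport, assess_success, coverage
from .simulate import SimConfig, simulate_cohort

log = logging.getLogger("pooledscreen")

STATUS_OK = "ok"
STATUS_NO_SUCCESS = "no-successful-screens"
STATUS_TOO_FEW = "insufficient-successful-screens"


@dataclass
class RunConfig:
    """Validated run configuration (YAML-friendly).

    ``mode="simulate"`` generates a cohort from ``sim``; ``mode="counts"``
    loads a manifest and per-patient count TSVs from ``samples``.
    """

    mode: str = "simulate"
    seed: int = 0
    n_patients: int = 9
    coverages: list[float] | None = None
    spike: dict[str, float] | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    manifest_path: str | None = None
    samples: list[dict] | None = None  # [{patient, counts, samples?}]

    def __post_init__(self):
        if self.mode not in ("simulate", "counts"):
            raise InvalidConfigError(f"mode must be simulate|counts, got {self.mode!r}")
        if self.mode == "counts":
            if not self.manifest_path or not self.samples:
                raise InvalidConfigError("counts mode requires manifest_path and samples")
            for entry in self.samples:
                if not Path(entry["counts"]).exists():
                    raise InvalidConfigError(f"counts file not found: {entry['counts']}")
            if not Path(self.manifest_path).exists():
                raise InvalidConfigError(f"manifest not found: {self.manifest_path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        analysis = AnalysisConfig(**raw.pop("analysis", {}))
        return cls(sim=sim, analysis=analysis, **raw)


def export_volcano(results: pd.DataFrame) -> pd.DataFrame:
    """Volcano-format table: gene, log2_fc, −log10 q, role.

    A q-value of exactly 0 is clamped to the smallest positive double before
    the log, so the export stays finite.
    """
    if results.empty:
        raise InvalidInputError("export_volcano requires non-empty results")
    q = np.maximum(results["q_value"].to_numpy(float), np.finfo(float).tiny)
    return pd.DataFrame(
        {
            "gene": results["gene"],
            "log2_fc": results["log2_fc"],
            "neg_log10_q": -np.log10(q),
            "role": results["role"],
        }
    )


def _load_tables(config: RunConfig) -> tuple[LibraryManifest, list[CountTable]]:
    manifest = LibraryManifest.from_tsv(config.manifest_path)
    tables = []
    for entry in config.samples:
        tables.append(
            CountTable.from_tsv(
                entry["counts"], samples_path=entry.get("samples"), manifest=manifest
            )
        )
    return manifest, tables


def _qc_for(
    results: pd.DataFrame, table: CountTable, manifest: LibraryManifest,
    patient: str, acfg: AnalysisConfig,
) -> ScreenQCReport:
    covs = {}
    for tp in ("D0", "D20"):
        cells = table.samples.loc[f"{patient}_{tp}", "cells_collected"]
        covs[tp] = coverage(float(cells), manifest.n_shrnas) if pd.notna(cells) else float("nan")
    return assess_success(
        results, manifest, patient=patient,
        coverage_d0=covs["D0"], coverage_d20=covs["D20"],
        q_max=acfg.q_max, logfc_max=acfg.logfc_max,
    )


def run_screen_pipeline(config: RunConfig, outdir) -> dict:
    """Run the full pipeline and write all artifacts under ``outdir``.

    Writes per-patient result TSVs and QC JSONs always; the pooled results,
    candidate list and volcano TSV only when ≥ 2 screens pass the gate.
    Returns a summary dict with the gate decisions and output paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    acfg = config.analysis

    if config.mode == "simulate":
        manifest, truth, tables = simulate_cohort(
            config.sim, config.n_patients, seed=config.seed,
            coverages=config.coverages, spike=config.spike,
        )
        manifest.to_tsv(outdir / "manifest.tsv")
    else:
        manifest, tables = _load_tables(config)

    summary: dict = {"status": STATUS_OK, "patients": [], "successful": []}
    successful_tables = []
    for table in tables:
        patient = table.patients[0]
        log.info("analyze patient=%s shape=%s test=%s", patient,
                 tuple(table.counts.shape), acfg.test)
        results = analyze_screen(table, manifest, acfg, patient=patient)
        results.to_csv(outdir / f"results_{patient}.tsv", sep="\t", index=False,
                       float_format="%.6g")
        report = _qc_for(results, table, manifest, patient, acfg)
        report.to_json(outdir / f"qc_{patient}.json")
        log.info("gate patient=%s success=%s (%s)", patient, report.success, report.reason)
        summary["patients"].append(
            {"patient": patient, "success": report.success,
             "coverage_d0": report.coverage_d0, "reason": report.reason}
        )
        if report.success:
            summary["successful"].append(patient)
            successful_tables.append(table)

    n_ok = len(successful_tables)
    if n_ok == 0:
        summary["status"] = STATUS_NO_SUCCESS
        warnings.warn("no screen passed the positive-control gate; pooled stage skipped")
    elif n_ok == 1:
        summary["status"] = STATUS_TOO_FEW
        warnings.warn("only one successful screen; pooled stage skipped")
    else:
        log.info("pooled re-analysis over %d screens (from raw counts)", n_ok)
        pooled = pooled_analyze(successful_tables, manifest, acfg)
        pooled.to_csv(outdir / "pooled_results.tsv", sep="\t", index=False,
                      float_format="%.6g")
        hits = call_hits(pooled, q_max=acfg.q_max, logfc_max=acfg.logfc_max)
        hits.candidates.to_csv(outdir / "candidates.tsv", sep="\t", index=False,
                               float_format="%.6g")
        export_volcano(pooled).to_csv(outdir / "volcano.tsv", sep="\t", index=False,
                                      float_format="%.6g")
        summary["n_candidates"] = int(len(hits.candidates))
        summary["depleted_controls"] = hits.controls["gene"].tolist()

    run_manifest = {
        "seed": config.seed,
        "mode": config.mode,
        "analysis": dataclasses.asdict(acfg),
        "thresholds": {"q_max": acfg.q_max, "logfc_max": acfg.logfc_max},
        "summary": {k: v for k, v in summary.items() if k != "patients"},
        "gate": summary["patients"],
    }
    if config.mode == "simulate":
        run_manifest["sim"] = dataclasses.asdict(config.sim)
        run_manifest["n_patients"] = config.n_patients
        run_manifest["coverages"] = config.coverages
        run_manifest["spike"] = config.spike
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, default=float)
    return summary
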