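"""Screen quality control: library coverage and the positive-control success gate.

A screen in primary cells has no biological replicates, so technical
success is judged by the behavior of known common-essential positive
controls (proteasome/ribosome genes): a screen passes the gate when at
least one positive-control gene is significantly depleted (q < 0.05 and
log2 FC < −0.2). The non-targeting negative control is reported but can
never trigger success. Only gated screens enter the pooled re-analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .errors import InvalidConfigError, InvalidInputError
from .genestats import DEFAULT_LOGFC_MAX, DEFAULT_Q_MAX
from .manifest import LibraryManifest


def coverage(n_cells: float, library_size: int) -> float:
    """Fold library representation: cells per library element (e.g. 60×).

    Uses cells collected for gDNA isolation, the quantity that actually
    bounds the number of shRNA observations sequenced.
    """
    if library_size <= 0:
        raise InvalidConfigError("library_size must be positive")
    if n_cells < 0:
        raise InvalidConfigError("n_cells must be non-negative")
    if n_cells == 0:
        warnings.warn("0 cells collected; coverage is 0x")
    return n_cells / library_size


@dataclass
class ScreenQCReport:
    """Per-screen QC: coverage at both timepoints and the success decision."""

    patient: str
    coverage_d0: float
    coverage_d20: float
    control_results: pd.DataFrame = field(repr=False)
    success: bool = False
    reason: str = ""

    def to_dict(self) -> dict:
        return {
            "patient": self.patient,
            "coverage_d0": self.coverage_d0,
            "coverage_d20": self.coverage_d20,
            "success": self.success,
            "reason": self.reason,
            "controls": self.control_results.to_dict(orient="records"),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def assess_success(
    results: pd.DataFrame,
    manifest: LibraryManifest,
    patient: str = "",
    coverage_d0: float = float("nan"),
    coverage_d20: float = float("nan"),
    q_max: float = DEFAULT_Q_MAX,
    logfc_max: float = DEFAULT_LOGFC_MAX,
) -> ScreenQCReport:
    """Apply the screen-success rule to one screen's per-gene results.

    Success ⟺ at least one *positive*-control gene has q < q_max and
    log2 FC < logfc_max (strict). All five positive controls must be present
    in the results; the negative control is included in the report but never
    counts toward success.
    """
    pos = manifest.positive_controls
    neg = manifest.negative_controls
    present = set(results["gene"])
    absent = [g for g in pos if g not in present]
    if absent:
        raise InvalidInputError(f"results missing positive-control genes: {absent}")
    controls = results.loc[results["gene"].isin(pos + neg)].reset_index(drop=True)
    posr = controls.loc[controls["gene"].isin(pos)]
    qualifying = posr.loc[
        (posr["q_value"] < q_max) & (posr["log2_fc"] < logfc_max), "gene"
    ].tolist()
    if qualifying:
        reason = (
            "positive control(s) significantly depleted "
            f"(q < {q_max}, log2 FC < {logfc_max}): {', '.join(qualifying)}"
        )
    else:
        reason = (
            f"no positive-control gene met q < {q_max} and log2 FC < {logfc_max}"
        )
    return ScreenQCReport(
        patient=patient,
        coverage_d0=coverage_d0,
        coverage_d20=coverage_d20,
        control_results=controls,
        success=bool(qualifying),
        reason=reason,
    )
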