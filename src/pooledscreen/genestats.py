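"""Per-gene depletion statistics and hit calling.

The unit of inference is the gene: all normalized log2-CPM observations of
its shRNAs at Day 0 form one group and those at Day 20 the other (in pooled
mode the groups concatenate over all successful screens, ~12 shRNAs ×
patients per group). A two-sample test (Wilcoxon rank-sum by default,
Welch's t optional) yields a per-gene p-value; fold change is the log2
ratio of Day 20 to Day 0 mean linear CPM; multiplicity is handled with both
Benjamini–Hochberg FDR-adjusted p-values and Storey q-values. A gene is a
candidate dependency when q < 0.05 and log2 FC < −0.2 (strict).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts import CountTable, concat_tables
from .errors import InsufficientInputError, InvalidConfigError, InvalidInputError
from .manifest import ROLE_TARGET, LibraryManifest
from .normalize import (
    DEFAULT_ITERATIONS,
    DEFAULT_PSEUDOCOUNT,
    DEFAULT_SPAN,
    NormalizedTable,
    linear_cpm,
    normalize_table,
)
from .stats import (
    DEFAULT_EXACT_CUTOFF,
    DEFAULT_LAMBDA_GRID,
    bh_adjust,
    storey_q,
    welch_t,
    wilcoxon_rank_sum,
)

TESTS = ("wilcoxon", "welch_t")

RESULT_COLUMNS = [
    "gene", "role", "n_d0", "n_d20", "log2_fc",
    "p_value", "fdr_p", "q_value", "test_used",
]

DEFAULT_Q_MAX = 0.05
DEFAULT_LOGFC_MAX = -0.2


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the per-gene analysis."""

    test: str = "wilcoxon"
    pseudocount: float = DEFAULT_PSEUDOCOUNT   # added to CPM before log2
    fc_pseudo: float = DEFAULT_PSEUDOCOUNT     # added to group means in the FC ratio
    span: float = DEFAULT_SPAN
    iterations: int = DEFAULT_ITERATIONS
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    exact_cutoff: int = DEFAULT_EXACT_CUTOFF
    q_max: float = DEFAULT_Q_MAX
    logfc_max: float = DEFAULT_LOGFC_MAX

    def __post_init__(self):
        if self.test not in TESTS:
            raise InvalidConfigError(f"test must be one of {TESTS}, got {self.test!r}")
        if not 0 < self.q_max < 1:
            raise InvalidConfigError("q_max must be in (0,1)")
        if self.logfc_max >= 0:
            raise InvalidConfigError("logfc_max must be negative (depletion threshold)")


def gene_group(
    norm: NormalizedTable,
    manifest: LibraryManifest,
    patients: list[str] | None = None,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-gene (Day 0 values, Day 20 values) over the selected patients.

    Per-patient mode passes one patient; pooled mode concatenates the
    observations of every selected patient, which is what raises power for
    shared dependencies.
    """
    patients = patients if patients is not None else norm.patients
    have = set(norm.patients)
    missing = [p for p in patients if p not in have]
    if missing:
        raise InvalidInputError(f"patients not in table: {missing}")
    d0_cols, d20_cols = [], []
    for p in patients:
        for tp, dest in (("D0", d0_cols), ("D20", d20_cols)):
            sid = f"{p}_{tp}"
            if sid not in norm.values.columns:
                from .errors import IncompletePairError

                raise IncompletePairError(f"patient {p!r} has no {tp} sample")
            dest.append(sid)
    d0 = norm.values[d0_cols].to_numpy()
    d20 = norm.values[d20_cols].to_numpy()
    positions = pd.Series(np.arange(len(norm.values)), index=norm.values.index)
    groups: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    gene_of = manifest.gene_of
    for gene in manifest.genes:
        idx = positions[gene_of.index[gene_of == gene]].to_numpy()
        groups[gene] = (d0[idx].ravel(), d20[idx].ravel())
    return groups


def gene_log_fc(day20, day0, pseudo: float = DEFAULT_PSEUDOCOUNT,
                log_pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2 of (mean Day 20 linear CPM + pseudo) / (mean Day 0 linear CPM + pseudo).

    Ratio of means (not mean of ratios), robust to individual zero-count
    shRNAs; linear CPM is recovered from the normalized log2 values by
    inverting the log pseudocount.
    """
    if len(day20) == 0 or len(day0) == 0:
        raise InvalidInputError("gene_log_fc requires non-empty groups")
    m20 = linear_cpm(day20, log_pseudocount).mean()
    m0 = linear_cpm(day0, log_pseudocount).mean()
    return float(np.log2((m20 + pseudo) / (m0 + pseudo)))


def _gene_p(d0: np.ndarray, d20: np.ndarray, config: AnalysisConfig) -> tuple[float, str]:
    if min(len(d0), len(d20)) < 2:
        warnings.warn("gene with < 2 shRNA observations per group; using rank-sum test")
        return wilcoxon_rank_sum(d20, d0, config.exact_cutoff), "wilcoxon"
    if config.test == "welch_t":
        _, _, p = welch_t(d20, d0)
        return p, "welch_t"
    return wilcoxon_rank_sum(d20, d0, config.exact_cutoff), "wilcoxon"


def _results_from_norm(
    norm: NormalizedTable,
    manifest: LibraryManifest,
    config: AnalysisConfig,
    patients: list[str],
) -> pd.DataFrame:
    groups = gene_group(norm, manifest, patients)
    roles = manifest.gene_roles
    rows = []
    for gene, (d0, d20) in groups.items():
        p, used = _gene_p(d0, d20, config)
        fc = gene_log_fc(d20, d0, pseudo=config.fc_pseudo, log_pseudocount=config.pseudocount)
        rows.append(
            {"gene": gene, "role": roles[gene], "n_d0": len(d0), "n_d20": len(d20),
             "log2_fc": fc, "p_value": p, "test_used": used}
        )
    res = pd.DataFrame(rows)
    res["fdr_p"] = bh_adjust(res["p_value"].to_numpy())
    q, pi0 = storey_q(res["p_value"].to_numpy(), lambda_grid=config.lambda_grid)
    res["q_value"] = q
    res = res[RESULT_COLUMNS]
    res.attrs["pi0"] = pi0.pi0
    res.attrs["patients"] = list(patients)
    return res


def analyze_screen(
    table: CountTable,
    manifest: LibraryManifest,
    config: AnalysisConfig | None = None,
    patient: str | None = None,
) -> pd.DataFrame:
    """Full per-patient analysis: normalize the patient's D0/D20 pair,
    group by gene, test, fold change, BH and Storey corrections.

    Returns one row per gene (controls included) with columns
    ``RESULT_COLUMNS``; the π₀ estimate is stored in ``result.attrs['pi0']``.
    """
    config = config or AnalysisConfig()
    if patient is None:
        pats = table.patients
        if len(pats) != 1:
            raise InvalidInputError(
                f"table holds {len(pats)} patients; pass `patient` explicitly"
            )
        patient = pats[0]
    sub = table.subset_patients([patient])
    norm = normalize_table(sub, config.pseudocount, config.span, config.iterations)
    return _results_from_norm(norm, manifest, config, [patient])


def pooled_analyze(
    tables: list[CountTable],
    manifest: LibraryManifest,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Cross-sample re-analysis of the successful screens.

    Restarts from the raw counts of every table, normalizes all samples
    jointly (so pooled values are comparable across patients), concatenates
    each gene's observations across patients, and tests with the rank-sum
    test by default.
    """
    config = config or AnalysisConfig()
    if len(tables) < 2:
        raise InsufficientInputError(
            f"pooled analysis needs >= 2 successful screens, got {len(tables)}"
        )
    combined = concat_tables(tables)
    norm = normalize_table(combined, config.pseudocount, config.span, config.iterations)
    return _results_from_norm(norm, manifest, config, combined.patients)


@dataclass
class HitCalls:
    """Candidate dependencies (targets) and controls meeting the same rule."""

    candidates: pd.DataFrame = field(repr=False)
    controls: pd.DataFrame = field(repr=False)


def call_hits(
    results: pd.DataFrame,
    q_max: float = DEFAULT_Q_MAX,
    logfc_max: float = DEFAULT_LOGFC_MAX,
    direction: str = "depleted",
) -> HitCalls:
    """Apply the nomination rule (strict q < q_max and log2 FC < logfc_max).

    ``direction="enriched"`` mirrors the rule with log2 FC > +|logfc_max|.
    Control genes meeting the rule are reported separately, never as
    candidates.
    """
    if results.empty:
        raise InvalidInputError("call_hits requires non-empty results")
    if direction == "depleted":
        meets = (results["q_value"] < q_max) & (results["log2_fc"] < logfc_max)
    elif direction == "enriched":
        meets = (results["q_value"] < q_max) & (results["log2_fc"] > abs(logfc_max))
    else:
        raise InvalidConfigError("direction must be 'depleted' or 'enriched'")
    hits = results.loc[meets].sort_values("q_value", kind="mergesort")
    return HitCalls(
        candidates=hits.loc[hits["role"] == ROLE_TARGET].reset_index(drop=True),
        controls=hits.loc[hits["role"] != ROLE_TARGET].reset_index(drop=True),
    )
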