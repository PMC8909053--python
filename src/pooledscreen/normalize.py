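"""CPM transformation and cyclic loess normalization.

Counts are scaled to counts per million (CPM), shifted by a pseudocount and
log2-transformed; intensity-dependent biases between samples are then
removed by cyclic loess: for every unordered sample pair an MA plot is
formed (A = mean log2 intensity, M = log2 ratio), a locally weighted linear
regression of M on A with tricube weights is fitted, and half the fitted
curve is subtracted from one sample and added to the other; all pairs are
swept per iteration and the sweep repeated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .counts import CountTable
from .errors import DegenerateSampleError, InvalidConfigError, InvalidInputError

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_SPAN = 0.7
DEFAULT_ITERATIONS = 3


@dataclass
class NormalizedTable:
    """log2-CPM matrix after cyclic loess, same axes as the source counts."""

    values: pd.DataFrame = field(repr=False)
    genes: pd.Series = field(repr=False)
    samples: pd.DataFrame = field(repr=False)
    provenance: dict = field(default_factory=dict)

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.samples["patient"]))

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.insert(0, "gene", self.genes)
        out.index.name = "shrna_id"
        out.to_csv(path, sep="\t", float_format="%.6f")


def cpm(counts: pd.DataFrame | CountTable) -> pd.DataFrame:
    """Counts per million: each column scaled to sum to 1e6."""
    df = counts.counts if isinstance(counts, CountTable) else counts
    totals = df.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateSampleError(
            f"sample(s) with zero total counts: {list(zero.index)}"
        )
    return df * 1e6 / totals


def log2_cpm(counts, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    if pseudocount <= 0:
        raise InvalidConfigError("pseudocount must be positive")
    return np.log2(cpm(counts) + pseudocount)


def ma_transform(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MA coordinates of two log2 vectors: A = (x+y)/2, M = x − y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError(f"length mismatch: {x.shape} vs {y.shape}")
    return (x + y) / 2.0, x - y


def _loess_fit(A: np.ndarray, M: np.ndarray, span: float) -> np.ndarray:
    """Fitted M(A) curve at the observed A, tricube-weighted local linear."""
    span_range = float(A.max() - A.min())
    delta = 0.01 * span_range  # interpolation shortcut; exact at delta=0
    return lowess(M, A, frac=span, it=0, delta=delta, return_sorted=False)


def cyclic_loess(
    log2cpm: pd.DataFrame,
    span: float = DEFAULT_SPAN,
    iterations: int = DEFAULT_ITERATIONS,
) -> pd.DataFrame:
    """Cyclic loess over all unordered column pairs.

    Each sweep visits pairs in lexicographic order and updates the two
    columns in place (subtract half the fitted M(A) curve from the first,
    add half to the second), as in the pairwise variant of limma's
    ``normalizeCyclicLoess``.
    """
    if not 0 < span <= 1:
        raise InvalidConfigError(f"span must be in (0,1], got {span}")
    if iterations < 1:
        raise InvalidConfigError("iterations must be >= 1")
    vals = log2cpm.to_numpy(dtype=float).copy()
    if not np.isfinite(vals).all():
        raise InvalidInputError("log2 CPM values must be finite (apply a pseudocount)")
    n_samples = vals.shape[1]
    if n_samples < 2:
        warnings.warn("cyclic loess needs >= 2 samples; returning input unchanged")
        return log2cpm.copy()
    for _ in range(iterations):
        for i, j in combinations(range(n_samples), 2):
            A, M = ma_transform(vals[:, i], vals[:, j])
            fit = _loess_fit(A, M, span)
            vals[:, i] -= fit / 2.0
            vals[:, j] += fit / 2.0
    return pd.DataFrame(vals, index=log2cpm.index, columns=log2cpm.columns)


def normalize_table(
    table: CountTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    span: float = DEFAULT_SPAN,
    iterations: int = DEFAULT_ITERATIONS,
) -> NormalizedTable:
    """Full normalization of a count table: CPM → log2(+pseudocount) → cyclic loess."""
    values = cyclic_loess(log2_cpm(table, pseudocount), span=span, iterations=iterations)
    return NormalizedTable(
        values=values,
        genes=table.genes,
        samples=table.samples,
        provenance={"pseudocount": pseudocount, "span": span, "iterations": iterations},
    )


def linear_cpm(values: np.ndarray, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> np.ndarray:
    """Invert the log2(+pseudocount) transform; clipped at zero."""
    return np.maximum(2.0 ** np.asarray(values, dtype=float) - pseudocount, 0.0)
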