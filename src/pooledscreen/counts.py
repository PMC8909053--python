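"""Integer shRNA × sample count tables with sample metadata.

The TSV dialect is ``shrna_id``, ``gene``, then one integer column per
sample named ``<patient>_<D0|D20>``. Sample metadata beyond what the column
name encodes (cells collected for gDNA isolation, used for coverage QC) is
carried in an optional sidecar samples TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IncompletePairError, InvalidInputError
from .manifest import LibraryManifest

TIMEPOINTS = ("D0", "D20")

SAMPLE_COLUMNS = ["sample_id", "patient", "timepoint", "cells_collected"]


def sample_id(patient: str, timepoint: str) -> str:
    if timepoint not in TIMEPOINTS:
        raise InvalidInputError(f"timepoint must be one of {TIMEPOINTS}, got {timepoint!r}")
    return f"{patient}_{timepoint}"


@dataclass
class CountTable:
    """Raw read counts per shRNA and sample.

    Parameters
    ----------
    counts
        Integer matrix, index = shrna_id (manifest order), columns = sample
        ids of the form ``<patient>_<D0|D20>``.
    genes
        shrna_id → gene, aligned to ``counts.index``.
    samples
        Metadata frame indexed by sample_id with columns ``patient``,
        ``timepoint`` and ``cells_collected`` (nullable).
    """

    counts: pd.DataFrame = field(repr=False)
    genes: pd.Series = field(repr=False)
    samples: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        if not self.counts.index.equals(pd.Index(self.genes.index)):
            raise InvalidInputError("counts index and genes index differ")
        if self.counts.columns.duplicated().any():
            raise InvalidInputError("duplicate sample ids")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise InvalidInputError(f"samples metadata missing for: {sorted(missing)}")
        self.samples = self.samples.loc[list(self.counts.columns)]
        vals = self.counts.to_numpy()
        if np.any(vals < 0):
            raise InvalidInputError("counts must be non-negative")
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals)):
                raise InvalidInputError("counts must be integral")
            self.counts = self.counts.astype(np.int64)

    # -- accessors ---------------------------------------------------------

    @property
    def shrna_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.samples["patient"]))

    def column(self, patient: str, timepoint: str) -> pd.Series:
        sid = sample_id(patient, timepoint)
        if sid not in self.counts.columns:
            raise IncompletePairError(f"patient {patient!r} has no {timepoint} sample")
        return self.counts[sid]

    def subset_patients(self, patients) -> "CountTable":
        cols = []
        for p in patients:
            for tp in TIMEPOINTS:
                sid = sample_id(p, tp)
                if sid not in self.counts.columns:
                    raise IncompletePairError(f"patient {p!r} has no {tp} sample")
                cols.append(sid)
        return CountTable(self.counts[cols], self.genes, self.samples.loc[cols])

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path, samples_path=None) -> None:
        out = self.counts.copy()
        out.insert(0, "gene", self.genes)
        out.index.name = "shrna_id"
        out.to_csv(path, sep="\t")
        if samples_path is not None:
            self.samples.reset_index().rename(columns={"index": "sample_id"})[
                SAMPLE_COLUMNS
            ].to_csv(samples_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, samples_path=None, manifest: LibraryManifest | None = None) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="shrna_id")
        genes = df.pop("gene")
        counts = df.astype(np.int64)
        if manifest is not None:
            if not counts.index.equals(pd.Index(manifest.shrna_ids)):
                raise InvalidInputError("count table row order does not match manifest")
        if samples_path is not None:
            samples = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
        else:
            samples = samples_from_column_names(counts.columns)
        return cls(counts, genes, samples)


def samples_from_column_names(columns) -> pd.DataFrame:
    """Derive sample metadata from ``<patient>_<D0|D20>`` column names."""
    rows = []
    for sid in columns:
        patient, _, tp = sid.rpartition("_")
        if not patient or tp not in TIMEPOINTS:
            raise InvalidInputError(
                f"sample id {sid!r} is not of the form <patient>_<D0|D20>"
            )
        rows.append({"sample_id": sid, "patient": patient, "timepoint": tp,
                     "cells_collected": pd.NA})
    return pd.DataFrame(rows).set_index("sample_id")


def concat_tables(tables: list[CountTable]) -> CountTable:
    """Column-concatenate per-patient count tables sharing one library."""
    if not tables:
        raise InvalidInputError("no tables to concatenate")
    first = tables[0]
    for t in tables[1:]:
        if not t.counts.index.equals(first.counts.index):
            raise InvalidInputError("tables index different shRNA sets")
    all_counts = pd.concat([t.counts for t in tables], axis=1)
    if all_counts.columns.duplicated().any():
        dups = all_counts.columns[all_counts.columns.duplicated()].tolist()
        raise InvalidInputError(f"duplicate sample ids across tables: {dups}")
    all_samples = pd.concat([t.samples for t in tables], axis=0)
    return CountTable(all_counts, first.genes, all_samples)
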