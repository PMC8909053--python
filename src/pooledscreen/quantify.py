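"""Barcode counting: amplicon FASTQ → per-shRNA read counts.

Reads carry the shRNA barcode at a fixed offset inside a constant vector
context, so assignment is exact (or single-mismatch) Hamming matching of
the barcode window — no alignment, no indel tolerance. Ambiguous reads
(within the mismatch budget of more than one barcode) are dropped, never
split, so counts stay integral.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .counts import CountTable, samples_from_column_names
from .errors import FastqParseError, InvalidManifestError
from .manifest import LibraryManifest

_AMBIGUOUS = -1


@dataclass(frozen=True)
class BarcodeQC:
    """Read-assignment tallies; assigned + ambiguous + unassigned = total."""

    total: int
    assigned: int
    ambiguous: int
    unassigned: int

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "assigned": self.assigned,
            "ambiguous": self.ambiguous,
            "unassigned": self.unassigned,
        }


def _barcode_index(manifest: LibraryManifest, max_mismatch: int) -> dict[str, int]:
    """Map every acceptable barcode window to a shRNA index or _AMBIGUOUS.

    For max_mismatch=1, all single-substitution variants are enumerated; a
    window reachable from two different barcodes (including a window that IS
    one barcode and lies within one mismatch of another) maps to _AMBIGUOUS.
    """
    if not manifest.has_barcodes:
        raise InvalidManifestError("manifest has no barcodes")
    barcodes = manifest.entries["barcode"].tolist()
    index: dict[str, int] = {}
    for i, bc in enumerate(barcodes):
        index[bc] = i
    if max_mismatch == 0:
        return index
    for i, bc in enumerate(barcodes):
        for pos in range(len(bc)):
            for base in "ACGT":
                if base == bc[pos]:
                    continue
                variant = bc[:pos] + base + bc[pos + 1 :]
                prev = index.get(variant)
                if prev is None:
                    index[variant] = i
                elif prev != i:
                    index[variant] = _AMBIGUOUS
    return index


def _iter_fastq(reads):
    """Accept a path, an open handle, or an iterable of (id, seq, qual)."""
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        with open(reads) as handle:
            yield from _checked(FastqGeneralIterator(handle))
    elif hasattr(reads, "read"):
        yield from _checked(FastqGeneralIterator(reads))
    else:
        yield from reads


def _checked(iterator):
    i = 0
    while True:
        try:
            rec = next(iterator)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqParseError(f"malformed FASTQ at record {i}: {exc}", i) from exc
        yield rec
        i += 1


def count_barcodes(
    reads,
    manifest: LibraryManifest,
    offset: int | None = None,
    max_mismatch: int = 0,
) -> tuple[pd.Series, BarcodeQC]:
    """Assign reads to shRNAs by their barcode window.

    Parameters
    ----------
    reads
        FASTQ path, open handle, or iterable of (id, sequence, quality).
    offset
        0-based start of the barcode within each read; defaults to the
        length of the simulated 5' vector context.
    max_mismatch
        0 for exact matching, 1 to additionally accept single substitutions.
        A read within the budget of more than one barcode is ambiguous.

    Returns
    -------
    counts
        Integer Series indexed by shrna_id in manifest order.
    qc
        Total/assigned/ambiguous/unassigned tallies.
    """
    if max_mismatch not in (0, 1):
        raise InvalidManifestError("max_mismatch must be 0 or 1")
    if offset is None:
        from .simulate import VECTOR_5P

        offset = len(VECTOR_5P)
    bclen = manifest.barcode_length  # raises if barcodes absent/heterogeneous
    index = _barcode_index(manifest, max_mismatch)
    tallies = [0] * manifest.n_shrnas
    total = ambiguous = unassigned = 0
    for _rid, seq, _qual in _iter_fastq(reads):
        total += 1
        window = seq[offset : offset + bclen]
        hit = index.get(window)
        if hit is None or len(window) < bclen:
            unassigned += 1
        elif hit == _AMBIGUOUS:
            ambiguous += 1
        else:
            tallies[hit] += 1
    counts = pd.Series(tallies, index=manifest.shrna_ids, name="count")
    assigned = total - ambiguous - unassigned
    return counts, BarcodeQC(total, assigned, ambiguous, unassigned)


def quantify_samples(
    fastq_by_sample: dict[str, object],
    manifest: LibraryManifest,
    offset: int | None = None,
    max_mismatch: int = 0,
) -> tuple[CountTable, dict[str, BarcodeQC]]:
    """Count several samples' FASTQs into one CountTable."""
    from .simulate import VECTOR_5P

    if offset is None:
        offset = len(VECTOR_5P)
    cols, qcs = {}, {}
    for sample_id, reads in fastq_by_sample.items():
        counts, qc = count_barcodes(reads, manifest, offset=offset, max_mismatch=max_mismatch)
        cols[sample_id] = counts
        qcs[sample_id] = qc
    counts_df = pd.DataFrame(cols, index=manifest.shrna_ids)
    table = CountTable(counts_df, manifest.gene_of, samples_from_column_names(counts_df.columns))
    return table, qcs
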