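"""Synthetic pooled dropout-screen generator.

Emulates the design of a focused shRNA screen in primary AML cells: a
library of 540 genes × 12 shRNAs (five essential positive-control genes and
one non-targeting negative control), lentiviral transduction into a limited
number of cells (the coverage bottleneck), 20 days of culture during which
shRNAs against fitness genes deplete, and amplicon sequencing of the
integrated barcodes at Day 0 and Day 20.

Generative model
----------------
1. *Bottleneck*: the Day 0 cell composition is a single multinomial draw of
   ``n_cells_infected`` cells over the plasmid-library proportions
   (log-normal across shRNAs). This is the mechanism that makes low
   coverage noisy: at 10× representation many shRNAs start from a handful
   of cells.
2. *Growth*: each shRNA's clone grows (or shrinks) exponentially; after
   ``duration_days`` days the expected abundance of shRNA *s* targeting
   gene *g* is ``day0_cells(s) * 2**(duration_days * gene_fitness(g) *
   efficacy(s))``, where ``gene_fitness`` is the per-day log2 growth
   deficit (≤ 0 for essential genes) and ``efficacy`` the fraction of the
   gene-level effect the individual hairpin transmits. Realized Day-20
   clone sizes are Poisson draws around that expectation (clonal drift),
   which is the second place the cell bottleneck injects noise: relative
   drift scales as 1/√cells, so poorly covered screens stay noisy even at
   high sequencing depth.
3. *Sequencing*: read counts per sample are negative-binomial around the
   depth-scaled relative abundances (variance = μ + dispersion·μ²), so each
   sample's expected total equals the configured depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .counts import CountTable, sample_id
from .errors import InvalidConfigError, InvalidManifestError, UnknownGeneError
from .manifest import (
    NEGATIVE_CONTROL_GENE,
    POSITIVE_CONTROL_GENES,
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
    ROLE_TARGET,
    LibraryManifest,
)

# Default per-day log2 fitness of a spiked shared dependency: a real
# dependency depletes somewhat more weakly than the common-essential
# positive controls (default essential_effect = -0.15/day).
DEFAULT_DEPENDENCY_EFFECT = -0.12

# Constant amplicon context around the barcode (a fixed stretch of the
# lentiviral vector on either side, as in a two-step barcode PCR).
VECTOR_5P = "TTGTGGAAAGGACGAAACACCG"
VECTOR_3P = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAAC"
DEFAULT_READ_LENGTH = 60


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the simulated screen.

    Defaults reproduce the screened library (540 genes, 12 shRNAs/gene) at
    60× coverage with a desk-scale sequencing depth of 1e6 reads per sample
    (the screen itself was sequenced at 1e7; set ``depth`` accordingly for
    full scale). ``essential_effect`` is the per-day log2 growth deficit of
    positive-control genes; −0.15/day gives an 8-fold dropout of a fully
    effective hairpin over 20 days.
    """

    n_genes: int = 540
    shrnas_per_gene: int = 12
    depth: int = 1_000_000
    dispersion: float = 0.1
    n_cells_infected: int = 388_800  # 60× the default 6480-shRNA library
    essential_effect: float = -0.15
    efficacy_active_fraction: float = 2.0 / 3.0
    efficacy_range: tuple[float, float] = (0.5, 1.0)
    control_efficacy_range: tuple[float, float] = (0.7, 1.0)
    duration_days: float = 20.0
    plasmid_lognorm_sigma: float = 0.5
    barcodes: bool = False
    barcode_length: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 7:
            raise InvalidConfigError(
                "n_genes must be >= 7 (five positive controls, one negative "
                f"control and at least one target gene); got {self.n_genes}"
            )
        if self.shrnas_per_gene < 1:
            raise InvalidConfigError("shrnas_per_gene must be positive")
        if self.depth <= 0 or self.n_cells_infected <= 0:
            raise InvalidConfigError("depth and n_cells_infected must be positive")
        if self.dispersion < 0:
            raise InvalidConfigError("dispersion must be >= 0")
        if self.duration_days <= 0:
            raise InvalidConfigError("duration_days must be positive")
        if not 0.0 <= self.efficacy_active_fraction <= 1.0:
            raise InvalidConfigError("efficacy_active_fraction must be in [0,1]")
        for rng_name in ("efficacy_range", "control_efficacy_range"):
            lo, hi = getattr(self, rng_name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise InvalidConfigError(f"{rng_name} must satisfy 0 <= lo <= hi <= 1")

    @property
    def n_shrnas(self) -> int:
        return self.n_genes * self.shrnas_per_gene

    def with_coverage(self, fold: float) -> "SimConfig":
        """Config with ``n_cells_infected`` set to ``fold``× the library size."""
        return replace(self, n_cells_infected=int(round(fold * self.n_shrnas)))


@dataclass(frozen=True)
class SimTruth:
    """Ground-truth fitness structure behind a simulated screen."""

    gene_fitness: pd.Series = field(repr=False)     # gene -> log2/day deficit
    shrna_efficacy: pd.Series = field(repr=False)   # shrna_id -> [0,1]
    plasmid_fractions: pd.Series = field(repr=False)  # shrna_id -> proportion

    def __post_init__(self):
        eff = self.shrna_efficacy.to_numpy(float)
        if np.any((eff < 0) | (eff > 1)):
            raise InvalidConfigError("efficacies must lie in [0,1]")
        total = float(self.plasmid_fractions.sum())
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(f"plasmid_fractions sum to {total}, not 1")


def growth_factor(fitness: float, efficacy: float, days: float) -> float:
    """Expected Day-T/Day-0 abundance ratio of one shRNA, before renormalization."""
    return float(2.0 ** (days * fitness * efficacy))


def build_manifest(config: SimConfig | None = None) -> LibraryManifest:
    """Build the synthetic focused library manifest.

    Control genes count toward ``n_genes``: the default 540 genes comprise
    534 synthetic targets (G0001…G0534), five positive controls and LUC.
    Barcodes (when ``config.barcodes``) are drawn uniformly over {A,C,G,T},
    deterministically from ``config.seed``, and checked unique.
    """
    config = config or SimConfig()
    n_targets = config.n_genes - len(POSITIVE_CONTROL_GENES) - 1
    genes = (
        [(g, ROLE_POSITIVE) for g in POSITIVE_CONTROL_GENES]
        + [(NEGATIVE_CONTROL_GENE, ROLE_NEGATIVE)]
        + [(f"G{i:04d}", ROLE_TARGET) for i in range(1, n_targets + 1)]
    )
    rows = [
        {"shrna_id": f"{gene}_sh{k:02d}", "gene": gene, "role": role}
        for gene, role in genes
        for k in range(1, config.shrnas_per_gene + 1)
    ]
    df = pd.DataFrame(rows)
    if config.barcodes:
        rng = np.random.default_rng(config.seed)
        n = len(df)
        seen: set[str] = set()
        barcodes: list[str] = []
        while len(barcodes) < n:
            draw = rng.integers(0, 4, size=(n, config.barcode_length))
            for row in draw:
                bc = "".join("ACGT"[b] for b in row)
                if bc not in seen:
                    seen.add(bc)
                    barcodes.append(bc)
                    if len(barcodes) == n:
                        break
        df["barcode"] = barcodes
    return LibraryManifest(df)


def simulate_truth(
    manifest: LibraryManifest,
    config: SimConfig,
    seed: int | None = None,
    spike: dict[str, float] | None = None,
) -> SimTruth:
    """Assign fitness, hairpin efficacies and plasmid proportions.

    Positive-control genes get ``config.essential_effect``; the negative
    control and unspiked targets are neutral. ``spike`` forces chosen target
    genes to a given per-day log2 fitness (shared dependencies). Hairpin
    efficacy follows a mixture: a fraction ``efficacy_active_fraction`` of
    each gene's shRNAs is active with efficacy ~ Uniform(efficacy_range),
    the rest are inert (efficacy 0) — typical of unvalidated shRNA sets.
    Positive-control reagents are validated by construction, so their
    hairpins are all active with efficacy ~ Uniform(control_efficacy_range).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    roles = manifest.gene_roles
    fitness = pd.Series(0.0, index=roles.index)
    fitness[roles == ROLE_POSITIVE] = config.essential_effect
    if spike:
        for gene, f in spike.items():
            if gene not in fitness.index:
                raise UnknownGeneError(gene)
            fitness[gene] = f
    fitness[roles == ROLE_NEGATIVE] = 0.0

    ids = manifest.shrna_ids
    active = rng.random(len(ids)) < config.efficacy_active_fraction
    lo, hi = config.efficacy_range
    eff = np.where(active, rng.uniform(lo, hi, size=len(ids)), 0.0)
    is_pos = (manifest.entries["role"] == ROLE_POSITIVE).to_numpy()
    clo, chi = config.control_efficacy_range
    eff[is_pos] = rng.uniform(clo, chi, size=int(is_pos.sum()))
    efficacy = pd.Series(eff, index=ids)

    frac = rng.lognormal(mean=0.0, sigma=config.plasmid_lognorm_sigma, size=len(ids))
    frac /= frac.sum()
    # exact unit sum despite float rounding
    frac[-1] += 1.0 - frac.sum()
    fractions = pd.Series(frac, index=ids)
    return SimTruth(fitness, efficacy, fractions)


def expected_abundance(
    truth: SimTruth, manifest: LibraryManifest, day0_cells: np.ndarray, days: float
) -> np.ndarray:
    """Expected clone sizes after ``days`` of growth, before renormalization."""
    fitness = truth.gene_fitness.loc[manifest.gene_of.to_numpy()].to_numpy()
    eff = truth.shrna_efficacy.to_numpy()
    return day0_cells * 2.0 ** (days * fitness * eff)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(μ, var = μ + dispersion·μ²) via gamma–Poisson mixing; Poisson at 0."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = np.zeros_like(mean)
    pos = mean > 0
    lam[pos] = rng.gamma(1.0 / dispersion, scale=mean[pos] * dispersion)
    return rng.poisson(lam)


def simulate_counts(
    truth: SimTruth,
    config: SimConfig,
    seed: int | None = None,
    patient: str = "P1",
    *,
    manifest: LibraryManifest,
) -> CountTable:
    """Simulate Day 0 / Day 20 read counts for one screen.

    The multinomial Day 0 draw over plasmid fractions is the coverage
    bottleneck; sequencing counts are NB around depth-scaled proportions so
    each sample's expected total equals ``config.depth``. ``cells_collected``
    records the (integer) cell numbers behind each timepoint for coverage QC.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ids = manifest.shrna_ids
    fractions = truth.plasmid_fractions.loc[ids].to_numpy()

    day0_cells = rng.multinomial(config.n_cells_infected, fractions).astype(float)
    # clonal drift: realized Day-20 clone sizes fluctuate Poisson around the
    # exponential-growth expectation, so the bottleneck matters at both ends
    day20_cells = rng.poisson(
        expected_abundance(truth, manifest, day0_cells, config.duration_days)
    ).astype(float)

    cols, meta = {}, []
    for tp, cells in (("D0", day0_cells), ("D20", day20_cells)):
        total = cells.sum()
        mean_reads = config.depth * cells / total if total > 0 else np.zeros_like(cells)
        cols[sample_id(patient, tp)] = _nb_draw(rng, mean_reads, config.dispersion)
        meta.append(
            {
                "sample_id": sample_id(patient, tp),
                "patient": patient,
                "timepoint": tp,
                "cells_collected": int(round(total)),
            }
        )
    counts = pd.DataFrame(cols, index=ids)
    return CountTable(counts, manifest.gene_of.loc[ids], pd.DataFrame(meta).set_index("sample_id"))


def simulate_screen(
    config: SimConfig,
    seed: int | None = None,
    patient: str = "P1",
    spike: dict[str, float] | None = None,
    manifest: LibraryManifest | None = None,
) -> tuple[LibraryManifest, SimTruth, CountTable]:
    """Convenience wrapper: manifest → truth → counts for one patient."""
    manifest = manifest or build_manifest(config)
    base = config.seed if seed is None else seed
    truth = simulate_truth(manifest, config, seed=base, spike=spike)
    table = simulate_counts(truth, config, seed=base + 1, patient=patient, manifest=manifest)
    return manifest, truth, table


def simulate_cohort(
    config: SimConfig,
    n_patients: int,
    seed: int | None = None,
    coverages: list[float] | None = None,
    spike: dict[str, float] | None = None,
) -> tuple[LibraryManifest, SimTruth, list[CountTable]]:
    """Simulate a cohort of screens sharing one library and one biology.

    The manifest, plasmid fractions, hairpin efficacies and gene fitness
    (including spiked shared dependencies) are drawn once; each patient gets
    an independent infection bottleneck and sequencing draw. ``coverages``
    optionally sets per-patient fold representation (cells per shRNA).
    """
    if n_patients < 1:
        raise InvalidConfigError("n_patients must be >= 1")
    if coverages is not None and len(coverages) != n_patients:
        raise InvalidConfigError("coverages must have one entry per patient")
    base = config.seed if seed is None else seed
    rng = np.random.default_rng(base)
    manifest = build_manifest(config)
    truth = simulate_truth(manifest, config, seed=int(rng.integers(2**31 - 1)), spike=spike)
    tables = []
    for i in range(n_patients):
        cfg = config if coverages is None else config.with_coverage(coverages[i])
        tables.append(
            simulate_counts(
                truth, cfg, seed=int(rng.integers(2**31 - 1)),
                patient=f"P{i + 1:02d}", manifest=manifest,
            )
        )
    return manifest, truth, tables


def simulate_fastq(
    table: CountTable,
    manifest: LibraryManifest,
    sample: str,
    seed: int = 0,
    error_rate: float = 0.0,
    read_length: int = DEFAULT_READ_LENGTH,
):
    """Yield FASTQ records (id, sequence, quality) for one sample's counts.

    Emits exactly the tabulated number of reads per shRNA. Each read places
    the shRNA barcode at offset ``len(VECTOR_5P)`` inside the constant
    vector context, padded to ``read_length``. ``error_rate`` applies i.i.d.
    per-base substitutions.
    """
    if not manifest.has_barcodes:
        raise InvalidManifestError("simulate_fastq requires a manifest with barcodes")
    rng = np.random.default_rng(seed)
    barcodes = manifest.entries.set_index("shrna_id")["barcode"]
    qual = "I" * read_length
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    i = 0
    for shrna_id, n in table.counts[sample].items():
        bc = barcodes[shrna_id]
        template = (VECTOR_5P + bc + VECTOR_3P)[:read_length].ljust(read_length, "A")
        for _ in range(int(n)):
            seq = template
            if error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                hits = rng.random(read_length) < error_rate
                if hits.any():
                    arr[hits] = alphabet[rng.integers(0, 4, size=int(hits.sum()))]
                seq = arr.tobytes().decode()
            yield (f"{sample}:read{i}", seq, qual)
            i += 1


def write_fastq(records, path) -> int:
    """Write (id, seq, qual) triples as Phred+33 FASTQ; returns read count."""
    n = 0
    close = False
    if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__"):
        handle = open(path, "w")
        close = True
    else:
        handle = path
    try:
        for rid, seq, qual in records:
            handle.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    finally:
        if close:
            handle.close()
    return n
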