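# Methods

## The analysis problem

A pooled shRNA dropout screen transduces a library of hairpins into a cell
population, cultures it, and sequences the integrated barcodes at baseline
(Day 0) and endpoint (Day 20). Hairpins against genes the cells depend on
deplete. In immortal cell lines this is routine; in primary patient cells
the cell number is limited, coverage (cells per library element) is
variable and often low, and there are no biological replicates. The
pipeline here is built around the two consequences of that setting: a
per-screen success gate based on built-in essential-gene positive controls,
and a pooled cross-sample re-analysis that recovers power by concatenating
per-gene observations across the screens that passed the gate.

## Per-screen analysis

Raw counts are scaled to counts per million (CPM), shifted by a pseudocount
(default 0.5) and log2-transformed. Between-sample intensity-dependent bias
is removed by cyclic loess: for each unordered pair of samples the MA
transform is formed (A = mean log2 intensity, M = log2 ratio), a locally
weighted linear regression of M on A (tricube weights, span 0.7) is fitted,
and half of the fitted curve is subtracted from one sample and added to the
other; all pairs are swept per iteration, three iterations by default. The
smoother is `statsmodels`' lowess with an interpolation shortcut
(`delta` = 1% of the A range), which changes fitted values negligibly on
these densities. These are conventional fast-mode choices; all are
configurable (`AnalysisConfig`). No low-count filter is applied by default.

Per gene, all shRNA observations at Day 0 form one group and those at Day
20 the other; observations are treated as exchangeable replicates (no
pairing of a hairpin across timepoints — the comparison is group vs group).
The default test is the two-sided Wilcoxon rank-sum test: exact (via the
full null distribution of the rank-sum statistic) when the pooled sample is
tie-free and of size ≤ 20, otherwise the normal approximation with
mid-ranks, tie correction and continuity correction. Exact enumeration with
ties is ambiguous, so the exact path refuses ties. Welch's unequal-variance
t test is available as an alternative (`test="welch_t"`); with fewer than
two observations per group the rank-sum test is used and a warning emitted.
Degenerate conventions: identical groups give p = 1; zero variance in both
groups with unequal means gives p = 0 with a warning.

Fold change is the log2 ratio of means, FC = log2((mean CPM_D20 + c) /
(mean CPM_D0 + c)) with c = 0.5, computed on linear CPM recovered from the
normalized log2 values. Ratio-of-means rather than mean-of-ratios keeps
single zero-count hairpins from dominating; base 2 makes the −0.2
nomination threshold ≈ 13% depletion, a plausible screen-scale effect.
(The threshold's log base is a documented choice: log2.)

Multiplicity: Benjamini–Hochberg step-up adjusted p-values are reported
alongside Storey q-values. π₀ (the null proportion) is estimated as
raw π₀(λ) = #{p > λ}/(m(1−λ)) on the grid λ = 0.05…0.95 (step 0.05),
smoothed with a cubic polynomial fit and evaluated at λ = 0.95, clamped to
(0,1]. A non-positive or failed smooth falls back to the conservative
π₀ = 1 with a warning (on a 540-gene screen the raw estimates are noisy,
so the fallback is common and harmless — q-values then equal BH exactly).
q-values are the π₀-scaled step-up quantities, monotonized, so ranking
genes by q always reproduces the ranking by p.

## Screen QC and pooling

Coverage is cells collected for gDNA isolation divided by library size,
reported as fold representation (60× = 60 cells per shRNA). A screen is
successful iff at least one of the five positive-control genes (PSMA1,
PSMA3, RPS13, RPL6, RPL30 — proteasome/ribosome common essentials) has
q < 0.05 and log2 FC < −0.2 (strict inequalities). The non-targeting
negative control (LUC) is reported but never contributes to success:
depletion of a non-targeting hairpin would indicate artifact. Note the
per-gene enrichment/depletion call uses q < 0.05 alone, while success
nomination and candidate nomination use the conjunction with FC — the two
rules are intentionally distinct.

The pooled stage restarts from raw counts of the successful screens,
normalizes all samples jointly (one cyclic-loess pass over every pair, so
pooled values are comparable across patients), concatenates each gene's
observations across patients (~12 shRNAs × patients per group), tests with
the rank-sum test, and nominates candidate dependencies at q < 0.05 and
log2 FC < −0.2. Controls are excluded from the candidate list and reported
separately. At least two successful screens are required; the pipeline
skips the stage with an explicit status otherwise.

## Synthetic screen generator

The generator emulates the screened design: 540 genes × 12 shRNAs
(controls counted among the 540, so 534 synthetic targets G0001…G0534),
sequencing depth 1 × 10⁶ reads per sample by default (a desk-scale tenth
of the screen's 1 × 10⁷; configurable), 20-day duration, and coverage set
through the number of infected cells (default 60×; the screen observed a
10–300× range with median 56×, emulated in `scripts/acceptance.py` with a
log-uniform draw).

Mechanism, per screen:

1. **Bottleneck** — Day 0 clone sizes are one multinomial draw of
   `n_cells_infected` cells over plasmid-library proportions (log-normal
   across hairpins, σ = 0.5).
2. **Growth with drift** — the expected Day-20 clone size of hairpin *s*
   on gene *g* is `day0_cells · 2^(20 · fitness(g) · efficacy(s))`;
   realized clone sizes are Poisson draws around it. The drift term is
   essential: with deterministic growth the Day-0 bottleneck cancels in
   the Day20/Day0 ratio and coverage would not affect screen noise at all,
   contrary to what screens show. With drift, the null log-ratio variance
   decreases monotonically in coverage, and the success gate degrades at
   low coverage (100% at 60× vs ~0% at 10× under defaults at depth 1e6).
3. **Sequencing** — reads per hairpin are negative-binomial around the
   depth-scaled relative abundance (variance = μ + φμ², φ = 0.1 by
   default), so each sample's expected total equals the depth.

Gene fitness is the per-day log2 growth deficit: positive controls default
to −0.15/day (an 8-fold 20-day dropout at full efficacy), the negative
control and unspiked targets are 0, and shared dependencies can be spiked
(default −0.12/day, somewhat weaker than the essentials). Hairpin efficacy
is a mixture: for target genes, 2/3 of hairpins are active with efficacy ~
Uniform(0.5, 1) and 1/3 are inert — typical of unvalidated shRNA sets.
Positive-control reagents are modeled as validated hairpins: all active,
efficacy ~ Uniform(0.7, 1). This distinction matters quantitatively: with a
third of control hairpins inert, a 12-vs-12 rank-sum test cannot reach
q < 0.05 over 540 genes in a single screen, and no screen could ever pass
the gate — real control sets are chosen precisely because they deplete
reliably.

FASTQ emission places each hairpin's barcode at a fixed offset inside a
constant vector context with optional i.i.d. per-base substitution errors;
quantification reverses this by exact or 1-mismatch Hamming matching (reads
within the mismatch budget of more than one barcode are dropped as
ambiguous, never fractionally split). No alignment is attempted — the
amplicon structure is fixed by the vector, so indel tolerance buys nothing.

**What the generator does not model:** viability loss during thawing and
culture (the major cause of screen attrition in primary material),
B/T-cell contamination, cytokine response, differentiation, or
PCR-amplification bias. Passing tests therefore demonstrate the analysis
behaves correctly under the assumed count-generating mechanism, not that
any particular primary screen will succeed; in particular the synthetic
cohort passes the success gate far more often than primary screens do,
because gate failures in practice are dominated by viability, which is out
of scope here.

## Numerical and design choices

- **Test choice**: the method description names both a "rank sum t-Test"
  and the Wilcoxon rank-sum; both are implemented, the rank-sum is the
  default (it is the test named for the pooled analysis), selectable via
  `AnalysisConfig(test=...)`.
- **Determinism**: every stochastic step takes a seed; identical seeds give
  bit-identical manifests, truths, counts and result TSVs. Cohort
  simulation derives per-patient seeds from one base generator.
- **Degenerate inputs**: zero-total count columns raise a named error; a
  single-sample normalization is a warned no-op; q = 0 is clamped to the
  smallest positive double before −log10 in volcano export; empty groups,
  missing timepoints, missing control genes and unknown spike genes raise
  typed errors.
- **Problem sizes in tests**: property suites run the full 540 × 12 library
  at depth 1e6 (the desk-scale default); the FDR-null suite uses 50
  simulations, gate and pooling suites 20 seeds per condition — sizes at
  which the Monte-Carlo error of the checked rates is well below the
  asserted margins.
- **π₀ smoothing**: cubic polynomial rather than a spline — with 19 grid
  points the polynomial is stable and reproduces the smoother's purpose
  (borrowing strength across λ); bootstrap π₀ is not implemented.

## Known limitations

- The exact rank-sum path is O(C(n₁+n₂, n₁)) through the null distribution
  and is capped at pooled size 20 by default.
- Cyclic loess over k samples costs O(k²) smoother fits per iteration;
  pooling tens of screens is fine (~1500 fits), hundreds would warrant the
  fast (reference-based) variant, which is not implemented.
- Storey q-values on very small gene sets (m ≲ 50) effectively reduce to
  BH via the conservative fallback.
- shRNA-level hit calling, rank-aggregation methods and moderated-variance
  tests are deliberately out of scope.
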