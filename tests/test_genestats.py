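import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from pooledscreen import (
    AnalysisConfig,
    SimConfig,
    analyze_screen,
    build_manifest,
    call_hits,
    gene_group,
    gene_log_fc,
    pooled_analyze,
    simulate_cohort,
    simulate_screen,
    welch_t,
)
from pooledscreen.counts import CountTable, samples_from_column_names
from pooledscreen.errors import (
    IncompletePairError,
    InsufficientInputError,
    InvalidConfigError,
    InvalidInputError,
)
from pooledscreen.normalize import NormalizedTable, normalize_table


def make_norm(manifest, patients, rng, loc=7.0):
    """NormalizedTable with random log2 values, bypassing loess (cheap)."""
    cols = [f"{p}_{tp}" for p in patients for tp in ("D0", "D20")]
    values = pd.DataFrame(
        rng.normal(loc, 1.0, size=(manifest.n_shrnas, len(cols))),
        index=pd.Index(manifest.shrna_ids, name="shrna_id"),
        columns=cols,
    )
    return NormalizedTable(values, manifest.gene_of, samples_from_column_names(cols))


@pytest.fixture(scope="module")
def mini_manifest():
    return build_manifest(SimConfig(n_genes=8, shrnas_per_gene=12))


class TestGeneGroup:
    def test_per_patient_group_sizes(self, mini_manifest, rng):
        norm = make_norm(mini_manifest, ["P1"], rng)
        groups = gene_group(norm, mini_manifest, ["P1"])
        for d0, d20 in groups.values():
            assert len(d0) == len(d20) == 12

    def test_pooled_group_sizes(self, mini_manifest, rng):
        patients = [f"P{i}" for i in range(1, 10)]
        norm = make_norm(mini_manifest, patients, rng)
        groups = gene_group(norm, mini_manifest, patients)
        for d0, d20 in groups.values():
            assert len(d0) == len(d20) == 12 * 9 == 108

    def test_missing_timepoint(self, mini_manifest, rng):
        norm = make_norm(mini_manifest, ["P1"], rng)
        norm.values = norm.values.drop(columns=["P1_D20"])
        with pytest.raises(IncompletePairError):
            gene_group(norm, mini_manifest, ["P1"])

    def test_unknown_patient(self, mini_manifest, rng):
        norm = make_norm(mini_manifest, ["P1"], rng)
        with pytest.raises(InvalidInputError):
            gene_group(norm, mini_manifest, ["P9"])


class TestGeneLogFC:
    def test_equal_means(self):
        v = np.log2(np.array([100.0, 200.0]) + 0.5)
        assert gene_log_fc(v, v) == 0.0

    def test_doubling(self):
        d0 = np.log2(np.array([100.0, 200.0]) + 0.5)
        d20 = np.log2(np.array([200.0, 400.0]) + 0.5)
        assert gene_log_fc(d20, d0, pseudo=1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_depletion_boundary(self):
        """Day20 mean 870 vs Day0 mean 1000 sits at the log2 -0.2 nomination
        boundary (log2 0.87 = -0.2009)."""
        d20 = np.log2(np.array([870.0] * 4) + 0.5)
        d0 = np.log2(np.array([1000.0] * 4) + 0.5)
        assert gene_log_fc(d20, d0, pseudo=1e-12) == pytest.approx(np.log2(0.87))

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidInputError):
            gene_log_fc(np.array([]), np.array([1.0]))


class TestAnalyzeScreen:
    def test_self_comparison_is_null(self, mini_manifest):
        """Duplicating D0 as D20 gives log2 FC 0 and p = 1 for every gene."""
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            {"P1_D0": rng.integers(50, 500, mini_manifest.n_shrnas)},
            index=pd.Index(mini_manifest.shrna_ids, name="shrna_id"),
        )
        counts["P1_D20"] = counts["P1_D0"]
        table = CountTable(counts, mini_manifest.gene_of, samples_from_column_names(counts.columns))
        res = analyze_screen(table, mini_manifest)
        assert np.allclose(res["log2_fc"], 0.0, atol=1e-9)
        # identical groups: U sits exactly at its null mean; the continuity
        # correction keeps the asymptotic p just below 1
        assert np.all(res["p_value"] >= 0.95)
        assert np.all(res["q_value"] >= 0.95)

    def test_result_invariants(self, small_screen):
        manifest, _, table = small_screen
        res = analyze_screen(table, manifest)
        assert len(res) == manifest.n_genes
        for col in ("p_value", "fdr_p", "q_value"):
            assert res[col].between(0, 1).all()
        assert np.all(res["fdr_p"] >= res["p_value"] - 1e-12)
        order_p = res.sort_values("p_value", kind="mergesort").index
        assert np.all(np.diff(res.loc[order_p, "q_value"]) >= -1e-15)

    def test_single_shrna_gene_warns(self, rng):
        manifest = build_manifest(SimConfig(n_genes=7, shrnas_per_gene=1))
        norm = make_norm(manifest, ["P1"], rng)
        from pooledscreen.genestats import _results_from_norm

        with pytest.warns(UserWarning, match="< 2 shRNA"):
            res = _results_from_norm(norm, manifest, AnalysisConfig(), ["P1"])
        assert (res["n_d0"] == 1).all()

    def test_multi_patient_table_needs_explicit_patient(self, mini_manifest):
        cfg = SimConfig(n_genes=8, shrnas_per_gene=12, depth=50_000)
        _, _, tables = simulate_cohort(cfg, 2, seed=1)
        from pooledscreen.counts import concat_tables

        combined = concat_tables(tables)
        with pytest.raises(InvalidInputError):
            analyze_screen(combined, mini_manifest)

    def test_welch_option_used(self, small_screen):
        manifest, _, table = small_screen
        res = analyze_screen(table, manifest, AnalysisConfig(test="welch_t"))
        assert (res["test_used"] == "welch_t").all()


class TestPooledAnalyze:
    def test_requires_two_screens(self, small_screen):
        manifest, _, table = small_screen
        with pytest.raises(InsufficientInputError):
            pooled_analyze([table], manifest)

    def test_duplication_preserves_ranking(self):
        """Pooling a screen with a renamed copy of itself reproduces the
        single-screen p-value ranking (rank correlation; rank-sum p-values
        are heavily tied across genes, so exact order is not defined)."""
        cfg = SimConfig()
        manifest, _, t1 = simulate_screen(cfg, seed=31)
        c2 = t1.counts.copy()
        c2.columns = ["P2_D0", "P2_D20"]
        t2 = CountTable(c2, t1.genes, samples_from_column_names(c2.columns))
        single = analyze_screen(t1, manifest)
        pooled = pooled_analyze([t1, t2], manifest)
        rho = sps.spearmanr(single["p_value"], pooled["p_value"]).statistic
        assert rho >= 0.99

    def test_pooled_restarts_from_raw_counts(self, mini_manifest):
        """Feeding raw tables twice gives bit-identical pooled output —
        nothing is cached from any per-patient normalization."""
        cfg = SimConfig(n_genes=8, shrnas_per_gene=12, depth=50_000)
        _, _, tables = simulate_cohort(cfg, 3, seed=2)
        r1 = pooled_analyze(tables, mini_manifest)
        r2 = pooled_analyze(tables, mini_manifest)
        pd.testing.assert_frame_equal(r1, r2)


class TestLabelPermutationNull:
    def test_permutation_p_values_uniform(self):
        """Randomly reassigning D0/D20 labels within each gene's fixed
        normalized observations yields a uniform p distribution (KS)."""
        cfg = SimConfig(essential_effect=0.0)
        manifest, _, table = simulate_screen(cfg, seed=200)
        norm = normalize_table(table)
        groups = gene_group(norm, manifest)
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(10):
            for d0, d20 in groups.values():
                pooled = np.concatenate([d0, d20])
                rng.shuffle(pooled)
                _, _, p = welch_t(pooled[: len(d0)], pooled[len(d0):])
                pvals.append(p)
        ks = sps.kstest(np.asarray(pvals), "uniform")
        assert len(pvals) >= 5000
        assert ks.pvalue > 0.01


def test_parameter_recovery_at_high_coverage():
    """At 300x coverage the pooled per-gene log2 FC tracks the ground truth
    duration*fitness*mean-efficacy with Pearson r >= 0.9."""
    rng = np.random.default_rng(0)
    spike = {f"G{i:04d}": float(rng.uniform(-0.2, 0)) for i in range(1, 61)}
    cfg = SimConfig().with_coverage(300)
    manifest, truth, tables = simulate_cohort(cfg, 9, seed=77, spike=spike)
    res = pooled_analyze(tables, manifest).set_index("gene")
    mean_eff = truth.shrna_efficacy.groupby(manifest.gene_of).mean()
    predicted = (truth.gene_fitness * mean_eff * cfg.duration_days).loc[res.index]
    r = np.corrcoef(predicted, res["log2_fc"])[0, 1]
    assert r >= 0.9


class TestCallHits:
    @pytest.fixture
    def results(self):
        return pd.DataFrame(
            {
                "gene": ["A", "B", "C", "PSMA1", "LUC"],
                "role": ["target", "target", "target", "positive_control", "negative_control"],
                "log2_fc": [-0.5, 0.5, -0.1, -1.0, -0.9],
                "q_value": [0.01, 0.01, 0.04, 0.001, 0.001],
            }
        )

    def test_depletion_rule(self, results):
        hits = call_hits(results)
        assert hits.candidates["gene"].tolist() == ["A"]  # B wrong direction, C fails FC
        assert set(hits.controls["gene"]) == {"PSMA1", "LUC"}

    def test_strict_boundaries(self):
        res = pd.DataFrame(
            {"gene": ["X", "Y"], "role": ["target", "target"],
             "log2_fc": [-0.2, -0.3], "q_value": [0.01, 0.05]}
        )
        hits = call_hits(res)
        assert hits.candidates.empty  # -0.2 and 0.05 are not strict hits

    def test_enriched_direction(self, results):
        hits = call_hits(results, direction="enriched")
        assert hits.candidates["gene"].tolist() == ["B"]

    def test_bad_direction_and_empty(self, results):
        with pytest.raises(InvalidConfigError):
            call_hits(results, direction="sideways")
        with pytest.raises(InvalidInputError):
            call_hits(results.iloc[0:0])
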