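import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pooledscreen import SimConfig, cpm, cyclic_loess, log2_cpm, ma_transform, normalize_table, simulate_screen
from pooledscreen.errors import DegenerateSampleError, InvalidConfigError, InvalidInputError


class TestCpm:
    def test_arithmetic(self):
        df = pd.DataFrame({"s": [1, 1, 2]})
        expected = [250_000.0, 250_000.0, 500_000.0]
        assert cpm(df)["s"].tolist() == expected

    def test_degenerate_mass(self):
        df = pd.DataFrame({"s": [10**6, 0, 0]})
        assert cpm(df)["s"].tolist() == [1e6, 0.0, 0.0]

    def test_columns_sum_to_million(self, small_screen):
        _, _, table = small_screen
        totals = cpm(table).sum(axis=0)
        assert np.allclose(totals, 1e6, rtol=1e-6)

    def test_zero_total_column_named_in_error(self):
        df = pd.DataFrame({"ok": [1, 2], "empty": [0, 0]})
        with pytest.raises(DegenerateSampleError, match="empty"):
            cpm(df)


class TestMaTransform:
    def test_identity_and_shift(self):
        y = np.array([1.0, 2.0, 3.0])
        A, M = ma_transform(y, y)
        assert np.all(M == 0)
        A, M = ma_transform(y + 2.0, y)
        assert np.allclose(M, 2.0)
        assert np.allclose(A, y + 1.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-20, 20), min_size=1, max_size=30))
    def test_invertible(self, xs):
        x = np.array(xs)
        y = x[::-1].copy()
        A, M = ma_transform(x, y)
        assert np.allclose(A + M / 2.0, x, atol=1e-12)
        assert np.allclose(A - M / 2.0, y, atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            ma_transform([1.0], [1.0, 2.0])


@pytest.fixture(scope="module")
def null_log2cpm():
    """Two null NB samples, log2 CPM: technical-replicate noise (dispersion
    0.01) at high coverage, so intensity-dependent bias — not counting
    noise — is what the normalization tests measure."""
    cfg = SimConfig(essential_effect=0.0, dispersion=0.01, seed=7).with_coverage(1000)
    _, _, table = simulate_screen(cfg, seed=7)
    return log2_cpm(table)


class TestCyclicLoess:
    def test_identical_columns_unchanged(self):
        x = np.linspace(3, 12, 200)
        df = pd.DataFrame({"a": x, "b": x})
        out = cyclic_loess(df)
        assert np.allclose(out.to_numpy(), df.to_numpy(), atol=1e-9)

    def test_constant_offset_split_evenly(self, null_log2cpm):
        """Columns differing by a constant c converge: median M -> 0 and each
        column moves c/2 toward the other (a loess fit of a constant is that
        constant)."""
        base = null_log2cpm.iloc[:, 0]
        df = pd.DataFrame({"a": base + 1.0, "b": base})
        out = cyclic_loess(df)
        _, M = ma_transform(out["a"].to_numpy(), out["b"].to_numpy())
        assert abs(np.median(M)) < 1e-6
        assert np.allclose(out["a"], base + 0.5, atol=1e-6)
        assert np.allclose(out["b"], base + 0.5, atol=1e-6)

    def test_removes_quadratic_intensity_bias(self, null_log2cpm):
        """An injected intensity-dependent bias M(A)=0.5-0.02(A-10)^2 is
        flattened: |median M| < 0.05 within every A-decile."""
        biased = null_log2cpm.copy()
        A0 = biased.mean(axis=1).to_numpy()
        biased.iloc[:, 1] += 0.5 - 0.02 * (A0 - 10.0) ** 2
        out = cyclic_loess(biased)
        A, M = ma_transform(out.iloc[:, 1].to_numpy(), out.iloc[:, 0].to_numpy())
        deciles = pd.qcut(A, 10)
        medians = pd.Series(M).groupby(deciles, observed=True).median()
        assert np.abs(medians.to_numpy()).max() < 0.05

    def test_swap_symmetry(self, null_log2cpm):
        """Swapping the two columns negates M but yields the same normalized
        value for each sample."""
        df = null_log2cpm.iloc[:500, :2].copy()
        out = cyclic_loess(df)
        swapped = df[df.columns[::-1]]
        out_swapped = cyclic_loess(swapped)
        assert np.allclose(out.to_numpy(), out_swapped[df.columns].to_numpy(), atol=1e-9)

    def test_median_m_non_increasing_over_iterations(self, null_log2cpm):
        biased = null_log2cpm.copy()
        A0 = biased.mean(axis=1).to_numpy()
        biased.iloc[:, 1] += 0.5 - 0.02 * (A0 - 10.0) ** 2
        med = []
        for its in (1, 2, 3):
            out = cyclic_loess(biased, iterations=its)
            _, M = ma_transform(out.iloc[:, 0].to_numpy(), out.iloc[:, 1].to_numpy())
            med.append(abs(np.median(M)))
        # non-increasing up to the residual-noise floor of the fixture
        assert med[2] <= med[0] + 5e-3
        assert max(med) < 0.02

    def test_single_sample_noop_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning, match=">= 2 samples"):
            out = cyclic_loess(df)
        pd.testing.assert_frame_equal(out, df)

    @pytest.mark.parametrize("span", [0.0, 1.5, -0.2])
    def test_invalid_span(self, span):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]})
        with pytest.raises(InvalidConfigError):
            cyclic_loess(df, span=span)

    def test_nonfinite_input_rejected(self):
        df = pd.DataFrame({"a": [1.0, np.inf], "b": [1.0, 2.0]})
        with pytest.raises(InvalidInputError):
            cyclic_loess(df)


def test_normalize_table_preserves_axes(small_screen):
    _, _, table = small_screen
    norm = normalize_table(table)
    assert norm.values.shape == table.counts.shape
    assert norm.values.index.equals(table.counts.index)
    assert list(norm.values.columns) == list(table.counts.columns)
    assert np.isfinite(norm.values.to_numpy()).all()
    assert norm.provenance == {"pseudocount": 0.5, "span": 0.7, "iterations": 3}
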