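import numpy as np
import pytest

from tilesplice.preprocess import (
    ArrayInfo,
    IntensityMatrix,
    background_correct,
    log2_transform,
    preprocess,
    quantile_normalize,
)


def matrix(values, state="raw"):
    values = np.asarray(values, dtype=float)
    arrays = tuple(
        ArrayInfo(f"a{i}", "control" if i < values.shape[1] // 2 else "treatment",
                  i % max(values.shape[1] // 2, 1) + 1)
        for i in range(values.shape[1])
    )
    return IntensityMatrix(
        probe_ids=tuple(f"p{i}" for i in range(values.shape[0])),
        arrays=arrays,
        values=values,
        state=state,
    )


def reference_quantile_normalize(v):
    """Independent oracle: explicit sort / average / unsort per column."""
    ref = np.sort(v, axis=0).mean(axis=1)
    out = np.empty_like(v)
    for j in range(v.shape[1]):
        order = np.argsort(v[:, j], kind="stable")
        out[order, j] = ref
    return out


class TestQuantileNormalize:
    def test_two_identical_arrays_unchanged(self):
        m = matrix([[1, 1], [5, 5], [3, 3]])
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values, m.values)

    def test_simple_two_array_example(self):
        m = matrix([[1, 4], [2, 5], [3, 6]])
        out = quantile_normalize(m)
        expected = np.array([[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])
        np.testing.assert_allclose(out.values, expected)

    def test_matches_sort_average_unsort_oracle(self, rng):
        v = rng.lognormal(3, 1, size=(100, 6))
        out = quantile_normalize(matrix(v))
        np.testing.assert_allclose(out.values, reference_quantile_normalize(v))

    def test_sorted_vectors_identical_and_ranks_preserved(self, rng):
        v = rng.lognormal(3, 1, size=(100, 6))
        out = quantile_normalize(matrix(v)).values
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, 0]), np.sort(out[:, j]))
        for j in range(6):
            # within-array monotonicity: raw a < b implies normalized a' <= b'
            order = np.argsort(v[:, j])
            assert np.all(np.diff(out[order, j]) >= 0)

    def test_idempotent_on_continuous_data(self, rng):
        v = rng.lognormal(3, 1, size=(80, 5))  # ties have probability zero
        once = quantile_normalize(matrix(v))
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_idempotent_with_shared_tie_pattern(self, rng):
        # each column is a monotone transform of one tied template, so the
        # tie spans sit at the same sorted positions in every array
        template = rng.integers(1, 12, size=60).astype(float)
        v = np.column_stack([template * c + c for c in (1.0, 2.0, 3.5, 7.0)])
        once = quantile_normalize(matrix(v))
        twice = quantile_normalize(once)
        np.testing.assert_allclose(twice.values, once.values, atol=1e-9)

    def test_tied_values_get_mean_of_spanned_quantiles(self):
        # column [1, 1, 4] spans reference ranks 1-2 with its tied pair
        m = matrix([[1.0, 2.0], [1.0, 4.0], [4.0, 6.0]])
        out = quantile_normalize(m)
        ref = np.sort(m.values, axis=0).mean(axis=1)
        assert out.values[0, 0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out.values[1, 0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out.values[2, 0] == pytest.approx(ref[2])

    def test_requires_two_arrays(self):
        with pytest.raises(ValueError, match="2 arrays"):
            quantile_normalize(matrix([[1.0], [2.0]]))


class TestBackgroundCorrect:
    def test_none_is_identity(self, rng):
        m = matrix(rng.lognormal(3, 1, size=(50, 4)))
        out = background_correct(m, method="none")
        np.testing.assert_array_equal(out.values, m.values)

    def test_constant_array_stays_constant_positive(self):
        m = matrix(np.full((40, 2), 100.0))
        out = background_correct(m, method="normexp")
        for j in range(2):
            col = out.values[:, j]
            assert np.all(col > 0)
            assert np.allclose(col, col[0])

    def test_normexp_recovers_signal_mean(self):
        """Observed = Exp(alpha) signal + Normal background: the mean
        corrected value approaches the generative signal mean 1/alpha."""
        rng = np.random.default_rng(7)
        alpha, mu, sigma = 1 / 200.0, 400.0, 40.0
        n = 100_000
        x = rng.exponential(1 / alpha, n) + rng.normal(mu, sigma, n)
        m = matrix(np.column_stack([x, x]))
        out = background_correct(m, method="normexp")
        assert out.values[:, 0].mean() == pytest.approx(1 / alpha, rel=0.05)

    def test_rejects_nonraw_state(self):
        m = matrix(np.full((5, 2), 3.0), state="normalized_log2")
        with pytest.raises(ValueError):
            background_correct(m, "normexp")


class TestLog2Transform:
    def test_known_values(self):
        m = matrix([[8.0, 1.0], [10.0, 2.0]])
        out = log2_transform(m)
        assert out.state == "normalized_log2"
        np.testing.assert_allclose(
            out.values, [[3.0, 0.0], [np.log(10) / np.log(2), 1.0]]
        )
        assert out.values[1, 0] == pytest.approx(3.3219, abs=1e-4)

    def test_double_transform_rejected(self):
        out = log2_transform(matrix([[8.0, 8.0]]))
        with pytest.raises(ValueError, match="transformed"):
            log2_transform(out)

    def test_nonpositive_raw_rejected_naming_probe(self):
        with pytest.raises(ValueError, match="p1"):
            matrix([[2.0, 2.0], [0.0, 2.0]])


def test_pipeline_order_and_state(rng):
    m = preprocess(matrix(rng.lognormal(3, 1, size=(30, 4))))
    assert m.state == "normalized_log2"
    for j in range(1, 4):
        np.testing.assert_allclose(np.sort(m.values[:, 0]), np.sort(m.values[:, j]))
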