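import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crossnorm.core_io import DataError, clean_and_match
from crossnorm.normalize import (
    NormalizationSpec,
    apply_npn_reference,
    apply_rqn,
    fit_reference_target,
    log_transform,
    nicg_scale,
    normal_scores,
    normalize,
    npn,
    quantile_normalize,
    zscore,
)
from crossnorm.selection import GeneSelection, anova_table, select_genes
from crossnorm.synthetic import SyntheticDesign, generate

from conftest import em

distinct_rows = st.lists(
    st.integers(-1000, 1000), min_size=3, max_size=12, unique=True
).map(lambda v: [float(x) for x in v])


class TestLogTransform:
    @pytest.mark.parametrize("value,expected", [(0, 0), (3, 2), (1023, 10)])
    def test_log2_with_pseudocount(self, value, expected):
        out = log_transform(em([[float(value)]] * 2), pseudo_count=1)
        assert out.values[0, 0] == pytest.approx(expected)
        assert out.scale == "log"

    def test_negative_input_rejected(self):
        with pytest.raises(DataError, match="log"):
            log_transform(em([[-1.0, 2.0]]))


class TestZscore:
    def test_direct_formula(self):
        out = zscore(em([[1.0, 2.0, 3.0]]))
        expected = (np.array([1, 2, 3]) - 2.0) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(out.values[0], expected, rtol=1e-12)
        np.testing.assert_allclose(out.values[0], [-1.2247, 0, 1.2247], atol=1e-4)

    def test_constant_row_maps_to_zero(self):
        assert (zscore(em([[5.0, 5.0, 5.0]])).values == 0).all()

    @given(distinct_rows)
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_centering_and_rank_preservation(self, row):
        out = zscore(em([row])).values[0]
        assert abs(out.mean()) < 1e-12
        assert (np.argsort(out) == np.argsort(row)).all()


class TestNormalScores:
    def test_three_sample_row(self):
        out = normal_scores(em([[10.0, 20.0, 30.0]]))
        expected = stats.norm.ppf([0.25, 0.5, 0.75])
        np.testing.assert_allclose(out.values[0], expected, rtol=1e-12)
        np.testing.assert_allclose(out.values[0], [-0.6745, 0, 0.6745], atol=1e-4)

    def test_ties_get_average_rank(self):
        assert (normal_scores(em([[7.0, 7.0]])).values == 0).all()

    @given(distinct_rows)
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_rank_preservation(self, row):
        out = normal_scores(em([row])).values[0]
        assert (np.argsort(out) == np.argsort(row)).all()


class TestNpn:
    def test_normal_target_equals_normal_scores(self):
        x = em([[10.0, 20.0, 30.0], [3.0, 1.0, 2.0]])
        np.testing.assert_array_equal(npn(x, "normal").values, normal_scores(x).values)

    def test_uniform_target_returns_percentiles(self):
        np.testing.assert_allclose(
            npn(em([[10.0, 20.0, 30.0]]), "uniform").values[0], [0.25, 0.5, 0.75]
        )
        assert (npn(em([[4.0, 4.0, 4.0]]), "uniform").values == 0.5).all()

    def test_unknown_target_rejected(self):
        with pytest.raises(DataError, match="target"):
            npn(em([[1.0, 2.0]]), "cauchy")


class TestQuantileNormalize:
    def test_single_sample_unchanged(self):
        x = em([[3.0], [1.0], [2.0]])
        np.testing.assert_array_equal(quantile_normalize(x).values, x.values)

    def test_two_column_rank_average(self):
        out = quantile_normalize(em([[2.0, 1.0], [4.0, 3.0], [6.0, 5.0]]))
        np.testing.assert_allclose(out.values, [[1.5, 1.5], [3.5, 3.5], [5.5, 5.5]])

    def test_identical_columns_unchanged(self):
        x = em([[3.0, 3.0], [1.0, 1.0], [2.0, 2.0]])
        np.testing.assert_allclose(quantile_normalize(x).values, x.values)

    def test_columns_share_value_multiset(self):
        rng = np.random.default_rng(0)
        out = quantile_normalize(em(rng.normal(size=(40, 6)))).values
        ref = np.sort(out[:, 0])
        for j in range(out.shape[1]):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_within_column_order_preserved(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(30, 4))
        out = quantile_normalize(em(v)).values
        for j in range(4):
            assert (np.argsort(out[:, j]) == np.argsort(v[:, j])).all()


class TestReferenceTarget:
    def test_all_genes_reference_equals_qn_target(self):
        x = em([[2.0, 1.0], [4.0, 3.0], [6.0, 5.0]])
        fitted = fit_reference_target(x, x.gene_ids)
        np.testing.assert_allclose(fitted.target, [1.5, 3.5, 5.5])
        assert (np.diff(fitted.target) >= 0).all()

    def test_single_reference_gene_is_its_mean(self):
        fitted = fit_reference_target(em([[2.0, 4.0], [9.0, 9.0]]), ["g1"])
        np.testing.assert_allclose(fitted.target, [3.0])

    def test_empty_reference_rejected(self):
        with pytest.raises(DataError, match="reference"):
            fit_reference_target(em([[1.0, 2.0]]), [])


class TestApplyRqn:
    def test_matches_qn_when_reference_is_everything(self):
        rng = np.random.default_rng(2)
        x = em(rng.normal(size=(25, 5)))  # distinct values: grids coincide exactly
        fitted = fit_reference_target(x, x.gene_ids)
        np.testing.assert_allclose(
            apply_rqn(x, fitted).values, quantile_normalize(x).values, atol=1e-10
        )

    def test_interpolation_against_hand_oracle(self):
        # G=4, m=2, target (0,10): u=.125/.375/.625/.875 vs nodes .25/.75
        # -> clamp, 0+ (0.125/0.5)*10, 0+(0.375/0.5)*10, clamp
        x = em([[5.0], [1.0], [9.0], [3.0]])
        fitted = fit_reference_target(em([[0.0], [10.0]]), ["g1", "g2"])
        np.testing.assert_allclose(apply_rqn(x, fitted).values[:, 0], [7.5, 0.0, 10.0, 2.5])

    def test_depends_only_on_ranks(self):
        x = em([[1.0, 10.0], [2.0, 30.0], [3.0, 31.0]])
        fitted = fit_reference_target(em([[0.0, 0.0], [6.0, 6.0]]), ["g1", "g2"])
        out = apply_rqn(x, fitted).values
        np.testing.assert_allclose(out[:, 0], out[:, 1])

    def test_single_reference_gene_rejected(self):
        from crossnorm.normalize import FittedNormalizer

        with pytest.raises(DataError, match="at least 2"):
            apply_rqn(em([[1.0]]), FittedNormalizer(["g1"], np.array([3.0])))

    def test_npn_reference_shares_mechanics(self):
        rng = np.random.default_rng(3)
        x = em(rng.normal(size=(12, 3)))
        fitted = fit_reference_target(x, x.gene_ids[:5])
        np.testing.assert_array_equal(
            apply_npn_reference(x, fitted).values, apply_rqn(x, fitted).values
        )


class TestNicg:
    def test_reference_mean_subtracted_per_sample(self):
        x = em([[2.0, 8.0], [4.0, 0.0], [7.0, 1.0]], scale="log")
        out = nicg_scale(x, ["g1", "g2"])  # ref means: 3, 4
        np.testing.assert_allclose(out.values, [[-1, 4], [1, -4], [4, -3]])
        ref_after = out.subset_genes(["g1", "g2"]).values.mean(axis=0)
        assert np.abs(ref_after).max() < 1e-12

    def test_all_genes_reference_centers_columns(self):
        x = em([[2.0, 8.0], [4.0, 0.0]], scale="log")
        out = nicg_scale(x, x.gene_ids)
        assert np.abs(out.values.mean(axis=0)).max() < 1e-12

    def test_linear_input_rejected(self):
        with pytest.raises(DataError, match="log"):
            nicg_scale(em([[1.0, 2.0]]), ["g1"])


class TestNormalizeDispatch:
    def _sel(self, ndeg):
        return GeneSelection(deg=[], ndeg=ndeg, tau_deg=0.05, tau_ndeg=0.95)

    def test_log_on_zeros_is_zeros(self):
        out = normalize(em(np.zeros((3, 2))), NormalizationSpec("LOG"))
        assert (out.values == 0).all()

    def test_log_rqn_z_rows_are_centered(self):
        rng = np.random.default_rng(4)
        x = em(rng.gamma(2, 50, size=(20, 6)))
        out = normalize(x, NormalizationSpec("LOG_RQN_Z"), self._sel(x.gene_ids[:8]))
        assert np.abs(out.values.mean(axis=1)).max() < 1e-10

    def test_log_rqn_with_full_reference_equals_log_then_qn(self):
        rng = np.random.default_rng(5)
        x = em(rng.gamma(2, 50, size=(15, 4)))
        out = normalize(x, NormalizationSpec("LOG_RQN"), self._sel(list(x.gene_ids)))
        ref = quantile_normalize(log_transform(x))
        np.testing.assert_allclose(out.values, ref.values, atol=1e-10)

    def test_reference_method_needs_ndeg(self):
        with pytest.raises(DataError, match="NDEG"):
            normalize(em([[1.0, 2.0]]), NormalizationSpec("LOG_RQN"), self._sel([]))

    def test_unknown_method_rejected(self):
        with pytest.raises(DataError, match="unknown"):
            NormalizationSpec("SHIFT")


class TestPlatformAlignment:
    def test_referenced_qn_with_standardization_aligns_platforms(self):
        """NDEG-referenced quantile mapping followed by standardization brings
        the two platforms' per-gene distributions much closer under a monotone
        platform distortion, and closer than standardization alone.

        LOG_RQN without the final Z intentionally keeps each platform on its
        own NDEG-derived scale (fitting is per platform), so the scale-free
        composite is the right place to measure cross-platform alignment.
        """
        a, b, labels, _ = generate(SyntheticDesign(n_genes=300, n_deg=30, dropout_rate=0.0))
        pair = clean_and_match(a, b, labels)
        table = anova_table(pair.matrix_b, labels.restrict(pair.matrix_b.sample_ids))
        sel = select_genes(table, 0.05, 0.95)

        def mean_ks(x, y):
            return np.mean([
                stats.ks_2samp(x.values[i], y.values[i], method="asymp").statistic
                for i in range(x.n_genes)
            ])

        def after(method):
            na = normalize(pair.matrix_a, NormalizationSpec(method), sel)
            nb = normalize(pair.matrix_b, NormalizationSpec(method), sel)
            return mean_ks(na, nb)

        before = mean_ks(pair.matrix_a, pair.matrix_b)
        assert after("LOG_RQN_Z") < before
        assert after("LOG_RQN_Z") < after("Z")
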