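"""Normalization, filters, Mann-Whitney DE, and BH adjustment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cerna import (
    ExpressionMatrix,
    bh_adjust,
    differential_expression,
    fpkm_normalize,
    log2iqr_filter,
    mann_whitney_p,
    presence_filter,
)
from cerna.expression import ExpressionError
from cerna.simulate import PlantedTriplet, SimulationConfig, simulate_cohort


def make_matrix(values, lengths=None, conditions=None, rna_class="mRNA"):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_feat, n_samp = values.shape
    fids = [f"f{i}" for i in range(n_feat)]
    sids = [f"s{j}" for j in range(n_samp)]
    fmeta = pd.DataFrame({"rna_class": rna_class}, index=pd.Index(fids))
    if lengths is not None:
        fmeta["length"] = lengths
    if conditions is None:
        conditions = ["tumor"] * (n_samp // 2) + ["normal"] * (n_samp - n_samp // 2)
    smeta = pd.DataFrame({"condition": conditions}, index=pd.Index(sids))
    return ExpressionMatrix(pd.DataFrame(values, index=fids, columns=sids), fmeta, smeta)


class TestFpkm:
    def test_unit_definition(self):
        # count 10, length 1000 nt, library size 1e6 -> FPKM 10
        mat = make_matrix([[10.0], [999_990.0]], lengths=[1000, 5000],
                          conditions=["tumor"])
        fpkm = fpkm_normalize(mat)
        assert fpkm.values.iloc[0, 0] == pytest.approx(10.0)

    def test_hand_arithmetic(self):
        # count 7, length 2500, library 3.2e6 -> 0.875
        mat = make_matrix([[7.0], [3_199_993.0]], lengths=[2500, 1000],
                          conditions=["tumor"])
        assert fpkm_normalize(mat).values.iloc[0, 0] == pytest.approx(0.875)

    def test_zero_count_maps_to_zero(self):
        mat = make_matrix([[0.0], [100.0]], lengths=[1000, 1000],
                          conditions=["tumor"])
        assert fpkm_normalize(mat).values.iloc[0, 0] == 0.0

    def test_scale_equivariance_per_sample(self, rng):
        counts = rng.poisson(50, size=(10, 4)).astype(float) + 1
        lengths = rng.integers(500, 3000, 10)
        a = fpkm_normalize(make_matrix(counts, lengths=lengths))
        doubled = counts.copy()
        doubled[:, 2] *= 2  # doubling every count of one sample
        b = fpkm_normalize(make_matrix(doubled, lengths=lengths))
        np.testing.assert_allclose(a.values.to_numpy(), b.values.to_numpy())

    def test_missing_length_is_an_error(self):
        mat = make_matrix([[1.0, 2.0]])
        with pytest.raises(ExpressionError, match="length"):
            fpkm_normalize(mat)


class TestFilters:
    def test_constant_feature_removed(self):
        mat = make_matrix([[5.0] * 6])
        assert log2iqr_filter(mat, 0.5) == []

    def test_linear_interpolation_quartiles(self):
        # log2(x+1) values {0,1,2,3} -> type-7 IQR = 1.5 > 0.5 -> retained
        mat = make_matrix([[0.0, 1.0, 3.0, 7.0]])
        assert log2iqr_filter(mat, 0.5) == ["f0"]
        assert log2iqr_filter(mat, 1.5) == []  # strict inequality

    def test_threshold_zero_keeps_any_nonconstant(self):
        mat = make_matrix([[1.0, 1.0, 1.0, 2.0]])
        assert log2iqr_filter(mat, 0.0) == ["f0"]

    @pytest.mark.parametrize(
        "n_pos,kept", [(8, True), (7, False), (0, False)]
    )
    def test_presence_is_strictly_more_than(self, n_pos, kept):
        row = [1.0] * n_pos + [0.0] * (10 - n_pos)
        mat = make_matrix([row])
        assert (presence_filter(mat, 0.70) == ["f0"]) is kept


class TestMannWhitney:
    def test_identical_groups_p_is_one(self):
        assert mann_whitney_p([3, 3, 3], [3, 3, 3]) == 1.0

    def test_disjoint_small_groups_exact(self):
        # no overlap, 3 vs 3: U = 0, two-sided exact p = 2/20
        assert mann_whitney_p([2, 3, 4], [20, 30, 40]) == pytest.approx(0.1)

    def test_exact_matches_labeling_enumeration(self, rng):
        """Exact path equals brute-force enumeration of group labelings,
        including under ties."""
        for n1, n2 in [(2, 3), (3, 3), (4, 4), (5, 3), (8, 8)]:
            x = rng.integers(0, 6, n1).astype(float)  # ties likely
            y = rng.integers(0, 6, n2).astype(float)
            pooled = np.concatenate([x, y])
            u_obs = stats.mannwhitneyu(x, y).statistic
            mu = n1 * n2 / 2
            hits = total = 0
            for idx in itertools.combinations(range(n1 + n2), n1):
                mask = np.zeros(n1 + n2, bool)
                mask[list(idx)] = True
                u = stats.mannwhitneyu(pooled[mask], pooled[~mask]).statistic
                total += 1
                hits += abs(u - mu) >= abs(u_obs - mu) - 1e-12
            assert mann_whitney_p(x, y) == pytest.approx(hits / total)

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            mann_whitney_p([1.0], [2.0, 3.0])


class TestBhAdjust:
    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_equal_and_singleton(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels_and_preserves_order(self, pvals):
        q = bh_adjust(pvals)
        expected = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(q, expected, atol=1e-12)
        order = np.argsort(pvals, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestDifferentialExpression:
    def test_planted_logfc_recovered_and_significant(self):
        cfg = SimulationConfig(
            n_tumor=100, n_normal=100,
            planted_triplets=[PlantedTriplet("L1", "M1", "G1", logfc_mrna=2.0)],
            n_mrna=5, seed=42,
        )
        mats, _ = simulate_cohort(cfg)
        de = differential_expression(mats["mRNA"]).set_index("feature_id")
        assert de.loc["G1", "logFC"] == pytest.approx(2.0, abs=0.3)
        assert de.loc["G1", "q"] < 0.05

    def test_null_features_control_fdr(self):
        cfg = SimulationConfig(n_tumor=30, n_normal=30,
                               planted_triplets=[], n_mrna=200, seed=7)
        mats, _ = simulate_cohort(cfg)
        de = differential_expression(mats["mRNA"])
        assert de["significant"].mean() <= 0.05 + 0.03

    def test_single_sample_group_rejected(self):
        mat = make_matrix([[1.0, 2.0, 3.0]], conditions=["tumor", "normal", "normal"])
        with pytest.raises(ExpressionError, match=">= 2 samples"):
            differential_expression(mat)
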