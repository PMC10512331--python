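import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from coexhub.data_model import DataModelError, PipelineConfig
from coexhub.normalize_de import (
    NormalizationResult,
    bh_adjust,
    call_degs,
    cpm_matrix,
    estimate_common_dispersion,
    nb_exact_test,
    tmm_factors,
    timepoint_contrasts,
)

from conftest import make_counts, make_samples
from _oracles import tmm_log2_factor


def unit_norm(cm):
    """Normalization with all factors 1 (effective size = library size)."""
    return NormalizationResult(
        sample_ids=list(cm.sample_ids),
        library_sizes=cm.library_sizes(),
        tmm_factors=np.ones(cm.n_samples),
        reference_sample=cm.sample_ids[0],
    )


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        col = [[10], [25], [3], [70]]
        cm = make_counts(np.hstack([col, col, col]))
        res = tmm_factors(cm)
        np.testing.assert_allclose(res.tmm_factors, 1.0, atol=1e-12)

    def test_pure_library_size_scaling_absorbed(self):
        a = np.array([10, 25, 3, 70, 200, 55])
        cm = make_counts(np.column_stack([a, 3 * a]))
        res = tmm_factors(cm)
        np.testing.assert_allclose(res.tmm_factors, 1.0, atol=1e-12)

    def test_factors_match_direct_formula_oracle(self):
        # fixed 8-gene x 3-sample matrix, chosen tie-free in M and A
        y = np.array([
            [120, 95, 310],
            [40, 61, 22],
            [900, 410, 700],
            [15, 33, 9],
            [260, 290, 180],
            [75, 52, 130],
            [480, 610, 333],
            [8, 17, 41],
        ])
        cm = make_counts(y)
        res = tmm_factors(cm, reference="g_ref" if False else cm.sample_ids[0])
        logf = [tmm_log2_factor(y[:, k], y[:, 0]) for k in range(3)]
        expected = 2.0 ** np.array(logf)
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(res.tmm_factors, expected, rtol=1e-12)

    def test_geometric_mean_is_one(self, rng):
        cm = make_counts(rng.integers(1, 1000, size=(60, 6)),
                         samples=make_samples(reps=3))
        res = tmm_factors(cm)
        assert abs(np.mean(np.log(res.tmm_factors))) < 1e-9

    def test_gene_permutation_invariance(self, rng):
        y = rng.integers(0, 500, size=(40, 4))
        cm = make_counts(y)
        perm = rng.permutation(40)
        cm_p = make_counts(y[perm], gene_ids=[f"g{i}" for i in perm])
        ref = cm.sample_ids[0]
        np.testing.assert_allclose(tmm_factors(cm, reference=ref).tmm_factors,
                                   tmm_factors(cm_p, reference=ref).tmm_factors)

    def test_rescaling_one_sample_barely_moves_factor(self, rng):
        # depth rescaling is absorbed by the library size; the factor moves
        # only through the depth-dependent precision weights, so the
        # invariance is approximate rather than exact
        y = rng.integers(1, 400, size=(50, 3))
        y2 = y.copy()
        y2[:, 2] *= 7
        ref = "s0"
        f1 = tmm_factors(make_counts(y), reference=ref).tmm_factors
        f2 = tmm_factors(make_counts(y2), reference=ref).tmm_factors
        np.testing.assert_allclose(f1, f2, rtol=0.05)

    def test_all_zero_sample_rejected(self):
        y = np.array([[1, 0], [2, 0]])
        with pytest.raises(DataModelError, match="all-zero"):
            tmm_factors(make_counts(y))


class TestCPM:
    def test_unit_definition(self):
        y = np.zeros((2, 2), dtype=int)
        y[0] = [10, 10]
        y[1] = [999990, 999990]
        cm = make_counts(y)
        out = cpm_matrix(cm, unit_norm(cm))
        np.testing.assert_allclose(out.loc["g0"], 10.0)

    def test_doubling_counts_leaves_cpm(self, rng):
        y = rng.integers(1, 100, size=(5, 4))
        cm1, cm2 = make_counts(y), make_counts(2 * y)
        out1 = cpm_matrix(cm1, unit_norm(cm1))
        out2 = cpm_matrix(cm2, unit_norm(cm2))
        np.testing.assert_allclose(out1.values, out2.values)

    def test_spot_values_against_formula(self, rng):
        y = rng.integers(0, 200, size=(5, 4))
        cm = make_counts(y)
        norm = tmm_factors(cm)
        out = cpm_matrix(cm, norm, log=True, prior_count=0.5)
        eff = norm.library_sizes * norm.tmm_factors
        for i in range(5):
            for j in range(4):
                expect = np.log2(y[i, j] / eff[j] * 1e6 + 0.5)
                assert out.iloc[i, j] == pytest.approx(expect, rel=1e-12)

    def test_mismatched_samples_rejected(self, rng):
        cm = make_counts(rng.integers(1, 9, size=(3, 4)))
        other = make_counts(rng.integers(1, 9, size=(3, 2)))
        with pytest.raises(DataModelError):
            cpm_matrix(cm, unit_norm(other))


class TestDispersion:
    def test_poisson_counts_give_near_zero(self, rng):
        means = rng.lognormal(5, 1, size=2000)
        y = rng.poisson(means[:, None], size=(2000, 6))
        cm = make_counts(y, samples=make_samples(reps=3))
        groups = ["a", "a", "a", "b", "b", "b"]
        assert estimate_common_dispersion(cm, groups) < 0.02

    def test_recovers_planted_dispersion(self, rng):
        phi = 0.4
        r = 1 / phi
        means = rng.lognormal(5, 1, size=2000)
        y = rng.negative_binomial(r, r / (r + means[:, None]), size=(2000, 6))
        cm = make_counts(y, samples=make_samples(reps=3))
        est = estimate_common_dispersion(cm, ["a"] * 3 + ["b"] * 3)
        assert est == pytest.approx(phi, abs=0.1)

    def test_identical_replicates_give_zero(self):
        col = np.array([[5], [40], [7]])
        y = np.hstack([col, col, col, col])
        cm = make_counts(y)
        assert estimate_common_dispersion(cm, ["a", "a", "b", "b"]) == 0.0

    def test_requires_replication(self):
        cm = make_counts(np.array([[1, 2], [3, 4]]))
        with pytest.raises(DataModelError):
            estimate_common_dispersion(cm, ["a", "b"])


class TestExactTest:
    def two_sample_matrix(self, a, b):
        """One treatment and one control library with equal totals."""
        filler_a, filler_b = 1000 - a, 1000 - b
        y = np.array([[a, b], [filler_a, filler_b]])
        return make_counts(y)

    def test_identical_groups_are_null(self):
        y = np.array([[10, 10, 10, 10], [500, 500, 500, 500]])
        cm = make_counts(y)
        out = nb_exact_test(cm, unit_norm(cm), ["s0", "s2"], ["s1", "s3"],
                            phi=0.1)
        assert out["log2fc"].tolist() == [0.0, 0.0]
        assert out["pvalue"].tolist() == [1.0, 1.0]

    def test_zero_vs_ten_binomial_closed_form(self):
        cm = self.two_sample_matrix(0, 10)
        out = nb_exact_test(cm, unit_norm(cm), ["s0"], ["s1"], phi=0.0)
        assert out["pvalue"].iloc[0] == pytest.approx(2 * 0.5 ** 10, rel=1e-12)
        assert out["pvalue"].iloc[0] == pytest.approx(0.001953125)

    @pytest.mark.parametrize("n_a,n_b", [(1, 1), (2, 3)])
    def test_phi_zero_matches_exact_binomial(self, n_a, n_b):
        # every outcome for every total 1..50 against scipy's exact test
        from coexhub.normalize_de import _exact_pvalue

        p_null = n_a / (n_a + n_b)
        for total in range(1, 51):
            for k in range(total + 1):
                ours = _exact_pvalue(k, total, n_a, n_b, 0.0)
                ref = stats.binomtest(k, total, p_null).pvalue
                assert ours == pytest.approx(ref, rel=1e-9), (total, k)

    def test_direction_of_fold_change(self):
        cm = self.two_sample_matrix(200, 40)
        out = nb_exact_test(cm, unit_norm(cm), ["s0"], ["s1"], phi=0.0)
        assert out["log2fc"].iloc[0] > 1.5
        assert out["pvalue"].iloc[0] < 1e-6

    def test_empty_group_rejected(self):
        cm = self.two_sample_matrix(5, 5)
        with pytest.raises(DataModelError):
            nb_exact_test(cm, unit_norm(cm), [], ["s1"], phi=0.0)


class TestBH:
    def test_single_p_passes_through(self):
        np.testing.assert_allclose(bh_adjust([0.03]), [0.03])

    def test_hand_worked_stepup(self):
        q = bh_adjust([0.005, 0.01, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.02, 0.02, 0.04, 0.04])

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataModelError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1,
                    max_size=40))
    def test_stepup_properties(self, ps):
        q = bh_adjust(ps)
        assert np.all(q >= np.asarray(ps) - 1e-15)
        assert np.all(q <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in p

    def test_fixed_points_of_stepup(self):
        # constant vectors are exact fixed points of the step-up procedure
        np.testing.assert_allclose(bh_adjust([0.04] * 4), [0.04] * 4)
        # re-adjusting never lowers an already-adjusted value
        q = bh_adjust([0.005, 0.01, 0.03, 0.04])
        assert np.all(bh_adjust(q) >= q - 1e-15)


class TestCalling:
    def frame(self, lfc, p):
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(len(lfc))],
            "contrast_id": "c",
            "timepoint_h": 6.0,
            "log2fc": lfc,
            "pvalue": p,
            "qvalue": np.nan,
            "call": "ns",
        })

    def test_thresholds_are_strict(self):
        # single-gene families: q equals p exactly
        out = call_degs(self.frame([1.5], [0.01]))
        assert out["call"].iloc[0] == "ns"  # log2fc must EXCEED 1.5
        out = call_degs(self.frame([-3.0], [0.05]))
        assert out["call"].iloc[0] == "ns"  # q must be BELOW 0.05

    def test_both_thresholds_met(self):
        out = call_degs(self.frame([2.0], [0.049]))
        assert out["call"].iloc[0] == "up"
        out = call_degs(self.frame([-2.0], [0.049]))
        assert out["call"].iloc[0] == "down"

    def test_calls_partition_genes(self, rng):
        lfc = rng.normal(0, 3, size=200)
        p = rng.uniform(0, 1, size=200)
        out = call_degs(self.frame(lfc, p))
        assert out["call"].isin(["up", "down", "ns"]).all()
        assert len(out) == 200
        assert (out["qvalue"] >= out["pvalue"] - 1e-15).all()


def test_timepoint_contrasts_cover_design():
    cm = make_counts(np.ones((2, 12), dtype=int),
                     samples=make_samples(timepoints=[6.0, 24.0, 36.0], reps=2))
    contrasts = timepoint_contrasts(cm)
    assert [tp for _, tp, _, _ in contrasts] == [6.0, 24.0, 36.0]
    for _, _, treat, ctrl in contrasts:
        assert len(treat) == 2 and len(ctrl) == 2
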