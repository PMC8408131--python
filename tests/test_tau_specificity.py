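"""Tau index, classification, composite score, housekeeping calls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from floramark import tau_specificity as tsp


class TestTau:
    def test_single_tissue_profile_is_one(self):
        assert tsp.tau([5, 0, 0, 0, 0, 0, 0, 0, 0, 0]) == pytest.approx(1.0)

    def test_uniform_profile_is_zero(self):
        assert tsp.tau([3] * 10) == pytest.approx(0.0)

    def test_two_tissue_profile_closed_form(self):
        # x = (1,1,0,...,0) over 10 tissues: sum(1-x) = 8, tau = 8/9
        assert tsp.tau([10, 10] + [0] * 8) == pytest.approx(8 / 9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            tsp.tau([0, 0, 0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=1e5, allow_nan=False),
                 min_size=2, max_size=15).filter(lambda v: max(v) > 0),
        st.floats(min_value=1e-3, max_value=1e3),
    )
    def test_scale_invariance(self, profile, c):
        assert tsp.tau(np.array(profile) * c) == pytest.approx(tsp.tau(profile), abs=1e-9)

    def test_monotone_in_concentration(self):
        """Moving mass from a low tissue to the max tissue never lowers tau."""
        rng = np.random.default_rng(0)
        for _ in range(25):
            v = rng.uniform(0.1, 10, size=8)
            i_max, i_low = int(np.argmax(v)), int(np.argmin(v))
            shift = v[i_low] * 0.5
            w = v.copy()
            w[i_max] += shift
            w[i_low] -= shift
            assert tsp.tau(w) >= tsp.tau(v) - 1e-12

    def test_table_matches_scalar(self, small_profile):
        sub = small_profile[small_profile.max(axis=1) > 0].head(30)
        table = tsp.tau_profile_table(sub)
        for g in sub.index[:5]:
            assert table[g] == pytest.approx(tsp.tau(sub.loc[g]))


class TestTauExpressionFraction:
    def test_argmax_tissue_carries_full_tau(self):
        qn = pd.DataFrame([[100.0, 50.0, 0.0]], columns=list("abc"))
        tef = tsp.tau_expression_fraction([0.9], qn)
        np.testing.assert_allclose(tef.iloc[0], [0.9, 0.45, 0.0])

    def test_zero_tau_gives_zero_everywhere(self):
        qn = pd.DataFrame([[5.0, 7.0, 2.0]])
        assert (tsp.tau_expression_fraction([0.0], qn).iloc[0] == 0).all()

    def test_exactly_one_tissue_attains_tau(self, small_profile):
        sub = small_profile[small_profile.max(axis=1) > 0].head(40)
        taus = tsp.tau_profile_table(sub)
        tef = tsp.tau_expression_fraction(taus.to_numpy(), sub)
        pos = taus > 0
        n_at_max = (tef.loc[pos].eq(taus[pos], axis=0)).sum(axis=1)
        assert (n_at_max >= 1).all()


class TestClassification:
    @pytest.mark.parametrize(
        "tau,expected",
        [(1.0, "ASG"), (0.9, "HSG"), (0.85, "HSG"), (0.5, "intermediate"),
         (0.2, "intermediate"), (0.1, "constitutive"), (0.0, "constitutive")],
    )
    def test_thresholds(self, tau, expected):
        assert tsp.classify_specificity(tau) == expected

    def test_partition_is_exhaustive(self):
        taus = pd.Series(np.linspace(0, 1, 101))
        klass = tsp.classify_specificity(taus)
        assert set(klass) <= {"ASG", "HSG", "intermediate", "constitutive"}
        assert klass.notna().all()


class TestGeneScore:
    def test_bounds_and_attainment(self):
        qn = pd.DataFrame({"t1": [10.0, 5.0, 0.0], "t2": [0.0, 1.0, 8.0]})
        tef = pd.DataFrame({"t1": [1.0, 0.3, 0.0], "t2": [0.0, 0.1, 0.9]})
        scores = tsp.gene_score(tef, qn)
        assert scores.to_numpy().max() <= 2.0
        assert scores.loc[0, "t1"] == pytest.approx(2.0)  # tau_ef 1 + tissue max
        assert scores.loc[0, "t2"] == pytest.approx(0.0)  # tau_ef 0 + tissue min

    def test_sum_structure(self):
        qn = pd.DataFrame({"t1": [0.0, 2.0, 8.0]})
        tef = pd.DataFrame({"t1": [0.0, 0.5, 0.0]})
        scores = tsp.gene_score(tef, qn)
        assert scores.loc[1, "t1"] == pytest.approx(0.5 + 0.25)

    def test_constant_column_scales_to_zero_with_warning(self):
        qn = pd.DataFrame({"t1": [3.0, 3.0]})
        tef = pd.DataFrame({"t1": [0.2, 0.4]})
        with pytest.warns(UserWarning, match="constant"):
            scores = tsp.gene_score(tef, qn)
        np.testing.assert_allclose(scores["t1"], [0.2, 0.4])


class TestRanking:
    def test_planted_specific_genes_rank_top(self, small_profile, small_dataset):
        _, _, truth = small_dataset
        sub = small_profile[small_profile.max(axis=1) > 0]
        table = tsp.build_tau_table(sub)
        ranked = tsp.rank_optimum_genes(table.scores, table.summary["tau"], k=10)
        spec = truth[truth["klass"] == "specific"]
        hits = 0
        for g, row in spec.iterrows():
            if g in ranked[row["target_tissue"]].index:
                hits += 1
        assert hits / len(spec) >= 0.9

    def test_k_larger_than_gene_count_returns_all(self):
        scores = pd.DataFrame({"t1": [1.0, 0.5]}, index=["a", "b"])
        taus = pd.Series([0.9, 0.8], index=["a", "b"])
        with pytest.warns(UserWarning, match="fewer genes"):
            out = tsp.rank_optimum_genes(scores, taus, k=10)
        assert len(out["t1"]) == 2

    def test_deterministic_tie_break(self):
        scores = pd.DataFrame({"t1": [1.0, 1.0, 1.0]}, index=["b", "c", "a"])
        taus = pd.Series([0.5, 0.7, 0.5], index=["b", "c", "a"])
        out = tsp.rank_optimum_genes(scores, taus, k=3)["t1"]
        assert list(out.index) == ["c", "a", "b"]  # tau desc, then gene id


class TestHousekeeping:
    def _profile(self):
        return pd.DataFrame(
            {
                "t1": [150.0, 50.0, 500.0, 300.0],
                "t2": [150.0, 50.0, 0.0, 290.0],
                "t3": [150.0, 50.0, 0.0, 310.0],
            },
            index=["uniform150", "uniform50", "specific", "wobbly300"],
        )

    def test_uniform_abundant_gene_included(self):
        prof = self._profile()
        taus = tsp.tau_profile_table(prof)
        hk = tsp.housekeeping_genes(taus, prof)
        assert "uniform150" in hk.index

    def test_low_expression_excluded(self):
        prof = self._profile()
        hk = tsp.housekeeping_genes(tsp.tau_profile_table(prof), prof)
        assert "uniform50" not in hk.index

    def test_specific_gene_excluded(self):
        prof = self._profile()
        hk = tsp.housekeeping_genes(tsp.tau_profile_table(prof), prof)
        assert "specific" not in hk.index

    def test_sorted_by_tpm_sd_ascending(self):
        prof = self._profile()
        hk = tsp.housekeeping_genes(tsp.tau_profile_table(prof), prof)
        assert list(hk.index) == ["uniform150", "wobbly300"]
        assert hk["tpm_sd"].is_monotonic_increasing

    def test_exact_zero_threshold_expressible(self):
        prof = self._profile()
        taus = tsp.tau_profile_table(prof)
        hk = tsp.housekeeping_genes(taus, prof, tau_max=0.0)
        assert list(hk.index) == ["uniform150"]


class TestBuildTauTable:
    def test_recovery_of_planted_classes(self, small_profile, small_dataset):
        _, _, truth = small_dataset
        sub = small_profile[small_profile.max(axis=1) > 0]
        table = tsp.build_tau_table(sub)
        spec = truth[truth["klass"] == "specific"].index.intersection(sub.index)
        frac_hsg = table.summary.loc[spec, "klass"].isin(["ASG", "HSG"]).mean()
        assert frac_hsg >= 0.95
        hk_truth = truth[truth["klass"] == "housekeeping"].index.intersection(sub.index)
        hk = tsp.housekeeping_genes(table.summary["tau_bin"], sub)
        assert len(hk.index.intersection(hk_truth)) / len(hk_truth) >= 0.95

    def test_bin_flag_switches_primary_tau(self, small_profile):
        sub = small_profile[small_profile.max(axis=1) > 0].head(100)
        cont = tsp.build_tau_table(sub, tau_on_bins=False)
        binned = tsp.build_tau_table(sub, tau_on_bins=True)
        pd.testing.assert_series_equal(
            binned.summary["tau"], binned.summary["tau_bin"], check_names=False
        )
        assert not cont.summary["tau"].equals(binned.summary["tau"])
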