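import dataclasses

import numpy as np
import pytest

from tppc import (
    AnalysisConfig,
    bh_adjust,
    build_null,
    classify_pairs,
    compute_pair_statistics,
    count_thresholds,
    empirical_pvalue,
    permute_componentwise,
    summarize_direction_changes,
)
from tppc.categorization import PairStatistics
from tppc.exceptions import SpecificationError
from tppc.synthetic_data import SyntheticSpec, generate_dataset

from conftest import classify_dataset, noise_dataset


class TestPermuteComponentwise:
    def test_value_multisets_preserved(self):
        ds = noise_dataset(seed=1)
        permuted = permute_componentwise(ds, np.random.default_rng(0))
        for layer in ("transcripts", "metabolites"):
            before = getattr(ds, layer).values
            after = getattr(permuted, layer).values
            np.testing.assert_array_equal(np.sort(before, axis=1), np.sort(after, axis=1))
            assert getattr(permuted, layer).variable_ids == getattr(ds, layer).variable_ids

    def test_same_seed_reproduces_permutation(self):
        ds = noise_dataset(seed=2)
        a = permute_componentwise(ds, np.random.default_rng(7))
        b = permute_componentwise(ds, np.random.default_rng(7))
        np.testing.assert_array_equal(a.transcripts.values, b.transcripts.values)
        np.testing.assert_array_equal(a.metabolites.values, b.metabolites.values)

    def test_variables_receive_distinct_permutations(self):
        # with 40 samples, two rows drawing the same permutation is ~1/40!
        ds = noise_dataset(n_transcripts=2, n_metabolites=2, n_samples=40, seed=3)
        coincidences = 0
        for trial in range(50):
            permuted = permute_componentwise(ds, np.random.default_rng(trial))
            order0 = np.argsort(permuted.transcripts.values[0])
            order1 = np.argsort(permuted.transcripts.values[1])
            ref0 = np.argsort(ds.transcripts.values[0])
            ref1 = np.argsort(ds.transcripts.values[1])
            if np.array_equal(order0[ref0.argsort()], order1[ref1.argsort()]):
                coincidences += 1
        assert coincidences <= 1


class TestBuildNull:
    def test_shapes_and_pair_count(self):
        ds = noise_dataset(n_metabolites=10, seed=4)
        config = AnalysisConfig(n_pcs=2, n_permutations=100, seed=0)
        null = build_null(ds, config)
        assert null.null_pearson.shape == (100, 45)
        assert null.null_partial.shape == (100, 45)
        assert null.null_diff.shape == (100, 45)
        assert len(null.pair_index) == 45

    def test_bit_identical_given_same_config(self):
        ds = noise_dataset(n_metabolites=6, seed=5)
        config = AnalysisConfig(n_pcs=2, n_permutations=100, seed=123)
        a = build_null(ds, config)
        b = build_null(ds, config)
        np.testing.assert_array_equal(a.null_pearson, b.null_pearson)
        np.testing.assert_array_equal(a.null_partial, b.null_partial)
        np.testing.assert_array_equal(a.null_diff, b.null_diff)

    def test_null_pearson_centered_at_zero_with_sampling_scale(self):
        n = 40
        ds = noise_dataset(n_metabolites=8, n_samples=n, seed=6)
        config = AnalysisConfig(n_pcs=2, n_permutations=200, seed=1)
        null = build_null(ds, config)
        assert abs(null.null_pearson.mean()) < 0.02
        # E|r| under independence is ~ sqrt(2/pi)/sqrt(n-1) ~ 0.128 here
        mean_abs = np.abs(null.null_pearson).mean()
        assert 0.5 / np.sqrt(n) < mean_abs < 2.0 / np.sqrt(n)

    def test_permute_metabolites_only_option(self):
        ds = noise_dataset(n_metabolites=6, seed=7)
        config = AnalysisConfig(
            n_pcs=2, n_permutations=100, seed=3, permute_layers="metabolites"
        )
        null = build_null(ds, config)
        assert null.null_pearson.shape == (100, 15)


class TestEmpiricalPValue:
    def test_observed_beyond_all_nulls(self):
        null = np.linspace(-0.5, 0.5, 999)
        assert empirical_pvalue(0.9, null) == pytest.approx(1 / 1000)

    def test_observed_zero_with_nonzero_null_gives_one(self):
        null = np.concatenate([np.linspace(0.01, 1, 500), -np.linspace(0.01, 1, 499)])
        assert empirical_pvalue(0.0, null) == 1.0

    def test_observed_at_median_magnitude(self):
        null = np.linspace(-1, 1, 999)
        p = empirical_pvalue(0.5, null)
        assert p == pytest.approx(0.5, abs=0.01)

    def test_too_small_null_rejected(self):
        with pytest.raises(SpecificationError):
            empirical_pvalue(0.5, np.ones(50))
        with pytest.raises(SpecificationError):
            empirical_pvalue(0.5, [])


class TestBHAdjust:
    def test_step_up_arithmetic(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_order_equivariance(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.001, 1, 20)
        perm = rng.permutation(20)
        np.testing.assert_allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_monotone_capped_and_dominates_input(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(1e-4, 1, 50)
        q = bh_adjust(p)
        assert np.all(q <= 1.0)
        assert np.all(q >= p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(SpecificationError):
            bh_adjust([0.0, 0.5])
        with pytest.raises(SpecificationError):
            bh_adjust([0.5, 1.2])


class TestComputePairStatistics:
    def test_pair_count_and_id_ordering(self):
        ds = noise_dataset(n_metabolites=7, seed=10)
        config = AnalysisConfig(n_pcs=2, n_permutations=100, seed=0)
        stats = compute_pair_statistics(ds, config)
        assert len(stats) == 21
        for s in stats:
            assert s.metabolite_1 < s.metabolite_2
            assert 0 < s.p_pearson <= 1
            assert s.q_pearson >= s.p_pearson

    def test_independent_transcripts_leave_partial_close_to_pearson(self):
        ds = noise_dataset(n_metabolites=10, n_samples=60, seed=11)
        config = AnalysisConfig(n_pcs=3, n_permutations=100, seed=0)
        stats = compute_pair_statistics(ds, config)
        diffs = [abs(s.r_pearson - s.r_partial) for s in stats]
        assert np.mean(diffs) < 0.1
        assert np.mean([s.p_diff for s in stats]) > 0.2

    def test_factor_driven_pair_loses_correlation_after_partialling(self):
        spec = SyntheticSpec(
            n_metabolites=10, n_tpc_pairs=2, n_ppc_pairs=0, seed=12,
            n_transcripts=200, n_samples=60,
        )
        ds, truth = generate_dataset(spec)
        config = AnalysisConfig(n_pcs=3, n_permutations=100, seed=0)
        stats = compute_pair_statistics(ds, config)
        planted = {tuple(sorted(p)) for p in truth.labels}
        for s in stats:
            if (s.metabolite_1, s.metabolite_2) in planted:
                assert abs(s.r_partial) < abs(s.r_pearson) / 2
                assert abs(s.r_pearson) > 0.5


def _pair(q_pearson, q_partial, q_diff):
    return PairStatistics(
        metabolite_1="mA", metabolite_2="mB",
        r_pearson=0.5, r_partial=0.1,
        p_pearson=q_pearson, p_partial=q_partial, p_diff=q_diff,
        q_pearson=q_pearson, q_partial=q_partial, q_diff=q_diff,
    )


class TestClassifyPairs:
    alpha = 0.01

    @pytest.mark.parametrize(
        "qs, expected",
        [
            ((0.001, 0.5, 0.001), "TPC"),    # sig Pearson, non-sig partial, sig diff
            ((0.5, 0.001, 0.001), "PPC"),    # sig partial + sig diff
            ((0.001, 0.001, 0.001), "PPC"),  # all significant -> partial survives
            ((0.001, 0.001, 0.5), "none"),   # no significant difference
            ((0.001, 0.5, 0.5), "none"),     # Pearson alone is not enough
            ((0.5, 0.5, 0.001), "none"),     # difference alone is not enough
        ],
    )
    def test_rule_table(self, qs, expected):
        config = AnalysisConfig(alpha=self.alpha, n_permutations=100)
        [out] = classify_pairs([_pair(*qs)], config)
        assert out.category == expected

    def test_ppc_require_pearson_option(self):
        config = AnalysisConfig(
            alpha=self.alpha, n_permutations=100, ppc_require_pearson=True
        )
        [out] = classify_pairs([_pair(0.5, 0.001, 0.001)], config)
        assert out.category == "none"
        [out] = classify_pairs([_pair(0.001, 0.001, 0.001)], config)
        assert out.category == "PPC"

    def test_tpc_and_ppc_rules_are_mutually_exclusive(self):
        # exhaustive over significance flags: no flag combination satisfies both
        config = AnalysisConfig(alpha=self.alpha, n_permutations=100)
        for qp in (0.001, 0.5):
            for qq in (0.001, 0.5):
                for qd in (0.001, 0.5):
                    [out] = classify_pairs([_pair(qp, qq, qd)], config)
                    tpc = qp <= self.alpha and qq > self.alpha and qd <= self.alpha
                    ppc = qq <= self.alpha and qd <= self.alpha
                    assert not (tpc and ppc)
                    assert out.category == ("TPC" if tpc else "PPC" if ppc else "none")


class TestSummaries:
    def _classified(self):
        base = dict(p_pearson=0.001, p_partial=0.001, p_diff=0.001,
                    q_pearson=0.001, q_partial=0.001, q_diff=0.001)
        return [
            PairStatistics("mA", "mB", 0.30, 0.25, **base, category="TPC"),
            PairStatistics("mC", "mD", -0.42, -0.39, **base, category="TPC"),
            PairStatistics("mE", "mF", 0.50, 0.60, **base, category="PPC"),
            PairStatistics("mG", "mH", 0.50, 0.50, **base, category="PPC"),
            PairStatistics("mI", "mJ", 0.95, 0.85, **base, category="none"),
        ]

    def test_direction_changes_fractions(self):
        table = summarize_direction_changes(self._classified())
        tpc_pos = table[(table.category == "TPC") & (table.sign == "+")].iloc[0]
        assert tpc_pos.frac_decreased == 1.0 and tpc_pos.frac_increased == 0.0
        tpc_neg = table[(table.category == "TPC") & (table.sign == "-")].iloc[0]
        assert tpc_neg.frac_decreased == 1.0  # |-0.39| < |-0.42|
        ppc_pos = table[(table.category == "PPC") & (table.sign == "+")].iloc[0]
        assert ppc_pos.frac_increased == 0.5 and ppc_pos.frac_tied == 0.5
        ppc_neg = table[(table.category == "PPC") & (table.sign == "-")].iloc[0]
        assert ppc_neg.n_pairs == 0 and np.isnan(ppc_neg.frac_increased)

    def test_threshold_counts_and_nesting(self):
        base = dict(p_pearson=0.001, p_partial=0.001, p_diff=0.001,
                    q_pearson=0.001, q_partial=0.001, q_diff=0.001)
        stats = [
            PairStatistics("mA", "mB", 0.9, 0.95, **base, category="PPC"),
            PairStatistics("mC", "mD", 0.8, 0.85, **base, category="PPC"),
            PairStatistics("mE", "mF", 0.5, 0.45, **base, category="PPC"),
            PairStatistics("mG", "mH", -0.6, -0.55, **base, category="TPC"),
        ]
        table = count_thresholds(stats, [0.9, 0.4, -0.5])
        assert table.loc[table.threshold == 0.9, "PPC"].item() == 1
        assert table.loc[table.threshold == 0.4, "PPC"].item() == 3
        assert table.loc[table.threshold == -0.5, "TPC"].item() == 1
        # counts nest: stricter positive thresholds can only lose pairs
        pos = table[table.threshold > 0].sort_values("threshold")
        assert (pos["PPC"].diff().dropna() <= 0).all()


class TestNullCalibration:
    def test_pvalues_super_uniform_under_null(self):
        # all-independent data: empirical p-values must not be anti-conservative
        ds = noise_dataset(n_transcripts=60, n_metabolites=12, n_samples=50, seed=13)
        config = AnalysisConfig(n_pcs=3, n_permutations=150, seed=5)
        stats = compute_pair_statistics(ds, config)
        for family in ("p_pearson", "p_partial"):
            p = np.sort([getattr(s, family) for s in stats])
            ecdf = np.arange(1, len(p) + 1) / len(p)
            # one-sided KS-style bound, generous for 66 dependent pairs
            assert np.max(ecdf - p) < 0.25

    def test_end_to_end_determinism_of_pair_table(self, tmp_path):
        from tppc import write_pair_table

        spec = SyntheticSpec(n_metabolites=8, n_tpc_pairs=1, n_ppc_pairs=1,
                             n_transcripts=60, n_samples=40, seed=21)
        ds, _ = generate_dataset(spec)
        config = AnalysisConfig(n_pcs=2, n_permutations=120, seed=9)
        for name in ("a.tsv", "b.tsv"):
            write_pair_table(classify_dataset(ds, config), tmp_path / name)
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()
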