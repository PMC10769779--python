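"""Response labelling and exact Wilcoxon tests against enumeration oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from helpers_oracles import rank_sum_p_enumeration, signed_rank_p_enumeration

from commfba.cohort import (
    label_response,
    run_cohort_tests,
    wilcoxon_rank_sum_exact,
    wilcoxon_signed_rank_exact,
)
from commfba.io import SampleMetadata
from commfba.pfba import SampleResult


class TestLabelResponse:
    @pytest.mark.parametrize(
        "v1,v2,expected",
        [
            (10, 5, "responder"),  # exactly 50% is inclusive
            (10, 6, "nonresponder"),
            (12, 3, "responder"),
            (4, 2, "responder"),
            (21, 11, "nonresponder"),
        ],
    )
    def test_examples(self, v1, v2, expected):
        assert label_response(v1, v2) == expected

    def test_inactive_baseline_not_eligible(self):
        with pytest.raises(ValueError, match="eligible"):
            label_response(3, 1)

    @pytest.mark.parametrize("v1,v2", [(25, 5), (10, -1), (10, 22)])
    def test_out_of_range_scores_rejected(self, v1, v2):
        with pytest.raises(ValueError, match="outside"):
            label_response(v1, v2)


class TestRankSumExact:
    def test_fully_separated_groups(self):
        res = wilcoxon_rank_sum_exact([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1)
        assert res.method == "exact"

    def test_two_vs_two(self):
        res = wilcoxon_rank_sum_exact([1, 2], [3, 4])
        assert res.p_value == pytest.approx(1 / 3)

    def test_single_tied_pair(self):
        res = wilcoxon_rank_sum_exact([5], [5])
        assert res.p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_rank_sum_exact([], [1.0])

    def test_swap_symmetry(self):
        x, y = [1.5, 2.0, 9.0], [2.0, 3.0, 4.0, 8.0]
        assert wilcoxon_rank_sum_exact(x, y).p_value == pytest.approx(
            wilcoxon_rank_sum_exact(y, x).p_value
        )

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_enumeration_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n_x, n_y = rng.integers(1, 6, size=2)
        x = rng.integers(0, 5, size=n_x).tolist()  # small ints force ties
        y = rng.integers(0, 5, size=n_y).tolist()
        for alternative in ("two_sided", "less", "greater"):
            ours = wilcoxon_rank_sum_exact(x, y, alternative=alternative)
            assert ours.p_value == pytest.approx(
                rank_sum_p_enumeration(x, y, alternative), abs=1e-12
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(size=4).tolist()
        y = rng.normal(size=5).tolist()
        ours = wilcoxon_rank_sum_exact(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)
        assert ours.statistic == pytest.approx(ref.statistic)

    def test_large_samples_fall_back_to_approximation(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20).tolist(), rng.normal(size=20).tolist()
        res = wilcoxon_rank_sum_exact(x, y)
        assert res.method == "approx"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=6)
        y = rng.normal(size=6).tolist()
        ps = [
            wilcoxon_rank_sum_exact((base + shift).tolist(), y).p_value
            for shift in (0.0, 1.0, 2.0, 4.0)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(ps, ps[1:]))


class TestSignedRankExact:
    def test_all_positive_differences(self):
        res = wilcoxon_signed_rank_exact([(0, 1), (0, 2), (0, 3)])
        assert res.p_value == pytest.approx(0.25)
        assert res.statistic == pytest.approx(6.0)

    def test_tied_opposite_differences(self):
        res = wilcoxon_signed_rank_exact([(0, 1), (0, -1)])
        assert res.p_value == 1.0

    def test_zeros_dropped_to_single_pair(self):
        res = wilcoxon_signed_rank_exact([(1, 1), (2, 2), (0, 2)])
        assert res.n == 1
        assert res.p_value == 1.0

    def test_all_zero_differences_degenerate(self):
        res = wilcoxon_signed_rank_exact([(1, 1), (2, 2)])
        assert res.p_value == 1.0
        assert res.method == "degenerate"

    def test_negation_symmetry(self):
        pairs = [(0, d) for d in (1.5, -2.0, 3.0, 0.5)]
        negated = [(0, -d) for _, d in pairs]
        assert wilcoxon_signed_rank_exact(pairs).p_value == pytest.approx(
            wilcoxon_signed_rank_exact(negated).p_value
        )

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_enumeration_oracle_with_ties_and_zeros(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(1, 9))
        diffs = rng.integers(-3, 4, size=m).tolist()  # ties and zeros likely
        if all(d == 0 for d in diffs):
            diffs[0] = 1
        pairs = [(0.0, float(d)) for d in diffs]
        for alternative in ("two_sided", "less", "greater"):
            ours = wilcoxon_signed_rank_exact(pairs, alternative=alternative)
            assert ours.p_value == pytest.approx(
                signed_rank_p_enumeration(diffs, alternative), abs=1e-12
            )

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_exact_without_ties(self, seed):
        rng = np.random.default_rng(50 + seed)
        diffs = rng.normal(size=7)
        ours = wilcoxon_signed_rank_exact([(0.0, d) for d in diffs])
        ref = sps.wilcoxon(diffs, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_samples_fall_back_to_approximation(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(size=30)
        res = wilcoxon_signed_rank_exact([(0.0, d) for d in diffs])
        assert res.method == "approx"
        ref = sps.wilcoxon(diffs, correction=True, method="approx")
        assert res.p_value == pytest.approx(ref.pvalue)


def _cohort_inputs(rates_by_patient: dict[str, tuple], lichtiger: dict[str, tuple]):
    """Build SampleResult + SampleMetadata lists from per-patient (V1, V2) tuples."""
    results, metadata = [], []
    for pid, (r1, r2) in rates_by_patient.items():
        l1, l2 = lichtiger[pid]
        for visit, rate, score in (("V1", r1, l1), ("V2", r2, l2)):
            if rate == "missing":
                continue
            sid = f"{pid}-{visit}"
            metadata.append(SampleMetadata(sid, pid, visit, score))
            results.append(
                SampleResult(sid, rate, 10.0, 5, 0.0, "optimal" if rate is not None else "empty_community")
            )
    return results, metadata


class TestRunCohortTests:
    def test_four_tests_on_planted_effect(self):
        rng = np.random.default_rng(3)
        rates, scores = {}, {}
        for i in range(8):  # responders gain 0.3 at V2
            v1 = float(rng.uniform(0.2, 0.4))
            rates[f"R{i}"] = (v1, v1 + 0.3)
            scores[f"R{i}"] = (10, 5)
        for i in range(6):
            v1 = float(rng.uniform(0.2, 0.4))
            rates[f"N{i}"] = (v1, v1 + float(rng.normal(0, 0.02)))
            scores[f"N{i}"] = (10, 8)
        res = run_cohort_tests(*_cohort_inputs(rates, scores))
        assert set(res.tests) == {"rs_V1", "rs_V2", "sr_responders", "sr_nonresponders"}
        assert res.tests["sr_responders"].p_value == pytest.approx(2 / 2**8)
        assert res.tests["sr_responders"].p_value < 0.05
        assert res.tests["rs_V2"].p_value < 0.05
        assert res.tests["rs_V1"].p_value > 0.05

    def test_single_nonresponder_pair(self):
        rates = {"R1": (0.2, 0.5), "R2": (0.3, 0.6), "N1": (0.25, 0.3)}
        scores = {"R1": (10, 5), "R2": (12, 4), "N1": (10, 9)}
        res = run_cohort_tests(*_cohort_inputs(rates, scores))
        assert res.tests["sr_nonresponders"].p_value == 1.0

    def test_missing_group_not_computable(self):
        rates = {"R1": (0.2, 0.5), "R2": (0.3, 0.6)}
        scores = {"R1": (10, 5), "R2": (12, 4)}
        res = run_cohort_tests(*_cohort_inputs(rates, scores))
        assert res.tests["rs_V1"].method == "not_computable"

    def test_undefined_rates_and_missing_visits_counted(self):
        rates = {"R1": (0.2, 0.5), "R2": (None, 0.6), "N1": (0.25, "missing"), "N2": (0.2, 0.4)}
        scores = {"R1": (10, 5), "R2": (12, 4), "N1": (10, 9), "N2": (10, 8)}
        res = run_cohort_tests(*_cohort_inputs(rates, scores))
        assert res.n_excluded_samples == 2  # one undefined rate + one unlabelled V1
        assert res.n_unlabelled_patients == 1
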