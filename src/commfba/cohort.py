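"""Response labelling and the exact nonparametric group comparisons.

Patients are labelled responders when their Lichtiger activity score drops by
at least 50% between baseline (V1) and week 4 (V2); eligibility requires
active disease at baseline (score >= 4).  Predicted butyrate production rates
are then compared with four tests: Wilcoxon rank sum between responders and
nonresponders at each visit, and paired Wilcoxon signed rank between visits
within each group.

Both tests are permutation-exact on the observed data: mid-ranks are assigned
to ties, the null distribution of the rank statistic is enumerated (all
C(n, n_x) group assignments for the rank sum; all 2^m sign patterns on the m
nonzero differences for the signed rank, zeros dropped beforehand), and the
two-sided p-value doubles the smaller one-sided tail, capped at 1.  Beyond an
enumeration cap the classical normal approximation (with continuity
correction) takes over, with a logged notice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import SampleMetadata
from .pfba import SampleResult

logger = logging.getLogger(__name__)

RESPONDER = "responder"
NONRESPONDER = "nonresponder"

RANK_SUM_EXACT_CAP = 25  # max combined n for exact enumeration
SIGNED_RANK_EXACT_CAP = 20  # max nonzero differences for exact enumeration

TEST_NAMES = ("rs_V1", "rs_V2", "sr_responders", "sr_nonresponders")
ALTERNATIVES = ("two_sided", "less", "greater")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str  # "exact" | "approx" | "degenerate" | "not_computable"


@dataclass
class CohortResult:
    per_sample: pd.DataFrame
    tests: dict[str, TestResult]
    n_excluded_samples: int
    n_unlabelled_patients: int


def label_response(lichtiger_v1: int, lichtiger_v2: int) -> str:
    """Responder iff the score decreased by >= 50% from V1 to V2 (inclusive)."""
    for name, score in (("V1", lichtiger_v1), ("V2", lichtiger_v2)):
        if not 0 <= score <= 21:
            raise ValueError(f"Lichtiger {name} score {score} outside 0..21")
    if lichtiger_v1 < 4:
        raise ValueError(
            f"patient not eligible: baseline Lichtiger {lichtiger_v1} < 4"
        )
    return RESPONDER if (lichtiger_v1 - lichtiger_v2) / lichtiger_v1 >= 0.5 else NONRESPONDER


def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Mid-ranks doubled to exact integers (ties give half-integer ranks)."""
    doubled = np.rint(2 * sps.rankdata(values)).astype(np.int64)
    return doubled


def _tail_counts_fixed_size(ranks2: np.ndarray, k: int) -> np.ndarray:
    """count[s] = #subsets of size k of ranks2 with doubled-rank sum s."""
    total = int(ranks2.sum())
    dp = np.zeros((k + 1, total + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in ranks2:
        for j in range(k - 1, -1, -1):  # descending so each item is used once
            dp[j + 1, r:] += dp[j, : total + 1 - r]
    return dp[k]


def _tail_counts_any_size(ranks2: np.ndarray) -> np.ndarray:
    """count[s] = #subsets (any size) of ranks2 with doubled-rank sum s."""
    total = int(ranks2.sum())
    dp = np.zeros(total + 1, dtype=np.float64)
    dp[0] = 1.0
    for r in ranks2:
        dp[r:] += dp[: total + 1 - r].copy()
    return dp


def _two_sided(p_low: float, p_high: float, alternative: str) -> float:
    if alternative == "two_sided":
        return min(1.0, 2.0 * min(p_low, p_high))
    if alternative == "less":
        return p_low
    if alternative == "greater":
        return p_high
    raise ValueError(f"alternative must be one of {ALTERNATIVES}")


def wilcoxon_rank_sum_exact(
    x: list[float],
    y: list[float],
    alternative: str = "two_sided",
    exact_cap: int = RANK_SUM_EXACT_CAP,
) -> TestResult:
    """Exact (permutation) Wilcoxon rank sum / Mann-Whitney test.

    Returns the Mann-Whitney U statistic of ``x`` and the p-value obtained by
    enumerating all C(n_x+n_y, n_x) assignments of the pooled mid-ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    n_x, n_y = x.size, y.size
    n = n_x + n_y
    pooled = np.concatenate([x, y])
    ranks2 = _doubled_midranks(pooled)
    w2 = int(ranks2[:n_x].sum())  # doubled rank sum of x
    u_stat = w2 / 2.0 - n_x * (n_x + 1) / 2.0
    if n > exact_cap:
        logger.info(
            "rank sum: combined n=%d exceeds exact cap %d; normal approximation",
            n,
            exact_cap,
        )
        alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}
        res = sps.mannwhitneyu(x, y, alternative=alt[alternative], method="asymptotic")
        return TestResult(float(res.statistic), float(res.pvalue), n, "approx")
    counts = _tail_counts_fixed_size(ranks2, n_x)
    total = math.comb(n, n_x)
    p_low = counts[: w2 + 1].sum() / total
    p_high = counts[w2:].sum() / total
    return TestResult(u_stat, _two_sided(p_low, p_high, alternative), n, "exact")


def wilcoxon_signed_rank_exact(
    pairs: list[tuple[float, float]],
    alternative: str = "two_sided",
    exact_cap: int = SIGNED_RANK_EXACT_CAP,
) -> TestResult:
    """Exact (sign-flip) paired Wilcoxon signed rank test on (v1, v2) pairs.

    Differences are v2 - v1; zero differences are dropped (classical
    convention) and |differences| receive mid-ranks.  The statistic is W+,
    the rank sum of positive differences; the exact p enumerates all 2^m
    sign assignments.
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    diffs = np.asarray([v2 - v1 for v1, v2 in pairs], dtype=float)
    if diffs.size == 0:
        raise ValueError("no pairs supplied")
    nonzero = diffs[diffs != 0]
    n_dropped = diffs.size - nonzero.size
    if n_dropped:
        logger.info("signed rank: dropped %d zero differences", n_dropped)
    m = nonzero.size
    if m == 0:
        logger.info("signed rank: all differences zero; p = 1")
        return TestResult(0.0, 1.0, 0, "degenerate")
    ranks2 = _doubled_midranks(np.abs(nonzero))
    w2 = int(ranks2[nonzero > 0].sum())
    w_plus = w2 / 2.0
    if m > exact_cap:
        logger.info(
            "signed rank: m=%d exceeds exact cap %d; normal approximation",
            m,
            exact_cap,
        )
        res = sps.wilcoxon(
            nonzero,
            correction=True,
            alternative={"two_sided": "two-sided", "less": "less", "greater": "greater"}[
                alternative
            ],
            method="approx",
        )
        return TestResult(float(res.statistic), float(res.pvalue), m, "approx")
    counts = _tail_counts_any_size(ranks2)
    total = 2.0**m
    p_low = counts[: w2 + 1].sum() / total
    p_high = counts[w2:].sum() / total
    return TestResult(w_plus, _two_sided(p_low, p_high, alternative), m, "exact")


def run_cohort_tests(
    results: list[SampleResult],
    metadata: list[SampleMetadata],
    rank_sum_cap: int = RANK_SUM_EXACT_CAP,
    signed_rank_cap: int = SIGNED_RANK_EXACT_CAP,
) -> CohortResult:
    """Assemble the four group/timepoint comparisons of the analysis.

    Samples with undefined rates are excluded and counted; patients whose
    response label cannot be derived (a visit's score missing) are excluded
    and counted.
    """
    meta_by_sample = {m.sample_id: m for m in metadata}
    lichtiger: dict[str, dict[str, int]] = {}
    for m in metadata:
        lichtiger.setdefault(m.patient_id, {})[m.visit] = m.lichtiger
    labels: dict[str, str] = {}
    unlabelled = 0
    for patient, scores in lichtiger.items():
        if "V1" in scores and "V2" in scores:
            labels[patient] = label_response(scores["V1"], scores["V2"])
        else:
            unlabelled += 1

    rows = []
    excluded = 0
    rates: dict[str, float] = {}
    for r in results:
        meta = meta_by_sample.get(r.sample_id)
        if meta is None:
            raise KeyError(f"sample {r.sample_id!r} missing from metadata")
        group = labels.get(meta.patient_id)
        if r.butyrate_rate is None or group is None:
            excluded += 1
            continue
        rates[r.sample_id] = r.butyrate_rate
        rows.append(
            (r.sample_id, meta.patient_id, meta.visit, group, r.butyrate_rate)
        )
    per_sample = pd.DataFrame(
        rows,
        columns=["sample_id", "patient_id", "visit", "response_group", "butyrate_rate"],
    )

    def visit_rates(group: str, visit: str) -> list[float]:
        sel = per_sample[
            (per_sample["response_group"] == group) & (per_sample["visit"] == visit)
        ]
        return list(sel["butyrate_rate"])

    def paired(group: str) -> list[tuple[float, float]]:
        sel = per_sample[per_sample["response_group"] == group]
        wide = sel.pivot(index="patient_id", columns="visit", values="butyrate_rate")
        if "V1" not in wide or "V2" not in wide:
            return []
        both = wide.dropna(subset=["V1", "V2"])
        return list(zip(both["V1"], both["V2"]))

    tests: dict[str, TestResult] = {}
    for name, visit in (("rs_V1", "V1"), ("rs_V2", "V2")):
        x = visit_rates(RESPONDER, visit)
        y = visit_rates(NONRESPONDER, visit)
        if not x or not y:
            tests[name] = TestResult(
                float("nan"), float("nan"), len(x) + len(y), "not_computable"
            )
        else:
            tests[name] = wilcoxon_rank_sum_exact(x, y, exact_cap=rank_sum_cap)
    for name, group in (
        ("sr_responders", RESPONDER),
        ("sr_nonresponders", NONRESPONDER),
    ):
        pairs = paired(group)
        if not pairs:
            tests[name] = TestResult(float("nan"), float("nan"), 0, "not_computable")
        else:
            tests[name] = wilcoxon_signed_rank_exact(pairs, exact_cap=signed_rank_cap)

    return CohortResult(per_sample, tests, excluded, unlabelled)


def tests_table(result: CohortResult) -> pd.DataFrame:
    rows = [
        (name, t.statistic, t.p_value, t.n, t.method)
        for name, t in result.tests.items()
    ]
    return pd.DataFrame(
        rows, columns=["test_name", "statistic", "p_value", "n", "method"]
    )
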