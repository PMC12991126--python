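"""Significance-testing layer: paired t, Welch t, one-way ANOVA with
Tukey-Kramer post hoc comparisons, and neuron-responsiveness
classification at alpha = 0.05.

All tests are two-sided; response *direction* (above/below baseline) is
reported separately from the p-value.  No correction is applied across
neurons; Tukey-Kramer operates only within each ANOVA family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateStatError

__all__ = [
    "TestResult",
    "PairwiseResult",
    "paired_t",
    "welch_t",
    "anova_tukey",
    "classify_responsive",
    "ResponsivenessRow",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p: float
    test_name: str
    n: tuple[int, ...]

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass(frozen=True)
class PairwiseResult:
    """One Tukey-Kramer pairwise comparison."""

    group_a: int
    group_b: int
    mean_diff: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def paired_t(a, b) -> TestResult:
    """Classical paired-sample t-test on matched per-trial values."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired_t needs two equal-length 1D arrays")
    if a.size < 2:
        raise ValueError("paired_t needs >= 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0.0:
        raise DegenerateStatError("zero-variance differences: paired t undefined")
    res = sps.ttest_rel(a, b)
    return TestResult(
        statistic=float(res.statistic),
        df=float(a.size - 1),
        p=float(res.pvalue),
        test_name="paired_t",
        n=(a.size,),
    )


def welch_t(a, b) -> TestResult:
    """Two-sample t-test with Welch's correction (Satterthwaite df)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs >= 2 observations per group")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            # identical groups: no evidence of a difference
            return TestResult(0.0, float(a.size + b.size - 2), 1.0, "welch_t", (a.size, b.size))
        raise DegenerateStatError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / a.size, vb / b.size
    df = (se2a + se2b) ** 2 / (se2a**2 / (a.size - 1) + se2b**2 / (b.size - 1))
    return TestResult(
        statistic=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
        test_name="welch_t",
        n=(a.size, b.size),
    )


def anova_tukey(groups: list) -> tuple[TestResult, list[PairwiseResult]]:
    """One-way ANOVA with Tukey-Kramer post hoc comparisons.

    Returns the omnibus F test and all pairwise comparisons via the
    studentized-range distribution with the Kramer unequal-n adjustment
    (scipy's ``tukey_hsd``).
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    for i, g in enumerate(gs):
        if g.size < 2:
            raise ValueError(f"group {i} has {g.size} < 2 observations")
    ns = tuple(g.size for g in gs)
    k = len(gs)
    n_tot = sum(ns)
    allv = np.concatenate(gs)
    pairs_idx = [(i, j) for i in range(k) for j in range(i + 1, k)]
    if np.var(allv) == 0.0:
        # identical constant data: no between- or within-group variability
        omni = TestResult(0.0, float(k - 1), 1.0, "anova", ns)
        pw = [PairwiseResult(i, j, 0.0, 1.0) for i, j in pairs_idx]
        return omni, pw
    f = sps.f_oneway(*gs)
    omni = TestResult(
        statistic=float(f.statistic),
        df=float(k - 1),
        p=float(f.pvalue),
        test_name="anova",
        n=ns,
    )
    hsd = sps.tukey_hsd(*gs)
    pw = [
        PairwiseResult(
            group_a=i,
            group_b=j,
            mean_diff=float(gs[i].mean() - gs[j].mean()),
            p=float(hsd.pvalue[i, j]),
        )
        for i, j in pairs_idx
    ]
    return omni, pw


@dataclass(frozen=True)
class ResponsivenessRow:
    """One neuron x epoch entry of the responsiveness table."""

    neuron_id: str
    epoch: str
    result: TestResult | None
    direction: str  # "above" | "below" | "none"
    testable: bool

    @property
    def significant(self) -> bool:
        return self.testable and self.result is not None and self.result.p < ALPHA


def classify_responsive(
    epoch_rates, baseline_rates, neuron_id: str = "", epoch: str = ""
) -> ResponsivenessRow:
    """Is an epoch response significantly different from baseline?

    Paired t-test on matched per-trial rates; direction is the sign of the
    mean difference.  Degenerate inputs yield an untestable row so the
    pipeline can continue.
    """
    er = np.asarray(epoch_rates, dtype=float)
    br = np.asarray(baseline_rates, dtype=float)
    try:
        res = paired_t(er, br)
    except (DegenerateStatError, ValueError):
        return ResponsivenessRow(neuron_id, epoch, None, "none", False)
    diff = float(er.mean() - br.mean())
    direction = "above" if diff > 0 else ("below" if diff < 0 else "none")
    return ResponsivenessRow(neuron_id, epoch, res, direction, True)
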