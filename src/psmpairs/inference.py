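"""Risk-difference estimation and paired vs independent-samples inference.

All inference is driven by the 2x2 classification of matched pairs by the
outcomes of their two members: ``a`` pairs where both have the event, ``b``
where only the treated member does, ``c`` where only the control member
does, ``d`` where neither does.  The point estimate is the same either way,

    rd = p_T - p_C = (b - c) / n,

but the two traditions disagree on its sampling variance:

* independent samples: ``var = (p_T (1 - p_T) + p_C (1 - p_C)) / N`` with
  ``N`` the number of pairs per group, tested by Pearson's chi-squared on
  the treatment-by-outcome table of the 2N matched subjects;
* paired samples: ``var = ((b + c) - (c - b)^2 / n) / n^2``, tested by
  McNemar's chi-squared on the discordant counts.

Both tests default to no continuity correction.  Wald 95% confidence
intervals are ``rd +/- 1.96 se`` and are not clipped to [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .matching import MatchedSample


@dataclass(frozen=True)
class PairedTable:
    """Concordant/discordant pair counts of a 1:1 matched sample."""

    a: int  # both members have the event
    b: int  # treated-only event
    c: int  # control-only event
    d: int  # neither member has the event

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("pair counts must be non-negative")
        if self.n < 1:
            raise ValueError("need at least one pair")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def p_treated(self) -> float:
        """Event proportion among treated pair members."""
        return (self.a + self.b) / self.n

    @property
    def p_control(self) -> float:
        """Event proportion among control pair members."""
        return (self.a + self.c) / self.n


@dataclass(frozen=True)
class RDInference:
    """Risk difference with both variance treatments side by side."""

    rd: float
    p_treated: float
    p_control: float
    n_pairs: int
    se_independent: float
    se_paired: float
    ci_independent: tuple[float, float]
    ci_paired: tuple[float, float]
    p_pearson: float
    p_mcnemar: float


def paired_table(matched: MatchedSample, Y: np.ndarray) -> PairedTable:
    """Cross-classify matched pairs by the outcomes of their members."""
    if matched.n_pairs == 0:
        raise ValueError("empty matched sample: no pairs to classify")
    Y = np.asarray(Y)
    yt = Y[matched.pairs[:, 0]].astype(bool)
    yc = Y[matched.pairs[:, 1]].astype(bool)
    a = int(np.sum(yt & yc))
    b = int(np.sum(yt & ~yc))
    c = int(np.sum(~yt & yc))
    d = int(np.sum(~yt & ~yc))
    return PairedTable(a=a, b=b, c=c, d=d)


def risk_difference(t: PairedTable) -> float:
    """``p_T - p_C = (b - c) / n``; identical under both traditions."""
    return (t.b - t.c) / t.n


def var_independent(t: PairedTable) -> float:
    """Two-independent-proportions variance, both group sizes = pair count."""
    pt, pc = t.p_treated, t.p_control
    return (pt * (1.0 - pt) + pc * (1.0 - pc)) / t.n


def var_paired(t: PairedTable) -> float:
    """Matched-pairs variance of the difference in proportions."""
    return ((t.b + t.c) - (t.c - t.b) ** 2 / t.n) / t.n**2


def mcnemar_test(
    t: PairedTable, correction: bool = False
) -> tuple[float, float]:
    """McNemar's chi-squared test on the discordant pair counts.

    Statistic ``(b - c)^2 / (b + c)`` (``(|b - c| - 1)^2 / (b + c)`` with
    the optional continuity correction), referred to chi-squared with one
    degree of freedom.  With no discordant pairs the statistic is 0 and
    p = 1.
    """
    disc = t.b + t.c
    if disc == 0:
        return 0.0, 1.0
    num = (abs(t.b - t.c) - 1.0) ** 2 if correction else (t.b - t.c) ** 2
    stat = num / disc
    return float(stat), float(chi2.sf(stat, 1))


def pearson_test(
    t: PairedTable, correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared test treating the 2n matched subjects as two
    independent samples.

    The treatment-by-outcome table has treated row ``(a+b, c+d)`` and
    control row ``(a+c, b+d)``.  A zero margin yields statistic 0 and
    p = 1.  The optional Yates correction subtracts 1/2 from each
    |O - E| before squaring.
    """
    e_t, e_c = t.a + t.b, t.a + t.c  # events by group
    ne_t, ne_c = t.c + t.d, t.b + t.d
    n2 = 2 * t.n
    r1, r2 = t.n, t.n
    c1, c2 = e_t + e_c, ne_t + ne_c
    if c1 == 0 or c2 == 0:
        return 0.0, 1.0
    det = abs(e_t * ne_c - e_c * ne_t)
    if correction:
        det = max(det - n2 / 2.0, 0.0)
    stat = n2 * det**2 / (r1 * r2 * c1 * c2)
    return float(stat), float(chi2.sf(stat, 1))


def wald_ci(
    rd: float, se: float, level_z: float = 1.96
) -> tuple[float, float]:
    """Symmetric Wald interval ``rd +/- z * se``, not clipped to [-1, 1]."""
    if se < 0:
        raise ValueError("standard error must be non-negative")
    return (rd - level_z * se, rd + level_z * se)


def infer_risk_difference(t: PairedTable) -> RDInference:
    """Full inference record for one matched sample: point estimate, both
    standard errors, both 95% Wald intervals, both test p-values."""
    rd = risk_difference(t)
    se_ind = math.sqrt(var_independent(t))
    se_pair = math.sqrt(var_paired(t))
    return RDInference(
        rd=rd,
        p_treated=t.p_treated,
        p_control=t.p_control,
        n_pairs=t.n,
        se_independent=se_ind,
        se_paired=se_pair,
        ci_independent=wald_ci(rd, se_ind),
        ci_paired=wald_ci(rd, se_pair),
        p_pearson=pearson_test(t)[1],
        p_mcnemar=mcnemar_test(t)[1],
    )
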