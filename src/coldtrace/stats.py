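"""The study's comparison battery.

Responder proportions (%CT) between genotypes are compared with Fisher's
exact test on 2x2 tables, corrected across comparisons with the
Benjamini-Hochberg (BH) step-up FDR procedure.  Rank-based metric
comparisons (Kruskal-Wallis, Mann-Whitney) use the two-stage sharpened FDR
procedure of Benjamini, Krieger and Yekutieli (BKY), and parametric
comparisons (one-way ANOVA) use Holm-Sidak.  The multiple-comparison
adjustments and the exact test are implemented here from their definitions;
the omnibus tests themselves are thin wrappers over scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParameterError

# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass
class ResponderTable:
    """2x2 counts: rows = responders/non-responders, cols = conditions."""

    table: np.ndarray
    labels: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        t = np.asarray(self.table)
        if t.shape != (2, 2):
            raise ParameterError("table must be 2x2")
        if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) \
                and not np.allclose(t, np.round(t)):
            raise ParameterError("counts must be non-negative integers")
        t = np.round(t).astype(np.int64)
        if np.any(t < 0):
            raise ParameterError("counts must be non-negative")
        if t.sum() == 0:
            raise ParameterError("at least one positive margin required")
        self.table = t

    @classmethod
    def from_summaries(cls, a, b) -> "ResponderTable":
        """Build from two :class:`~coldtrace.behavior.BehaviorSummary` objects."""
        t = np.array([[a.n_responders, b.n_responders],
                      [a.n_analyzed - a.n_responders,
                       b.n_analyzed - b.n_responders]])
        return cls(table=t, labels=(a.label, b.label))


@dataclass
class AdjustedPValues:
    """Raw and multiplicity-adjusted p-values with rejection flags."""

    raw: np.ndarray
    adjusted: np.ndarray
    procedure: str
    alpha: float
    reject: np.ndarray

    def __post_init__(self) -> None:
        if self.adjusted.shape != self.raw.shape:
            raise ParameterError("adjusted and raw lengths differ")


def _check_pvals(pvals) -> np.ndarray:
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ParameterError("need a non-empty 1-D p-value array")
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    return p


# --------------------------------------------------------------------------
# Fisher's exact test
# --------------------------------------------------------------------------


def fisher_exact_2x2(table, alternative: str = "two-sided") -> float:
    """Fisher's exact test on a 2x2 table, by hypergeometric enumeration.

    With margins fixed, the count in cell (0, 0) follows a hypergeometric
    distribution.  The two-sided p-value sums the probabilities of all
    tables no more probable than the observed one (with a 1 + 1e-7 relative
    guard against floating-point ties, the convention of common
    implementations); 'less'/'greater' use the hypergeometric CDF/SF of the
    observed cell.
    """
    if isinstance(table, ResponderTable):
        table = table.table
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ParameterError("need a 2x2 table of non-negative counts")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ParameterError("empty table")
    row1, col1 = a + b, a + c
    dist = sps.hypergeom(n, row1, col1)
    if alternative == "less":
        return float(min(1.0, dist.cdf(a)))
    if alternative == "greater":
        return float(min(1.0, dist.sf(a - 1)))
    if alternative != "two-sided":
        raise ParameterError(f"unknown alternative {alternative!r}")
    support = np.arange(max(0, col1 - (n - row1)), min(col1, row1) + 1)
    probs = dist.pmf(support)
    p_obs = dist.pmf(a)
    p = float(probs[probs <= p_obs * (1 + 1e-7)].sum())
    return min(1.0, p)


# --------------------------------------------------------------------------
# Multiple-comparison adjustments
# --------------------------------------------------------------------------


def adjust_bh(pvals, alpha: float = 0.05) -> AdjustedPValues:
    """Benjamini-Hochberg step-up FDR adjustment.

    Sorted ascending, the adjusted value of the k-th smallest p is
    ``min_{j >= k} (m * p_(j) / j)``, capped at 1; hypotheses with adjusted
    p <= alpha are rejected, which reproduces the step-up rule.
    """
    p = _check_pvals(pvals)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return AdjustedPValues(raw=p, adjusted=adjusted, procedure="bh",
                           alpha=alpha, reject=adjusted <= alpha)


def holm_sidak_adjust(pvals, alpha: float = 0.05) -> AdjustedPValues:
    """Holm-Sidak step-down adjustment.

    Ascending order; ``adj_(k) = max(adj_(k-1), 1 - (1 - p_(k))^(m - k + 1))``,
    capped at 1.
    """
    p = _check_pvals(pvals)
    m = p.size
    order = np.argsort(p, kind="stable")
    powers = m - np.arange(m)
    stepwise = 1.0 - (1.0 - p[order]) ** powers
    adj_sorted = np.minimum(1.0, np.maximum.accumulate(stepwise))
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return AdjustedPValues(raw=p, adjusted=adjusted, procedure="holm-sidak",
                           alpha=alpha, reject=adjusted <= alpha)


def adjust_bky_two_stage(pvals, alpha: float = 0.05) -> AdjustedPValues:
    """Two-stage sharpened FDR procedure of Benjamini, Krieger and Yekutieli.

    Stage 1 runs BH at the sharpened level ``alpha' = alpha / (1 + alpha)``;
    with r1 rejections the number of true nulls is estimated as
    ``m0 = m - r1``.  Stage 2 reruns BH at level ``alpha' * m / m0`` (reject
    all if m0 = 0; keep the stage-1 outcome of zero rejections if r1 = 0).
    The primary output is the rejection flags; ``adjusted`` carries the
    standard two-stage pseudo-adjusted values ``BH_adj * m0 / m``, to be
    compared against ``alpha'``.
    """
    p = _check_pvals(pvals)
    if not (0 < alpha < 1):
        raise ParameterError("alpha must lie in (0, 1)")
    m = p.size
    alpha1 = alpha / (1.0 + alpha)
    stage1 = adjust_bh(p, alpha=alpha1)
    r1 = int(stage1.reject.sum())
    m0 = m - r1
    if m0 == 0:
        adjusted = np.zeros(m)
        reject = np.ones(m, dtype=bool)
    else:
        adjusted = np.minimum(1.0, stage1.adjusted * m0 / m)
        reject = adjusted <= alpha1
    return AdjustedPValues(raw=p, adjusted=adjusted, procedure="bky-two-stage",
                           alpha=alpha, reject=reject)


# --------------------------------------------------------------------------
# Thin wrappers over standard omnibus tests
# --------------------------------------------------------------------------


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H test; returns (statistic, p)."""
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(a, b, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann-Whitney U test; returns (statistic, p)."""
    res = sps.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def one_way_anova(*groups) -> tuple[float, float]:
    """One-way ANOVA; returns (F, p)."""
    res = sps.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def paired_t(a, b) -> tuple[float, float]:
    """Paired t-test; returns (t, p)."""
    res = sps.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)
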