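"""Occupancy-pattern classification and per-group enrichment statistics.

Promoters are partitioned into the 2^k boolean combinations of a k-factor
set (default CREB, CEBPB, CJUN).  Per pattern, the fraction with a given
differential status is compared against the universe-wide ("chance") rate
with an enrichment ratio and a chi-square goodness-of-fit test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_FACTOR_SET = ("CREB", "CEBPB", "CJUN")
ALT_FACTOR_SET = ("CREB", "CEBPA", "CJUN")
NONE_LABEL = "none"


@dataclass(frozen=True)
class PercentileSummary:
    """15/50/85 percentile summary of a per-promoter log2 quantity."""

    label: str
    p15: float
    p50: float
    p85: float

    def to_dict(self) -> dict:
        return {"label": self.label, "p15": self.p15, "p50": self.p50, "p85": self.p85}


def pattern_label(bits: Sequence[bool], factors: Sequence[str]) -> str:
    """Canonical label for a boolean combination, e.g. ``CEBPB+CJUN``."""
    on = [f for f, b in zip(factors, bits) if b]
    return "+".join(on) if on else NONE_LABEL


def all_pattern_labels(factors: Sequence[str] = DEFAULT_FACTOR_SET) -> list[str]:
    """The 2^k labels ordered by combination size, then factor order."""
    labels = []
    for r in range(len(factors) + 1):
        for combo in itertools.combinations(range(len(factors)), r):
            bits = [i in combo for i in range(len(factors))]
            labels.append(pattern_label(bits, factors))
    return labels


def assign_patterns(
    bound: pd.DataFrame, factors: Sequence[str] = DEFAULT_FACTOR_SET
) -> pd.Series:
    """Map each promoter to its occupancy-pattern label.

    ``bound`` is a boolean DataFrame indexed by promoter_id with one column
    per factor.  Promoters with a missing call for any factor are dropped
    (logged).  Promoters bound by no factor get the ``none`` label.
    """
    missing = [f for f in factors if f not in bound.columns]
    if missing:
        raise KeyError(f"binding calls missing for factors: {missing}")
    sub = bound[list(factors)]
    complete = sub.dropna()
    n_dropped = len(sub) - len(complete)
    if n_dropped:
        logger.info("dropped %d promoters lacking a call for some factor", n_dropped)
    mat = complete.to_numpy(dtype=bool)
    labels = [pattern_label(row, factors) for row in mat]
    return pd.Series(labels, index=complete.index, name="pattern")


def euler_counts(
    patterns: pd.Series, factors: Sequence[str] = DEFAULT_FACTOR_SET
) -> tuple[pd.Series, pd.Series]:
    """Per-pattern counts plus single-factor marginal totals.

    The pattern counts sum to the universe size; each factor's marginal is
    the sum over patterns containing it.
    """
    labels = all_pattern_labels(factors)
    counts = patterns.value_counts().reindex(labels, fill_value=0)
    counts.name = "n"
    marginals = pd.Series(
        {f: int(counts[[lab for lab in labels if f in lab.split("+")]].sum()) for f in factors},
        name="n_bound",
    )
    return counts, marginals


def group_status_fraction(
    patterns: pd.Series, statuses: pd.Series, label: str, status: str
) -> tuple[int, int, float]:
    """(n_group, n_status, fraction) for one pattern group and one status.

    The universe is the intersection of the two indexes.  An empty group
    yields fraction NaN (flagged via logging).
    """
    common = patterns.index.intersection(statuses.index)
    pat = patterns.loc[common]
    st = statuses.loc[common]
    group = pat.index[pat == label]
    n_group = len(group)
    if n_group == 0:
        logger.warning("empty group for pattern %r", label)
        return 0, 0, float("nan")
    n_status = int((st.loc[group] == status).sum())
    return n_group, n_status, n_status / n_group


def expected_fraction(statuses: pd.Series | Sequence[str], status: str) -> float:
    """Universe-wide rate of ``status`` — the chance expectation for groups."""
    s = pd.Series(statuses)
    if len(s) == 0:
        raise ValueError("empty universe")
    return float((s == status).sum() / len(s))


def enrichment_ratio(fraction: float, expected: float) -> float:
    """Group fraction over the chance expectation; NaN when expected is 0."""
    if expected == 0:
        logger.warning("expected fraction is 0; enrichment undefined")
        return float("nan")
    return fraction / expected


def chi_square_gof(
    observed: Sequence[float], expected: Sequence[float]
) -> tuple[float, float]:
    """Chi-square goodness of fit of observed counts against expected counts.

    ``chi2 = sum((o - e)^2 / e)``; the p-value is the upper tail of the
    chi-square distribution with ``k - 1`` degrees of freedom (the classic
    spreadsheet CHITEST semantics).
    """
    o = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape or o.ndim != 1 or len(o) < 2:
        raise ValueError("observed and expected must be 1-D of equal length >= 2")
    if np.any(e <= 0):
        raise ValueError("expected counts must all be > 0; pool sparse cells first")
    if abs(o.sum() - e.sum()) > 0.5 + 1e-6 * max(1.0, e.sum()):
        raise ValueError(
            f"observed total {o.sum()} and expected total {e.sum()} differ beyond rounding"
        )
    chi2 = float(((o - e) ** 2 / e).sum())
    p = float(stats.chi2.sf(chi2, df=len(o) - 1))
    return chi2, p


def two_sample_ttest(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t statistic and two-tailed p.

    Pooled variance by default (spreadsheet TTEST type 2); Welch via
    ``equal_var=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need >= 2 values")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and np.mean(x) == np.mean(y):
        # identical constant samples: no variability at all
        if np.all(x == x[0]) and np.all(y == y[0]):
            raise ValueError("degenerate samples with zero variance")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    t, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(t):
        raise ValueError("degenerate samples with zero pooled variance")
    return t, p


def percentile_summary(
    values: Sequence[float],
    probs: Sequence[float] = (0.15, 0.50, 0.85),
    label: str = "",
) -> PercentileSummary:
    """Linear-interpolation quantiles at the given probabilities (default 15/50/85)."""
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("cannot summarise an empty value set")
    if len(probs) != 3 or not (probs[0] <= probs[1] <= probs[2]):
        raise ValueError("probs must be three non-decreasing probabilities")
    q = np.quantile(arr, probs, method="linear")
    return PercentileSummary(label=label, p15=float(q[0]), p50=float(q[1]), p85=float(q[2]))


def group_enrichment_table(
    patterns: pd.Series,
    statuses: pd.Series,
    factors: Sequence[str] = DEFAULT_FACTOR_SET,
    statuses_of_interest: Iterable[str] = ("induced", "repressed"),
) -> pd.DataFrame:
    """Per-pattern enrichment of each status against the universe rate.

    One row per (pattern, status): group size, status count, fraction,
    expected fraction (universe rate), enrichment ratio, chi2 and p from a
    2-cell goodness-of-fit against the chance expectation.
    """
    common = patterns.index.intersection(statuses.index)
    pat = patterns.loc[common]
    st = statuses.loc[common]
    rows = []
    for status in statuses_of_interest:
        exp_frac = expected_fraction(st, status)
        for label in all_pattern_labels(factors):
            n_group, n_status, frac = group_status_fraction(pat, st, label, status)
            ratio = enrichment_ratio(frac, exp_frac) if n_group else float("nan")
            chi2 = p = float("nan")
            if n_group > 0 and 0 < exp_frac < 1:
                chi2, p = chi_square_gof(
                    [n_status, n_group - n_status],
                    [n_group * exp_frac, n_group * (1 - exp_frac)],
                )
            rows.append(
                {
                    "pattern": label,
                    "status": status,
                    "n_group": n_group,
                    "n_status": n_status,
                    "fraction": frac,
                    "expected_fraction": exp_frac,
                    "enrichment_ratio": ratio,
                    "chi2": chi2,
                    "p_value": p,
                }
            )
    return pd.DataFrame(rows)


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are reported by default)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
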