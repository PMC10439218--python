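"""Household-survey validation statistics.

Per-cell model predictions are compared against reported source usage from
a household survey: every household inherits the predicted count of its
cell, and households reporting use of an access type are compared with
those not reporting it. Following common survey practice, normality of
each group is first checked with a Kolmogorov-Smirnov test (p < 0.1 in
either group routes to the Wilcoxon rank-sum test, otherwise a two-sample
t-test is used). Proportions are compared with a pooled two-proportion
z-test, and the minimum representative sample size follows the standard
finite-population chi-square guideline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

KS_GATE_P = 0.1
EXACT_MODE_MAX_N = 20  # below this group size the rank-sum test is exact


def load_households(path) -> pd.DataFrame:
    """Households CSV: household_id,cell_id,uses_<type>,... (flags 0/1)."""
    df = pd.read_csv(path)
    required = {"household_id", "cell_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"households file must contain columns {sorted(required)}")
    if not any(c.startswith("uses_") for c in df.columns):
        raise ValueError("households file has no uses_<type> columns")
    return df


@dataclass
class GroupComparison:
    access_type: str
    n_using: int
    n_not_using: int
    mean_pred_using: float
    mean_pred_not_using: float
    test_used: str  # 'wilcoxon', 't' or 'untestable'
    statistic: float
    p_value: float
    note: str = ""


def _ks_normal(x: np.ndarray) -> float:
    """KS p-value of x against a normal with the group's mean and SD."""
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return 0.0  # degenerate group can't be treated as normal
    return float(stats.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def rank_sum_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Wilcoxon rank-sum z with tie correction, two-sided p.

    Households sharing a cell share a prediction, so ties dominate; the
    normal approximation uses the tie-corrected variance.
    """
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, t_counts = np.unique(combined, return_counts=True)
    tie_term = np.sum(t_counts**3 - t_counts) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    z = (w - mu) / math.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def compare_usage_groups(
    countmap, households: pd.DataFrame, access_type: str
) -> GroupComparison:
    """Compare per-cell predictions between using and non-using households."""
    col = f"uses_{access_type}"
    if col not in households.columns:
        raise KeyError(f"households have no column {col!r}")
    y = countmap.y if hasattr(countmap, "y") else countmap
    preds = y.reindex(households["cell_id"]).to_numpy(dtype=float)
    if np.any(np.isnan(preds)):
        raise ValueError("households reference cells absent from the count map")
    using = preds[households[col].astype(bool).to_numpy()]
    not_using = preds[~households[col].astype(bool).to_numpy()]

    base = dict(
        access_type=access_type, n_using=using.size, n_not_using=not_using.size,
        mean_pred_using=float(using.mean()) if using.size else float("nan"),
        mean_pred_not_using=float(not_using.mean()) if not_using.size else float("nan"),
    )
    if using.size == 0 or not_using.size == 0:
        return GroupComparison(**base, test_used="untestable",
                               statistic=float("nan"), p_value=float("nan"),
                               note="one group empty; no statistical conclusion possible")
    if np.ptp(np.concatenate([using, not_using])) == 0:
        return GroupComparison(**base, test_used="untestable",
                               statistic=float("nan"), p_value=float("nan"),
                               note="zero variance (all households share one prediction)")

    if _ks_normal(using) < KS_GATE_P or _ks_normal(not_using) < KS_GATE_P:
        if min(using.size, not_using.size) < EXACT_MODE_MAX_N:
            res = stats.mannwhitneyu(using, not_using, alternative="two-sided",
                                     method="auto")
            return GroupComparison(**base, test_used="wilcoxon",
                                   statistic=float(res.statistic),
                                   p_value=float(res.pvalue),
                                   note="exact small-sample mode (U statistic)")
        z, p = rank_sum_z(using, not_using)
        return GroupComparison(**base, test_used="wilcoxon", statistic=z, p_value=p)
    res = stats.ttest_ind(using, not_using, equal_var=True)
    return GroupComparison(**base, test_used="t",
                           statistic=float(res.statistic), p_value=float(res.pvalue))


@dataclass
class ZTestResult:
    z: float
    p_two_sided: float
    p_one_sided: float  # in the direction of the observed difference


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> ZTestResult:
    """Pooled two-proportion z-test."""
    if n1 < 1 or n2 < 1:
        raise ValueError("both sample sizes must be at least 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes must lie between 0 and the sample size")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        raise ValueError("pooled proportion is 0 or 1; z statistic undefined")
    se = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    z = (p1 - p2) / se
    return ZTestResult(z, float(2 * stats.norm.sf(abs(z))),
                       float(stats.norm.sf(abs(z))))


def min_sample_size(chi2: float, n_p: int, p_p: float, d: float) -> tuple[float, int]:
    """Minimum representative sample size for a finite population.

    s = chi2 * N * P(1-P) / (d^2 (N-1) + chi2 * P(1-P)); returns the raw
    value and its ceiling. Monotone increasing in N and bounded above by
    the infinite-population value chi2 * P(1-P) / d^2.
    """
    if chi2 <= 0 or n_p <= 0:
        raise ValueError("chi2 and population size must be positive")
    if not (0 < p_p < 1 and 0 < d < 1):
        raise ValueError("proportions must lie in (0, 1)")
    pq = p_p * (1 - p_p)
    raw = chi2 * n_p * pq / (d**2 * (n_p - 1) + chi2 * pq)
    return float(raw), int(math.ceil(raw))


def comparison_table(comparisons, path=None) -> pd.DataFrame:
    """Survey-validation summary, one row per access type."""
    rows = [{
        "access_type": c.access_type,
        "hhs_using": c.n_using, "mean_pred_using": c.mean_pred_using,
        "hhs_not_using": c.n_not_using, "mean_pred_not_using": c.mean_pred_not_using,
        "test": c.test_used, "statistic": c.statistic, "p": c.p_value,
        "note": c.note,
    } for c in comparisons]
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
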