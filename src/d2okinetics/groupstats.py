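"""Age-group comparison layer: Welch tests, BH-FDR flags, table inversions.

Group sizes differ between age cohorts (every animal across labeling
durations is one biological replicate for concentration-type outcomes), and
variances are expected to change with age, so the comparison is an unpaired
two-tailed Welch t-test. Benjamini-Hochberg control is applied per outcome
family (concentrations, half-lives, absolute synthesis separately).

``invert_comparison`` recovers the two group means from a printed
(fold-change, mean-difference) pair, the identity used to reconstruct
summary-table entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["WelchResult", "welch_t", "bh_fdr", "invert_comparison",
           "compare_groups"]


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float                 # Welch-Satterthwaite degrees of freedom
    p: float                  # two-tailed
    diff: float               # mean(x) - mean(y)
    ci: tuple[float, float]   # 95% CI of the difference


def welch_t(x, y) -> WelchResult:
    """Two-tailed Welch t-test of mean(x) - mean(y) with a 95% CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("both samples have zero variance")
    res = stats.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(0.95)
    return WelchResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue),
                       diff=float(x.mean() - y.mean()),
                       ci=(float(ci.low), float(ci.high)))


def bh_fdr(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def invert_comparison(fold: float, diff: float) -> tuple[float, float]:
    """Recover group means from fold-change (old:young) and difference (old - young).

    mean_young = diff / (fold - 1); mean_old = fold * mean_young.
    """
    if fold == 1:
        raise ValueError("fold = 1 makes the system singular")
    mean_young = diff / (fold - 1.0)
    return mean_young, fold * mean_young


def compare_groups(
    df: pd.DataFrame,
    value: str,
    group: str = "age_group",
    by: str = "protein",
    reference: str | None = None,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-protein Welch comparison between two groups with BH flags.

    ``reference`` names the baseline (young) group; the difference and
    fold-change are computed as other minus/over reference. Rows where either
    group has n < 2 or both variances are zero are reported with NaN
    statistics and excluded from BH adjustment.
    """
    groups = sorted(df[group].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    ref = groups[0] if reference is None else reference
    other = [g for g in groups if g != ref][0]

    rows = []
    for prot, sub in df.groupby(by, sort=True):
        x = sub.loc[sub[group] == other, value].dropna().to_numpy()
        y = sub.loc[sub[group] == ref, value].dropna().to_numpy()
        base = {by: prot, "n_" + str(other): len(x), "n_" + str(ref): len(y)}
        try:
            res = welch_t(x, y)
            fold = x.mean() / y.mean() if y.mean() != 0 else np.nan
            base.update(fold_change=fold, mean_diff=res.diff,
                        ci_low=res.ci[0], ci_high=res.ci[1],
                        t=res.t, df=res.df, p=res.p)
        except ValueError:
            base.update(fold_change=np.nan, mean_diff=np.nan, ci_low=np.nan,
                        ci_high=np.nan, t=np.nan, df=np.nan, p=np.nan)
        rows.append(base)
    out = pd.DataFrame(rows)
    out["bh_significant"] = False
    ok = out["p"].notna()
    if ok.any():
        out.loc[ok, "bh_significant"] = bh_fdr(out.loc[ok, "p"].to_numpy(), q=q)
    return out
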