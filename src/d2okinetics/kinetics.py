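"""Per-peptide synthesis-rate fitting and protein-level aggregation.

The relative M0 abundance of each peptide declines from its natural value
toward a precursor-determined plateau as deuterium is incorporated into newly
synthesized protein. A single first-order rate constant k (1/day) is fit per
peptide; peptide rates are screened with an iterative Grubbs outlier test and
aggregated to a protein mean with a pooled standard deviation. Half-life is
ln(2)/k; proteins with no detectable M0 decline are flagged not-measurable and
rendered as dashes, never as huge numbers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .isotope import expected_M0

__all__ = [
    "PeptideTimeCourse",
    "PeptideRateFit",
    "ProteinKineticResult",
    "fit_peptide_k",
    "grubbs_critical",
    "grubbs_filter",
    "aggregate_protein",
    "half_life",
    "days_to_years",
    "K_BOUNDS",
]

K_BOUNDS = (0.0, 2.0)  # 1/day; upper bound ~ t1/2 of 8 h, far below any duration here
DAYS_PER_YEAR = 365.0


@dataclass
class PeptideTimeCourse:
    """Observed relative M0 abundances for one peptide across animals/durations."""

    protein: str
    peptide: str
    days: np.ndarray      # labeling duration per observation (days)
    m0: np.ndarray        # relative M0 abundance per observation

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.m0 = np.asarray(self.m0, dtype=float)
        if self.days.shape != self.m0.shape or self.days.ndim != 1:
            raise ValueError("days and m0 must be 1-D arrays of equal length")
        if np.any(self.days < 0):
            raise ValueError("labeling durations must be >= 0")
        if np.any((self.m0 < 0) | (self.m0 > 1)):
            raise ValueError("relative M0 abundances must lie in [0, 1]")

    def labeled(self) -> "PeptideTimeCourse":
        """Observations at positive durations (day-0 rows anchor M0_nat only)."""
        mask = self.days > 0
        return PeptideTimeCourse(self.protein, self.peptide,
                                 self.days[mask], self.m0[mask])


@dataclass
class PeptideRateFit:
    k: float                  # synthesis rate constant (1/day)
    se: float                 # standard error of k from the fit covariance
    residual_sd: float        # SD of fit residuals
    n_obs: int
    converged: bool
    measurable: bool
    protein: str = ""
    peptide: str = ""


@dataclass
class ProteinKineticResult:
    protein: str
    k: float                      # mean of retained peptide rate constants
    pooled_sd: float              # df-weighted pooled SD across peptides
    n_peptides: int
    half_life_days: float         # ln(2)/k; NaN when not measurable
    half_life_years: float
    measurable: bool
    peptides_removed: list = field(default_factory=list)


def fit_peptide_k(
    tc: PeptideTimeCourse,
    M0_nat: float,
    M0_plateau: float,
    k_bounds: tuple[float, float] = K_BOUNDS,
) -> PeptideRateFit:
    """Nonlinear least-squares fit of the first-order M0 decay for one peptide.

    ``M0_nat`` and ``M0_plateau`` are held fixed (the default pipeline mode):
    only k is free, bounded in ``k_bounds``. A series flat at natural abundance
    yields k = 0 with ``measurable=False``. Measurability requires the fitted
    total M0 decline over the observed window to exceed 3x the residual SD.
    """
    if not M0_plateau < M0_nat:
        raise ValueError("require M0_plateau < M0_nat")
    lab = tc.labeled()
    if len(np.unique(lab.days)) < 2:
        raise ValueError(
            f"peptide {tc.peptide!r}: need >= 2 distinct labeled durations"
        )
    t, y = lab.days, lab.m0

    def model(tt, k):
        return expected_M0(tt, k, M0_nat, M0_plateau)

    # closed-form starting value from the mean log-residual decline
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.clip((y - M0_plateau) / (M0_nat - M0_plateau), 1e-12, None)
        k0 = float(np.clip(np.mean(-np.log(frac) / t), k_bounds[0] + 1e-6,
                           k_bounds[1] - 1e-6))
    try:
        popt, pcov = curve_fit(model, t, y, p0=[k0], bounds=([k_bounds[0]],
                                                             [k_bounds[1]]),
                               maxfev=10000)
        converged = True
    except RuntimeError:
        popt, pcov = np.array([0.0]), np.array([[np.nan]])
        converged = False
    k = float(popt[0])
    # the bounded solver can stall near the k=0 boundary on flat series
    if np.sum((y - model(t, k)) ** 2) >= np.sum((y - M0_nat) ** 2):
        k = 0.0
    resid = y - model(t, k)
    dof = max(len(y) - 1, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan

    decline = (M0_nat - M0_plateau) * (1.0 - math.exp(-k * t.max()))
    measurable = bool(converged and k > 0 and decline > 3.0 * residual_sd)
    if not measurable and decline <= residual_sd:
        k = 0.0 if decline < 1e-12 else k
    return PeptideRateFit(k=k, se=se, residual_sd=residual_sd, n_obs=len(y),
                          converged=converged, measurable=measurable,
                          protein=tc.protein, peptide=tc.peptide)


def grubbs_critical(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the t distribution."""
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t_crit = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / math.sqrt(n) * math.sqrt(t_crit**2 / (n - 2 + t_crit**2))


def grubbs_filter(values, alpha: float = 0.05):
    """Iterative two-sided Grubbs outlier screen on per-peptide rate constants.

    Removes at most one value per iteration (the largest absolute deviation
    from the mean) while the test rejects; the test runs whenever n >= 3.
    With fewer than three values no test is performed and all are retained
    with a warning. Returns ``(retained, removed)`` preserving input order.
    """
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")
    vals = [float(v) for v in values]
    if len(vals) < 3:
        if len(vals) < 3 and len(vals) > 0:
            warnings.warn(
                f"Grubbs test skipped: n={len(vals)} < 3, all values retained",
                stacklevel=2,
            )
        return list(vals), []
    keep = sorted(range(len(vals)), key=lambda i: vals[i])  # deterministic order
    removed_idx: list[int] = []
    while len(keep) >= 3:
        arr = np.array([vals[i] for i in keep])
        s = arr.std(ddof=1)
        if s == 0:
            break
        dev = np.abs(arr - arr.mean())
        j = int(np.argmax(dev))
        if dev[j] / s > grubbs_critical(len(arr), alpha):
            removed_idx.append(keep.pop(j))
        else:
            break
    keep_set = set(keep)
    retained = [vals[i] for i in range(len(vals)) if i in keep_set]
    removed = [vals[i] for i in sorted(removed_idx)]
    return retained, removed


def aggregate_protein(
    fits: list[PeptideRateFit],
    grubbs_alpha: float = 0.05,
) -> ProteinKineticResult:
    """Combine peptide-level rate fits into one protein-level result.

    Only measurable peptides enter the mean; their k's are screened with the
    Grubbs filter first. The pooled SD is the square root of the df-weighted
    mean of per-peptide variances (df = n_obs - 1). A protein with no
    measurable peptide is flagged not-measurable (rendered downstream as a
    dash) and its half-life is NaN.
    """
    if not fits:
        raise ValueError("aggregate_protein requires >= 1 peptide fit")
    protein = fits[0].protein
    usable = [f for f in fits if f.measurable]
    if not usable:
        return ProteinKineticResult(protein=protein, k=0.0, pooled_sd=np.nan,
                                    n_peptides=0, half_life_days=np.nan,
                                    half_life_years=np.nan, measurable=False)
    ks = [f.k for f in usable]
    retained, removed = grubbs_filter(ks, alpha=grubbs_alpha)
    retained_set = list(retained)
    kept_fits = []
    for f in usable:  # map retained values back to fits, tolerating ties
        if f.k in retained_set:
            retained_set.remove(f.k)
            kept_fits.append(f)
    mean_k = float(np.mean([f.k for f in kept_fits]))
    dfs = np.array([max(f.n_obs - 1, 1) for f in kept_fits], dtype=float)
    variances = np.array([f.se**2 for f in kept_fits], dtype=float)
    if np.all(np.isfinite(variances)):
        pooled_sd = float(np.sqrt(np.sum(dfs * variances) / np.sum(dfs)))
    else:
        pooled_sd = float(np.nan)
    hl = half_life(mean_k) if mean_k > 0 else np.nan
    return ProteinKineticResult(
        protein=protein, k=mean_k, pooled_sd=pooled_sd,
        n_peptides=len(kept_fits), half_life_days=hl,
        half_life_years=days_to_years(hl) if np.isfinite(hl) else np.nan,
        measurable=True, peptides_removed=removed,
    )


def half_life(k: float) -> float:
    """Half-life in days, ln(2)/k. Raises for k <= 0 (not-measurable upstream)."""
    if k <= 0:
        raise ValueError("half-life undefined for k <= 0; flag as not measurable")
    return math.log(2) / k


def days_to_years(d: float) -> float:
    """Convert days to years (365 d/yr); report at 3 significant figures."""
    if d < 0:
        raise ValueError("negative duration")
    return d / DAYS_PER_YEAR
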