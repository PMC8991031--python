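"""Body-water (precursor) enrichment: calibration and time-course fitting.

Animals receive an i.p. bolus of D2O followed by enriched drinking water, so
serum enrichment starts at a nonzero offset and rises exponentially to a
maintenance plateau. Instrument readings are first mapped to mole fractions
through a standard curve of known D2O dilutions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["PrecursorModel", "calibrate_enrichment", "fit_precursor"]

DEFAULT_PLATEAU = 0.055  # cohort body-water plateau, fraction


@dataclass(frozen=True)
class PrecursorModel:
    """Bolus + rise-to-plateau body-water enrichment curve.

    p(t) = p_max - (p_max - p_0) * exp(-k_p * t)
    """

    p_max: float          # plateau enrichment (fraction)
    k_p: float            # rise rate (1/day)
    p_0: float            # enrichment immediately after the bolus (fraction)
    p_max_ci: tuple[float, float] = (np.nan, np.nan)  # 95% CI of the plateau
    converged: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_0 <= self.p_max < 0.2):
            raise ValueError(
                f"require 0 <= p_0 <= p_max < 0.2, got p_0={self.p_0}, p_max={self.p_max}"
            )
        if self.k_p < 0:
            raise ValueError("rise rate k_p must be >= 0")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return self.p_max - (self.p_max - self.p_0) * np.exp(-self.k_p * t)


def calibrate_enrichment(readings, standards) -> np.ndarray:
    """Map instrument readings to D2O mole fractions via a standard curve.

    ``standards`` is a sequence of ``(known_fraction, reading)`` pairs. An
    ordinary least-squares line ``reading = a + b * fraction`` is fit through
    the standards and inverted for the samples.
    """
    standards = np.asarray(standards, dtype=float)
    if standards.ndim != 2 or standards.shape[1] != 2 or len(standards) < 2:
        raise ValueError("need >= 2 (known_fraction, reading) standard pairs")
    known, resp = standards[:, 0], standards[:, 1]
    if np.ptp(known) == 0:
        raise ValueError("standard concentrations are identical; curve is singular")
    slope, intercept = np.polyfit(known, resp, 1)
    if slope == 0:
        raise ValueError("standard curve has zero slope; cannot invert")
    readings = np.asarray(readings, dtype=float)
    return (readings - intercept) / slope


def _rise(t, p_max, k_p, p_0):
    return p_max - (p_max - p_0) * np.exp(-k_p * t)


def fit_precursor(days, enrichments) -> PrecursorModel:
    """Fit the bolus + rise-to-plateau model to serum enrichment samples.

    Requires observations at >= 3 distinct days. The plateau 95% CI comes
    from the fit covariance. A fit that fails to converge is returned with
    ``converged=False`` (never a silent failure).
    """
    days = np.asarray(days, dtype=float)
    y = np.asarray(enrichments, dtype=float)
    if days.shape != y.shape:
        raise ValueError("days and enrichments must have the same length")
    if np.any(y < 0) or np.any(y >= 0.2):
        raise ValueError("enrichment values must lie in [0, 0.2)")
    if len(np.unique(days)) < 3:
        raise ValueError("need samples at >= 3 distinct days to fit the rise model")

    if np.ptp(y) < 1e-12:
        level = float(y[0])
        return PrecursorModel(level, 0.0, level, (level, level), converged=True)

    p0 = [max(y.max(), 1e-4), 0.3, max(y.min(), 0.0)]
    try:
        popt, pcov = curve_fit(
            _rise, days, y, p0=p0,
            bounds=([0.0, 0.0, 0.0], [0.2 - 1e-9, 50.0, 0.2 - 1e-9]),
            maxfev=20000,
        )
        converged = np.all(np.isfinite(popt))
    except RuntimeError:
        popt, pcov = p0, np.full((3, 3), np.nan)
        converged = False
    p_max, k_p, p_0_hat = (float(v) for v in popt)
    p_0_hat = min(p_0_hat, p_max)
    se = float(np.sqrt(pcov[0, 0])) if np.isfinite(pcov[0, 0]) else np.nan
    ci = (p_max - 1.96 * se, p_max + 1.96 * se)
    return PrecursorModel(p_max, k_p, p_0_hat, ci, converged=bool(converged))
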