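"""Assay quantification: 4PL dose-response fitting, MALDI adduct fractions,
and linear standard-curve calibration.

The four-parameter logistic (4PL) model in log10-dose space is

    Y = Bottom + (Top - Bottom) / (1 + 10**((LogIC50 - X) * HillSlope))

with X = log10(dose).  With a positive Hill slope the response increases with
dose; inhibition curves (response falling with dose) fit with a negative Hill
slope.  At X = LogIC50 the fitted curve passes through (Top + Bottom) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import FitError, InvalidParameterError

__all__ = [
    "FourPLFit",
    "MALDI_ADDUCT_MZ",
    "four_pl",
    "fit_4pl",
    "maldi_fractions",
    "CalibrationResult",
    "linear_calibration",
]

#: Nominal m/z of the 8-mer duplex adducts resolved by MALDI-TOF.
MALDI_ADDUCT_MZ = {"5mC": 2424.6, "5hmC": 2440.6, "5fC": 2438.6, "5caC": 2454.6}


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL parameters plus diagnostics."""

    bottom: float
    top: float
    log_ic50: float
    hill_slope: float
    rss: float
    converged: bool

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_ic50

    def predict(self, doses):
        return four_pl(np.log10(np.asarray(doses, dtype=float)),
                       self.bottom, self.top, self.log_ic50, self.hill_slope)


def four_pl(x, bottom, top, log_ic50, hill_slope):
    """Evaluate the 4PL curve at log10-dose ``x``."""
    x = np.asarray(x, dtype=float)
    with np.errstate(over="ignore"):
        return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - x) * hill_slope))


def fit_4pl(doses, responses) -> FourPLFit:
    """Least-squares fit of the 4PL model to a dose-response table.

    Parameters
    ----------
    doses : array-like
        Positive concentrations (at least 5 distinct values).
    responses : array-like
        Measured responses, same length.

    Raises
    ------
    InvalidParameterError
        Fewer than 5 distinct doses, non-positive doses, or non-finite data.
    FitError
        Degenerate (dose-independent) responses or optimizer failure.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.shape != y.shape or d.ndim != 1:
        raise InvalidParameterError("doses and responses must be 1-D and same length")
    if np.any(d <= 0):
        raise InvalidParameterError("doses must be positive (log scale)")
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(y))):
        raise InvalidParameterError("doses and responses must be finite")
    if len(np.unique(d)) < 5:
        raise InvalidParameterError("need at least 5 distinct doses")

    x = np.log10(d)
    span = float(y.max() - y.min())
    if span <= 0:
        raise FitError("responses are constant; IC50 is unidentifiable")

    # Heuristic start: extremes for the asymptotes, the dose nearest
    # mid-response for LogIC50, slope sign from the response direction.
    mid = 0.5 * (y.max() + y.min())
    x0 = float(x[np.argmin(np.abs(y - mid))])
    direction = np.sign(np.polyfit(x, y, 1)[0]) or 1.0
    p0 = [float(y.min()), float(y.max()), x0, float(direction)]
    lower = [y.min() - span, y.min() - span, x.min() - 2.0, -10.0]
    upper = [y.max() + span, y.max() + span, x.max() + 2.0, 10.0]
    try:
        popt, _ = optimize.curve_fit(
            four_pl, x, y, p0=p0, bounds=(lower, upper), maxfev=20000
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc
    resid = y - four_pl(x, *popt)
    return FourPLFit(
        bottom=float(popt[0]),
        top=float(popt[1]),
        log_ic50=float(popt[2]),
        hill_slope=float(popt[3]),
        rss=float(resid @ resid),
        converged=True,
    )


def maldi_fractions(peaks: dict) -> dict:
    """Adduct fractions from a MALDI peak-intensity table.

    Each fraction is the adduct's peak intensity divided by the summed
    intensity over all adducts; fractions sum to 1.
    """
    if not peaks:
        raise InvalidParameterError("empty peak table")
    vals = {k: float(v) for k, v in peaks.items()}
    if any(v < 0 for v in vals.values()):
        raise InvalidParameterError("peak intensities must be non-negative")
    total = sum(vals.values())
    if total <= 0:
        raise InvalidParameterError("all peak intensities are zero")
    return {k: v / total for k, v in vals.items()}


@dataclass(frozen=True)
class CalibrationResult:
    """Concentration inverted through a linear standard curve."""

    concentration: float
    below_range: bool
    slope: float
    intercept: float
    r_squared: float


def linear_calibration(standards, unknown_signal: float) -> CalibrationResult:
    """Invert an unknown signal through an OLS line fit to standards.

    ``standards`` is a sequence of (concentration, signal) pairs (>= 2, with
    distinct concentrations).  Negative inverted concentrations are reported
    as 0 with ``below_range=True`` (signal below the blank).
    """
    pairs = [(float(c), float(s)) for c, s in standards]
    if len(pairs) < 2:
        raise InvalidParameterError("need at least 2 standards")
    conc = np.array([p[0] for p in pairs])
    sig = np.array([p[1] for p in pairs])
    if len(np.unique(conc)) < 2 or len(np.unique(sig)) < 2:
        raise InvalidParameterError("standards are degenerate (no signal variation)")
    res = stats.linregress(conc, sig)
    if res.slope == 0:
        raise InvalidParameterError("zero calibration slope; cannot invert")
    est = (float(unknown_signal) - res.intercept) / res.slope
    below = est < 0
    return CalibrationResult(
        concentration=0.0 if below else float(est),
        below_range=bool(below),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
    )
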