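"""Residue depletion and withdrawal-time estimation against an MRL.

After a medicated-feed course ends, edible-tissue residues decline roughly
mono-exponentially, so ``ln(residue)`` is regressed on time since the end
of dosing. The withdrawal time is when predicted residues fall below the
maximum residue limit (MRL; 1,000 ug/kg for florfenicol marker residue in
fish muscle). Two estimators are provided:

* ``point`` — the regression line itself crosses the MRL:
  ``t = (intercept - ln MRL) / (-slope)``;
* ``tolerance-95-95`` — the regulatory-style upper one-sided 95%
  tolerance limit for the 95th percentile of residues crosses the MRL.
  The limit at time t is ``yhat(t) + k(t) * s`` with
  ``k(t) = t'_{0.95, n-2, delta(t)} * sqrt(d(t))``, where
  ``d(t) = 1/n + (t - tbar)^2 / Sxx`` and the noncentrality is
  ``delta(t) = z_{0.95} / sqrt(d(t))`` (noncentral-t construction).

Both estimates are reported in whole days, rounded up (conservative
convention), measured from the end of dosing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

#: Regulatory maximum residue limit for florfenicol marker residue in fish
#: muscle, ug/kg.
DEFAULT_MRL = 1000.0


class ResidueError(ValueError):
    """Residue analysis cannot proceed on the given inputs."""


@dataclass(frozen=True)
class ResidueSeries:
    """Muscle residue measurements across a dosing + depuration trial.

    ``days`` are days since trial start; ``dosing_end_day`` marks the last
    medicated day (depletion is analysed after it).
    """

    dose_group: str
    analyte: str
    days: np.ndarray
    residues: np.ndarray
    dosing_end_day: float = 30.0

    def __post_init__(self) -> None:
        days = np.asarray(self.days, dtype=float)
        residues = np.asarray(self.residues, dtype=float)
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "residues", residues)
        if len(days) != len(residues):
            raise ResidueError("days and residues must have equal length")
        if np.any(np.diff(days) <= 0):
            raise ResidueError("days must be strictly increasing")
        if np.any(residues < 0):
            raise ResidueError("residues must be non-negative")


@dataclass(frozen=True)
class DepletionFit:
    """Log-linear depletion regression, time origin at end of dosing."""

    slope: float          # 1/day, expected negative
    intercept: float      # ln ug/kg at end of dosing
    r_squared: float
    n: int
    residual_sd: float    # of log residuals, df = n - 2
    t_mean: float
    sxx: float
    flagged: bool         # True when the slope is non-negative

    def predict_log(self, t) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass(frozen=True)
class WithdrawalEstimate:
    """Withdrawal time for one dose group against an MRL."""

    slope: float
    intercept: float
    r_squared: float
    wt_point: int            # whole days after end of dosing, rounded up
    wt_tolerance: int | None  # same, from the 95/95 tolerance limit
    mrl: float
    method: str


def fit_depletion(series: ResidueSeries, window: tuple[float, float] | None = None
                  ) -> DepletionFit:
    """Least squares of ln(residue) on days after dosing end.

    ``window`` optionally restricts the fit to ``(start, end)`` days after
    the end of dosing; by default every sample at or after the end of
    dosing enters. Requires at least 3 positive residues.
    """
    rel = series.days - series.dosing_end_day
    keep = rel >= 0
    if window is not None:
        keep &= (rel >= window[0]) & (rel <= window[1])
    keep &= series.residues > 0
    t = rel[keep]
    y = np.log(series.residues[keep])
    n = len(t)
    if n < 3:
        raise ResidueError(
            f"group {series.dose_group}: {n} positive residue(s) in window, need 3"
        )
    slope, intercept = np.polyfit(t, y, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    sd = math.sqrt(ss_res / (n - 2)) if n > 2 else 0.0
    flagged = slope >= -1e-12  # flat-within-roundoff counts as non-depleting
    if flagged:
        logger.warning("group %s: non-negative depletion slope %.4g; "
                       "withdrawal time undefined", series.dose_group, slope)
    return DepletionFit(slope=float(slope), intercept=float(intercept),
                        r_squared=r2, n=n, residual_sd=sd,
                        t_mean=float(t.mean()),
                        sxx=float(np.sum((t - t.mean()) ** 2)),
                        flagged=flagged)


def _tolerance_limit_log(fit: DepletionFit, t, *, p: float = 0.95,
                         confidence: float = 0.95) -> np.ndarray:
    """Upper one-sided (confidence, p) tolerance limit of ln residue at t."""
    t = np.asarray(t, dtype=float)
    d = 1.0 / fit.n + (t - fit.t_mean) ** 2 / fit.sxx
    if fit.residual_sd == 0.0:
        return fit.predict_log(t)
    delta = stats.norm.ppf(p) / np.sqrt(d)
    k = stats.nct.ppf(confidence, fit.n - 2, delta) * np.sqrt(d)
    return fit.predict_log(t) + k * fit.residual_sd


def withdrawal_time(fit: DepletionFit, mrl: float = DEFAULT_MRL,
                    method: str = "point") -> WithdrawalEstimate:
    """Days (after end of dosing) until residues fall below the MRL.

    The point estimate solves the regression line against ln(MRL); the
    ``tolerance-95-95`` method additionally solves the upper tolerance
    limit, which always lies at or above the line, so
    ``wt_tolerance >= wt_point``. Both are rounded up to whole days and
    floored at zero.
    """
    if method not in ("point", "tolerance-95-95"):
        raise ResidueError(f"unknown withdrawal method {method!r}")
    if mrl <= 0:
        raise ResidueError("MRL must be positive")
    if fit.flagged or fit.slope >= -1e-12:
        raise ResidueError("non-negative depletion slope; withdrawal time undefined")

    log_mrl = math.log(mrl)
    t_point = (fit.intercept - log_mrl) / (-fit.slope)
    wt_point = max(0, math.ceil(t_point - 1e-9))

    wt_tol = None
    if method == "tolerance-95-95":
        def excess(t):
            return float(_tolerance_limit_log(fit, t) - log_mrl)

        t_lo = max(t_point, 0.0)
        if excess(t_lo) <= 0:
            wt_tol = max(0, math.ceil(t_lo - 1e-9))
        else:
            # the tolerance band is wider than the line, so the crossing is
            # later; scan outward then bisect
            t_hi, horizon = t_lo + 1.0, max(50.0 * (t_lo + 1.0), 1000.0)
            while excess(t_hi) > 0:
                t_hi *= 2.0
                if t_hi > horizon:
                    raise ResidueError(
                        "tolerance limit never falls below the MRL within "
                        f"{horizon:.0f} days")
            root = optimize.brentq(excess, t_lo, t_hi)
            wt_tol = max(0, math.ceil(root - 1e-9))
        wt_tol = max(wt_tol, wt_point)

    return WithdrawalEstimate(slope=fit.slope, intercept=fit.intercept,
                              r_squared=fit.r_squared, wt_point=wt_point,
                              wt_tolerance=wt_tol, mrl=mrl, method=method)


def mrl_compliance(series: ResidueSeries, mrl: float = DEFAULT_MRL,
                   day: float | None = None) -> bool:
    """Is the residue at ``day`` (default: last sampling day) <= MRL?

    A residue exactly at the MRL is compliant.
    """
    if day is None:
        day = float(series.days[-1])
    match = np.flatnonzero(series.days == day)
    if match.size == 0:
        raise ResidueError(
            f"group {series.dose_group}: no sample on day {day:g}"
        )
    return bool(series.residues[match[0]] <= mrl)
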