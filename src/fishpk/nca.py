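"""Non-compartmental analysis (NCA) of a concentration-time profile.

Estimates the standard single-dose parameters directly from the observed
curve, without fitting a compartment model:

* ``Cmax`` / ``Tmax`` — maximum observed concentration and its time
  (first occurrence on ties);
* ``AUC(0-last)`` — linear trapezoidal area under the curve;
* ``k_el`` — terminal elimination rate constant, the negative slope of an
  ordinary least-squares fit of ln C against t over a post-Tmax window;
* ``AUC(last-inf)`` — tail extrapolation ``C_last / k_el`` and the total
  ``AUC(0-inf)`` as the sum of observed and extrapolated areas;
* the half-life family ``t_1/2 = ln 2 / k_el``, mean lifetime
  ``T = t_1/2 / ln 2`` and decay constant ``lambda = 1 / T``. The reported
  absorption constant follows the convention ``Ka = ln 2 / t_1/2`` used in
  tissue-residue studies of florfenicol; it is numerically equal to the
  decay constant and is not an independently estimated absorption rate.

Negative terminal slopes are reported and flagged rather than suppressed:
sparse metabolite tail data can genuinely produce a rising terminal fit,
and hiding it would silently bias any downstream summary.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .profiles import ConcentrationTimeProfile, StudyDataset, tissue_sort_key

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)

FLAG_INSUFFICIENT = "insufficient"
FLAG_NO_TERMINAL = "insufficient terminal phase"
FLAG_NEGATIVE_KEL = "negative k_el"
FLAG_HIGH_EXTRAPOLATION = "extrapolated fraction > 20%"


class NCAError(ValueError):
    """Requested NCA quantity cannot be computed from the given inputs."""


@dataclass(frozen=True)
class TerminalPhaseSpec:
    """How to choose the log-linear terminal window.

    strategy
        ``"best-r2-search"`` (default): among all contiguous windows of at
        least ``min_points`` quantifiable post-Tmax points ending at the
        last quantifiable point, pick the one with maximal r-squared; ties
        favour more points. ``"fixed-last-n"``: always the last
        ``min_points`` quantifiable post-Tmax points.
    min_points
        Minimum window size, >= 3.
    """

    strategy: str = "best-r2-search"
    min_points: int = 3

    def __post_init__(self) -> None:
        if self.strategy not in ("best-r2-search", "fixed-last-n"):
            raise ValueError(f"unknown terminal-phase strategy {self.strategy!r}")
        if self.min_points < 3:
            raise ValueError("min_points must be >= 3")


@dataclass(frozen=True)
class TerminalFit:
    """OLS fit of ln C vs t over the selected terminal window."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    t_start: float
    t_end: float

    @property
    def k_el(self) -> float:
        return -self.slope


@dataclass
class NCAResult:
    """All derived parameters for one profile, plus quality flags."""

    tissue: str
    analyte: str
    tmax: float | None = None
    cmax: float | None = None
    auc_0_last: float | None = None
    k_el: float | None = None
    auc_tail: float | None = None
    auc_0_inf: float | None = None
    t_half: float | None = None
    mean_lifetime: float | None = None
    decay_constant: float | None = None
    ka: float | None = None
    auc_ratio: float | None = None   # AUC(tissue)/AUC(plasma), same analyte
    mr: float | None = None          # metabolite ratio, metabolite results only
    terminal_fit: TerminalFit | None = None
    flags: list[str] = field(default_factory=list)


def _auc_points(profile: ConcentrationTimeProfile, bloq_policy: str = "exclude"):
    """Times/concentrations entering the trapezoid, after BLOQ handling.

    Policies (the assay is silent below its LOQ, so some convention is
    required):

    * ``"exclude"`` (default): BLOQ points before Tmax contribute 0 (the
      drug has not appeared yet); BLOQ points after Tmax are dropped.
    * ``"loq2"``: every BLOQ point is replaced by LOQ/2.
    """
    t = profile.times
    c = profile.concentrations.copy()
    bloq = profile.bloq_mask
    if not bloq.any():
        return t, c
    if bloq_policy == "loq2":
        c = np.where(bloq, profile.loq / 2.0, c)
        return t, c
    if bloq_policy != "exclude":
        raise ValueError(f"unknown BLOQ policy {bloq_policy!r}")
    quant = profile.quantifiable
    if not quant.any():
        return t[:0], c[:0]
    tmax = t[quant][np.argmax(c[quant])]
    keep = quant | (t <= tmax)
    c = np.where(bloq, 0.0, c)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("(%s, %s): dropping %d BLOQ point(s) after Tmax from AUC",
                    profile.tissue, profile.analyte, dropped)
    return t[keep], c[keep]


def auc_trapezoid(profile: ConcentrationTimeProfile, *, bloq_policy: str = "exclude") -> float:
    """Linear trapezoidal AUC(0-last) in h*ug/kg.

    Sum over consecutive intervals of ``(C_i + C_{i+1}) / 2 * (t_{i+1} - t_i)``.
    """
    if profile.insufficient:
        raise NCAError(
            f"({profile.tissue}, {profile.analyte}): fewer than 2 quantifiable points"
        )
    t, c = _auc_points(profile, bloq_policy)
    if len(t) < 2:
        return 0.0
    return float(np.trapezoid(c, t))


def _ols_loglinear(t: np.ndarray, logc: np.ndarray) -> tuple[float, float, float]:
    """Plain least squares of ln C on t; returns (slope, intercept, r2)."""
    slope, intercept = np.polyfit(t, logc, 1)
    fitted = slope * t + intercept
    ss_res = float(np.sum((logc - fitted) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return float(slope), float(intercept), r2


def fit_terminal_phase(profile: ConcentrationTimeProfile,
                       spec: TerminalPhaseSpec = TerminalPhaseSpec()) -> TerminalFit:
    """Fit the terminal log-linear phase; ``k_el`` is the negated slope.

    Only quantifiable, strictly positive concentrations strictly after
    Tmax are eligible; the search window always ends at the last such
    point.

    Raises
    ------
    NCAError
        If fewer than ``spec.min_points`` eligible points exist.
    """
    if profile.insufficient:
        raise NCAError(
            f"({profile.tissue}, {profile.analyte}): fewer than 2 quantifiable points"
        )
    usable = profile.quantifiable & (profile.concentrations > 0)
    t_all = profile.times[usable]
    c_all = profile.concentrations[usable]
    tmax = t_all[np.argmax(c_all)]
    after = t_all > tmax
    t = t_all[after]
    logc = np.log(c_all[after])
    n = len(t)
    if n < spec.min_points:
        raise NCAError(
            f"({profile.tissue}, {profile.analyte}): only {n} quantifiable "
            f"point(s) after Tmax, need {spec.min_points}"
        )

    if spec.strategy == "fixed-last-n":
        starts = [n - spec.min_points]
    else:
        starts = range(n - spec.min_points, -1, -1)

    best = None
    for start in starts:
        slope, intercept, r2 = _ols_loglinear(t[start:], logc[start:])
        size = n - start
        # ties (within float fuzz) go to the larger window; iteration is
        # smallest-window first, so strict improvement keeps more points
        if best is None or r2 > best[0] + 1e-12:
            best = (r2, slope, intercept, size, t[start], t[-1])
    r2, slope, intercept, size, t0, t1 = best
    return TerminalFit(slope=slope, intercept=intercept, r_squared=r2,
                       n_points=size, t_start=t0, t_end=t1)


def extrapolate_auc_tail(c_last: float, k_el: float) -> float:
    """AUC from the last observation to infinity: ``C_last / k_el``.

    Assumes mono-exponential decline beyond the last sample.
    """
    if k_el <= 0:
        raise NCAError(f"{FLAG_NEGATIVE_KEL}: cannot extrapolate with k_el={k_el:g}")
    if c_last < 0:
        raise NCAError(f"negative C_last {c_last:g}")
    return c_last / k_el


def halflife_family(t_half: float) -> tuple[float, float, float]:
    """Derive (mean_lifetime, decay_constant, ka) from a half-life in hours.

    ``mean_lifetime = t_half / ln 2``, ``decay_constant = 1 / mean_lifetime``
    and ``ka = ln 2 / t_half`` (the study convention; numerically identical
    to the decay constant).
    """
    if t_half <= 0:
        raise NCAError(f"half-life must be positive, got {t_half:g}")
    mean_lifetime = t_half / LN2
    decay_constant = 1.0 / mean_lifetime
    ka = LN2 / t_half
    return mean_lifetime, decay_constant, ka


def tissue_plasma_ratio(auc_tissue: float, auc_plasma: float) -> float:
    """AUC(tissue) / AUC(plasma) for the same analyte — a distribution index."""
    if auc_plasma <= 0:
        raise NCAError(f"plasma AUC must be positive, got {auc_plasma:g}")
    return auc_tissue / auc_plasma


def analyze_profile(profile: ConcentrationTimeProfile,
                    spec: TerminalPhaseSpec = TerminalPhaseSpec(),
                    *, bloq_policy: str = "exclude") -> NCAResult:
    """Full NCA of a single profile; failures become flags, not exceptions."""
    result = NCAResult(tissue=profile.tissue, analyte=profile.analyte)
    if profile.insufficient:
        result.flags.append(FLAG_INSUFFICIENT)
        return result

    quant = profile.quantifiable
    t_q = profile.times[quant]
    c_q = profile.concentrations[quant]
    imax = int(np.argmax(c_q))  # argmax takes the first occurrence on ties
    result.cmax = float(c_q[imax])
    result.tmax = float(t_q[imax])
    result.auc_0_last = auc_trapezoid(profile, bloq_policy=bloq_policy)

    try:
        fit = fit_terminal_phase(profile, spec)
    except NCAError as exc:
        logger.info("terminal fit failed: %s", exc)
        result.flags.append(FLAG_NO_TERMINAL)
        return result

    result.terminal_fit = fit
    result.k_el = fit.k_el
    if fit.k_el <= 0:
        result.flags.append(FLAG_NEGATIVE_KEL)
        return result

    positive = c_q > 0
    c_last = float(c_q[positive][-1]) if positive.any() else 0.0
    result.auc_tail = extrapolate_auc_tail(c_last, fit.k_el)
    result.auc_0_inf = result.auc_0_last + result.auc_tail
    if result.auc_0_inf > 0 and result.auc_tail / result.auc_0_inf > 0.2:
        result.flags.append(FLAG_HIGH_EXTRAPOLATION)

    result.t_half = LN2 / fit.k_el
    result.mean_lifetime, result.decay_constant, result.ka = halflife_family(result.t_half)
    return result


def run_nca(dataset: StudyDataset,
            spec: TerminalPhaseSpec = TerminalPhaseSpec(),
            *, bloq_policy: str = "exclude") -> list[NCAResult]:
    """NCA of every profile in a dataset.

    Tissue/plasma AUC(0-last) ratios are filled for every non-plasma
    tissue whose analyte also has a plasma profile; a missing plasma
    profile logs a warning and leaves the ratios absent.
    """
    results = []
    plasma_auc: dict[str, float] = {}
    for profile in dataset:
        res = analyze_profile(profile, spec, bloq_policy=bloq_policy)
        results.append(res)
        if profile.tissue == "plasma" and res.auc_0_last is not None:
            plasma_auc[profile.analyte] = res.auc_0_last

    for res in results:
        if res.tissue == "plasma" or res.auc_0_last is None:
            continue
        ref = plasma_auc.get(res.analyte)
        if ref is None or ref <= 0:
            logger.warning("no plasma profile for analyte %s; tissue/plasma "
                           "ratio omitted for %s", res.analyte, res.tissue)
            continue
        res.auc_ratio = tissue_plasma_ratio(res.auc_0_last, ref)
    return sorted(results, key=lambda r: (tissue_sort_key(r.tissue), r.analyte))
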