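"""Parent-metabolite disposition statistics.

Three ratio statistics summarise how much of the parent drug appears as
its metabolite in a tissue:

* apparent metabolic rate  ``AMR = AUC_m / (AUC_p + AUC_m)``  in [0, 1];
* metabolite ratio         ``MR  = AUC_m / AUC_p``            >= 0;
* apparent distribution rate, per time point,
  ``ADR(t) = C_m(t) / (C_p(t) + C_m(t))`` in [0, 1].

AMR and MR carry the same information (``AMR = MR / (1 + MR)``); both are
reported because both are conventional. ADR is a concentration ratio, so
it is invariant under any common rescaling of the two profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nca import NCAError, TerminalPhaseSpec, analyze_profile
from .profiles import ANALYTE_METABOLITE, ANALYTE_PARENT, ConcentrationTimeProfile, StudyDataset


def apparent_metabolic_rate(auc_ffa: float, auc_ff: float) -> float:
    """AMR = AUC_metabolite / (AUC_parent + AUC_metabolite), in [0, 1]."""
    if auc_ffa < 0 or auc_ff < 0:
        raise NCAError("AUCs must be non-negative")
    total = auc_ff + auc_ffa
    if total <= 0:
        raise NCAError("both AUCs are zero; AMR undefined")
    return auc_ffa / total


def metabolite_ratio(auc_ffa: float, auc_ff: float) -> float:
    """MR = AUC_metabolite / AUC_parent."""
    if auc_ff <= 0:
        raise NCAError(f"parent AUC must be positive, got {auc_ff:g}")
    if auc_ffa < 0:
        raise NCAError("metabolite AUC must be non-negative")
    return auc_ffa / auc_ff


@dataclass
class MetaboliteDisposition:
    """AMR/MR and the time-resolved ADR for one tissue's parent-metabolite pair."""

    tissue: str
    amr: float
    mr: float
    adr_times: np.ndarray
    adr_series: np.ndarray
    adr_summary: float


def apparent_distribution_rate(ff_profile: ConcentrationTimeProfile,
                               ffa_profile: ConcentrationTimeProfile
                               ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-time-point ADR over the shared quantifiable time grid.

    Returns ``(times, adr_series, adr_summary)`` where the summary is the
    arithmetic mean of the series. Time points where both analytes are
    BLOQ or zero are skipped (0/0 carries no information).
    """
    if ff_profile.tissue != ffa_profile.tissue:
        raise NCAError(
            f"profiles from different tissues: {ff_profile.tissue} vs {ffa_profile.tissue}"
        )
    shared, i_ff, i_ffa = np.intersect1d(
        ff_profile.times, ffa_profile.times, return_indices=True
    )
    ok = ff_profile.quantifiable[i_ff] & ffa_profile.quantifiable[i_ffa]
    c_ff = np.where(ok, ff_profile.concentrations[i_ff], 0.0)
    c_ffa = np.where(ok, ffa_profile.concentrations[i_ffa], 0.0)
    total = c_ff + c_ffa
    keep = ok & (total > 0)
    if not keep.any():
        raise NCAError(
            f"({ff_profile.tissue}): no shared quantifiable time points"
        )
    times = shared[keep]
    adr = c_ffa[keep] / total[keep]
    return times, adr, float(adr.mean())


def disposition_for_tissue(ff_profile: ConcentrationTimeProfile,
                           ffa_profile: ConcentrationTimeProfile,
                           spec: TerminalPhaseSpec = TerminalPhaseSpec(),
                           *, auc_basis: str = "last") -> MetaboliteDisposition:
    """Compute AMR, MR and ADR for one tissue.

    ``auc_basis`` selects the AUC entering AMR/MR: ``"last"`` (AUC(0-last),
    the default, matching the common reporting convention) or ``"inf"``
    (AUC(0-inf), available only when both terminal fits are positive).
    """
    if auc_basis not in ("last", "inf"):
        raise ValueError(f"unknown AUC basis {auc_basis!r}")
    res_ff = analyze_profile(ff_profile, spec)
    res_ffa = analyze_profile(ffa_profile, spec)
    attr = "auc_0_last" if auc_basis == "last" else "auc_0_inf"
    auc_ff = getattr(res_ff, attr)
    auc_ffa = getattr(res_ffa, attr)
    if auc_ff is None or auc_ffa is None:
        raise NCAError(
            f"({ff_profile.tissue}): AUC({auc_basis}) unavailable for one analyte"
        )
    times, adr, summary = apparent_distribution_rate(ff_profile, ffa_profile)
    return MetaboliteDisposition(
        tissue=ff_profile.tissue,
        amr=apparent_metabolic_rate(auc_ffa, auc_ff),
        mr=metabolite_ratio(auc_ffa, auc_ff),
        adr_times=times,
        adr_series=adr,
        adr_summary=summary,
    )


def disposition_summary(dataset: StudyDataset,
                        spec: TerminalPhaseSpec = TerminalPhaseSpec(),
                        *, auc_basis: str = "last",
                        parent: str = ANALYTE_PARENT,
                        metabolite: str = ANALYTE_METABOLITE
                        ) -> list[MetaboliteDisposition]:
    """Disposition statistics for every tissue holding both analytes."""
    out = []
    for tissue in dataset.tissues():
        ff = dataset.get(tissue, parent)
        ffa = dataset.get(tissue, metabolite)
        if ff is None or ffa is None or ff.insufficient or ffa.insufficient:
            continue
        out.append(disposition_for_tissue(ff, ffa, spec, auc_basis=auc_basis))
    return out
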