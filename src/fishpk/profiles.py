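"""Core data model for concentration-time studies.

A study is a collection of tissue x analyte concentration-time profiles
measured after oral drug administration. Concentrations are stored in
ug/kg, times in hours post dose; a per-point below-limit-of-quantification
(BLOQ) mask records which values the assay could not quantify.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Canonical analyte labels: parent drug and its major metabolite.
ANALYTE_PARENT = "FF"
ANALYTE_METABOLITE = "FFA"

#: Fixed tissue ordering used for all tabular output.
TISSUE_ORDER = ("plasma", "skin", "muscle", "liver", "kidney", "gill", "intestine")


class ProfileError(ValueError):
    """Violation of a concentration-time profile invariant."""


class ValidationError(ValueError):
    """Dataset-level validation failure (duplicates, misaligned grids...)."""


class FormatError(ValueError):
    """Malformed input file (missing columns, non-numeric cells...)."""


def tissue_sort_key(tissue: str) -> tuple[int, str]:
    """Sort key placing the standard tissues in fixed order, others after."""
    try:
        return (TISSUE_ORDER.index(tissue), tissue)
    except ValueError:
        return (len(TISSUE_ORDER), tissue)


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One tissue x analyte concentration-time series.

    Parameters
    ----------
    tissue
        Tissue label, e.g. ``"plasma"`` or ``"kidney"``.
    analyte
        Analyte label, conventionally ``"FF"`` (parent) or ``"FFA"``
        (metabolite).
    times
        Sampling times in hours post dose, strictly increasing, >= 0.
    concentrations
        Measured concentrations in ug/kg, same length as ``times``.
        BLOQ entries may hold any placeholder value; they are ignored
        wherever the mask says so.
    loq
        Assay limit of quantification in ug/kg.
    bloq_mask
        Boolean mask, True where the measurement fell below the LOQ.
    """

    tissue: str
    analyte: str
    times: np.ndarray
    concentrations: np.ndarray
    loq: float = 0.0
    bloq_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        concs = np.asarray(self.concentrations, dtype=float)
        if self.bloq_mask is None:
            mask = np.zeros(times.shape, dtype=bool)
        else:
            mask = np.asarray(self.bloq_mask, dtype=bool)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "concentrations", concs)
        object.__setattr__(self, "bloq_mask", mask)
        if times.ndim != 1:
            raise ProfileError("times must be one-dimensional")
        if not (len(times) == len(concs) == len(mask)):
            raise ProfileError(
                f"({self.tissue}, {self.analyte}): times/concentrations/bloq_mask "
                f"lengths differ: {len(times)}/{len(concs)}/{len(mask)}"
            )
        if len(times) and times[0] < 0:
            raise ProfileError(f"({self.tissue}, {self.analyte}): negative time")
        if np.any(np.diff(times) <= 0):
            raise ProfileError(
                f"({self.tissue}, {self.analyte}): times must be strictly increasing"
            )
        if np.any(concs[~mask] < 0):
            raise ProfileError(
                f"({self.tissue}, {self.analyte}): negative quantified concentration"
            )

    def __len__(self) -> int:
        return len(self.times)

    @property
    def key(self) -> tuple[str, str]:
        return (self.tissue, self.analyte)

    @property
    def quantifiable(self) -> np.ndarray:
        """Mask of points usable in AUC/regression (not BLOQ)."""
        return ~self.bloq_mask

    @property
    def n_quantifiable(self) -> int:
        return int(self.quantifiable.sum())

    @property
    def insufficient(self) -> bool:
        """True when fewer than two quantifiable points exist.

        Such profiles are excluded from AUC and regression operations.
        """
        return self.n_quantifiable < 2

    def with_zero_origin(self) -> "ConcentrationTimeProfile":
        """Return a copy with C(0) = 0 prepended if t = 0 is absent.

        Oral dosing implies zero systemic concentration at the instant of
        administration.
        """
        if len(self.times) and self.times[0] == 0.0:
            return self
        logger.info(
            "(%s, %s): assuming concentration 0 at t=0 (oral dose)",
            self.tissue,
            self.analyte,
        )
        return replace(
            self,
            times=np.concatenate([[0.0], self.times]),
            concentrations=np.concatenate([[0.0], self.concentrations]),
            bloq_mask=np.concatenate([[False], self.bloq_mask]),
        )


@dataclass
class StudyDataset:
    """A full single-dose study: profiles keyed by (tissue, analyte).

    ``dose`` is in mg per kg body weight; internal concentration units are
    ug/kg, so dose in ug/kg is ``dose * 1000``.
    """

    profiles: dict[tuple[str, str], ConcentrationTimeProfile] = field(default_factory=dict)
    dose: float = 15.0
    route: str = "oral"
    metadata: dict = field(default_factory=dict)

    @property
    def dose_ugkg(self) -> float:
        return self.dose * 1000.0

    def add(self, profile: ConcentrationTimeProfile) -> None:
        if profile.key in self.profiles:
            raise ValidationError(f"duplicate profile for {profile.key}")
        self.profiles[profile.key] = profile

    def get(self, tissue: str, analyte: str) -> ConcentrationTimeProfile | None:
        return self.profiles.get((tissue, analyte))

    def tissues(self) -> list[str]:
        seen = {t for (t, _a) in self.profiles}
        return sorted(seen, key=tissue_sort_key)

    def analytes(self) -> list[str]:
        return sorted({a for (_t, a) in self.profiles})

    def __iter__(self):
        return iter(sorted(self.profiles.values(), key=lambda p: (tissue_sort_key(p.tissue), p.analyte)))

    def __len__(self) -> int:
        return len(self.profiles)
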