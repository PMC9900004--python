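"""Reading and writing study CSVs, parameter tables and run configuration.

Input CSV schema (comma separated, period decimal, UTF-8, header mandatory):

    tissue,analyte,time_h,conc_ugkg[,loq_ugkg]

Concentration cells may carry a ``<`` prefix (``<0.5``) to mark a value
below the limit of quantification; such points are masked BLOQ and the
numeric part is taken as the LOQ when no ``loq_ugkg`` column is present.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .profiles import (
    ConcentrationTimeProfile,
    FormatError,
    StudyDataset,
    ValidationError,
    tissue_sort_key,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("tissue", "analyte", "time_h", "conc_ugkg")

#: Row order of the wide parameter table (parameters as rows, tissues as
#: columns), mirroring the conventional layout of tissue-PK reports.
PARAMETER_ROWS = (
    "t_half",
    "T",
    "lambda",
    "Tmax",
    "Cmax",
    "AUC_0_last",
    "AUC_ratio",
    "k_el",
    "AUC_tail",
    "AUC_0_inf",
    "Ka",
    "MR",
)


def _parse_conc(cell, line_no: int):
    """Return (value, bloq, stated_loq) for a concentration cell."""
    if isinstance(cell, str):
        text = cell.strip()
        if text.startswith("<"):
            try:
                limit = float(text[1:])
            except ValueError as exc:
                raise FormatError(
                    f"line {line_no}: non-numeric BLOQ concentration {cell!r}"
                ) from exc
            return limit, True, limit
        cell = text
    try:
        value = float(cell)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"line {line_no}: non-numeric concentration {cell!r}") from exc
    return value, False, None


def read_study(path, *, dose: float = 15.0, assume_zero_origin: bool = True,
               metadata: dict | None = None) -> StudyDataset:
    """Read a tidy concentration-time CSV into a validated :class:`StudyDataset`.

    Parameters
    ----------
    path
        CSV file with columns ``tissue, analyte, time_h, conc_ugkg`` and an
        optional ``loq_ugkg`` column.
    dose
        Administered dose in mg/kg body weight.
    assume_zero_origin
        Prepend C(0) = 0 to profiles lacking a t = 0 sample (oral dosing).
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required column(s) {', '.join(missing)}")
    has_loq = "loq_ugkg" in frame.columns

    dataset = StudyDataset(dose=dose, metadata=metadata or {})
    for (tissue, analyte), group in frame.groupby(["tissue", "analyte"], sort=False):
        times, concs, bloq = [], [], []
        loq = 0.0
        for idx, row in group.iterrows():
            line_no = idx + 2  # header is line 1
            try:
                t = float(row["time_h"])
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"line {line_no}: non-numeric time {row['time_h']!r}"
                ) from exc
            value, is_bloq, stated = _parse_conc(row["conc_ugkg"], line_no)
            if has_loq and not pd.isna(row["loq_ugkg"]):
                loq = max(loq, float(row["loq_ugkg"]))
            elif stated is not None:
                loq = max(loq, stated)
            times.append(t)
            concs.append(value)
            bloq.append(is_bloq)

        order = np.argsort(times, kind="stable")
        times = np.asarray(times)[order]
        concs = np.asarray(concs)[order]
        bloq = np.asarray(bloq)[order]
        dup = np.flatnonzero(np.diff(times) == 0)
        if dup.size:
            raise ValidationError(
                f"duplicate time point ({tissue}, {analyte}, {times[dup[0]]:g})"
            )
        # values stated numerically but below the declared LOQ are masked
        # too; the pre-dose zero at t=0 is structural, not an assay reading
        below = (~bloq) & (loq > 0) & (np.asarray(concs) < loq) & (times > 0)
        if below.any():
            logger.info(
                "(%s, %s): masking %d point(s) below LOQ %g ug/kg",
                tissue, analyte, int(below.sum()), loq,
            )
            bloq = bloq | below
        profile = ConcentrationTimeProfile(
            tissue=tissue, analyte=analyte, times=times,
            concentrations=concs, loq=loq, bloq_mask=bloq,
        )
        if assume_zero_origin:
            profile = profile.with_zero_origin()
        if profile.insufficient:
            logger.info("(%s, %s): flagged insufficient (<2 quantifiable points)",
                        tissue, analyte)
        dataset.add(profile)
    return dataset


def write_study(dataset: StudyDataset, path) -> None:
    """Write a dataset back to the tidy CSV schema (lossless round trip)."""
    rows = []
    for profile in dataset:
        for t, c, b in zip(profile.times, profile.concentrations, profile.bloq_mask):
            rows.append({
                "tissue": profile.tissue,
                "analyte": profile.analyte,
                "time_h": repr(float(t)),
                "conc_ugkg": f"<{profile.loq:g}" if b else repr(float(c)),
                "loq_ugkg": repr(float(profile.loq)),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_parameter_table(results, path) -> None:
    """Write NCA results as a parameter x tissue CSV.

    Parameters appear as rows in the fixed order of :data:`PARAMETER_ROWS`;
    tissues as columns in the standard tissue order. All results must share
    an analyte. Values are written at full float precision so the table
    round-trips losslessly.
    """
    results = list(results)
    if not results:
        raise ValidationError("empty result set")
    analytes = {r.analyte for r in results}
    if len(analytes) > 1:
        raise ValidationError(f"results mix analytes: {sorted(analytes)}")

    columns = {}
    for res in sorted(results, key=lambda r: tissue_sort_key(r.tissue)):
        columns[res.tissue] = {
            "t_half": res.t_half,
            "T": res.mean_lifetime,
            "lambda": res.decay_constant,
            "Tmax": res.tmax,
            "Cmax": res.cmax,
            "AUC_0_last": res.auc_0_last,
            "AUC_ratio": res.auc_ratio,
            "k_el": res.k_el,
            "AUC_tail": res.auc_tail,
            "AUC_0_inf": res.auc_0_inf,
            "Ka": res.ka,
            "MR": res.mr,
        }
    frame = pd.DataFrame(columns, index=list(PARAMETER_ROWS), dtype=float)
    frame.index.name = "parameter"
    frame.to_csv(path, float_format="%.17g")  # lossless float round trip


def read_parameter_table(path) -> pd.DataFrame:
    """Read back a parameter table written by :func:`write_parameter_table`."""
    return pd.read_csv(path, index_col="parameter", float_precision="round_trip")


def load_config(path) -> dict:
    """Load a JSON or YAML run configuration.

    Recognised top-level sections: ``io``, ``nca``, ``simulate``,
    ``residue``. Unknown sections are preserved untouched.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        config = json.loads(text)
    else:
        config = yaml.safe_load(text)
    if not isinstance(config, dict):
        raise FormatError(f"{path.name}: configuration must be a mapping")
    return config
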