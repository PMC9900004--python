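"""End-to-end orchestration: simulate/read -> NCA -> metabolite -> residue.

`run_pipeline` produces a report bundle in an output directory:

* ``nca_FF.csv``  — parent parameter table (parameters x tissues);
* ``nca_FFA.csv`` — metabolite parameter table, including the MR row;
* ``metabolite.csv`` — AMR / ADR summary per tissue;
* ``residue.json`` — depletion regression, withdrawal times and MRL
  compliance per dose group;
* ``summary.json`` — run metadata, per-profile quality flags, errors.

A failure in one tissue/analyte is logged and recorded but never aborts
the rest of the bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .metabolite import disposition_summary
from .nca import NCAError, TerminalPhaseSpec, analyze_profile, run_nca, tissue_plasma_ratio
from .profiles import ANALYTE_METABOLITE, ANALYTE_PARENT, StudyDataset, tissue_sort_key
from .residue import (
    DEFAULT_MRL,
    ResidueError,
    ResidueSeries,
    fit_depletion,
    mrl_compliance,
    withdrawal_time,
)
from .simulate import DosingRegimen, SimulationConfig, simulate_repeated_dosing, simulate_study

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    outdir: Path = Path("fishpk-out")
    seed: int = 0
    input_csv: Path | None = None     # read this study instead of simulating
    dose: float = 15.0
    simulate: dict = field(default_factory=dict)    # SimulationConfig overrides
    nca: dict = field(default_factory=dict)         # TerminalPhaseSpec overrides
    bloq_policy: str = "exclude"
    auc_basis: str = "last"
    residue: dict = field(default_factory=dict)     # mrl, method, regimen overrides

    @classmethod
    def from_mapping(cls, mapping: dict, **overrides) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        kwargs = {k: v for k, v in mapping.items() if k in known}
        kwargs.update(overrides)
        config = cls(**kwargs)
        config.outdir = Path(config.outdir)
        if config.input_csv is not None:
            config.input_csv = Path(config.input_csv)
        return config


def _build_simulation_config(config: RunConfig) -> SimulationConfig:
    kwargs = dict(config.simulate)
    kwargs.setdefault("dose", config.dose)
    kwargs.setdefault("seed", config.seed)
    return SimulationConfig(**kwargs)


def _residue_report(config: RunConfig, sim_config: SimulationConfig) -> dict:
    opts = dict(config.residue)
    mrl = opts.pop("mrl", DEFAULT_MRL)
    method = opts.pop("method", "tolerance-95-95")
    multipliers = opts.pop("multipliers", (1, 3, 5, 10))
    regimen_base = {k: v for k, v in opts.items()
                    if k in ("dose_per_day", "n_days", "interval", "depuration_days")}
    sample_days = np.array(opts.pop("sample_days", (10.0, 20.0, 30.0, 40.0, 50.0)))

    report = {"mrl_ugkg": mrl, "method": method, "groups": {}}
    for mult in multipliers:
        group = f"{mult}x"
        try:
            regimen = DosingRegimen(multiplier=mult, **regimen_base)
            profile = simulate_repeated_dosing(
                sim_config, regimen, tissue="muscle",
                sample_times=sample_days * 24.0,
            )
            series = ResidueSeries(
                dose_group=group, analyte=ANALYTE_PARENT,
                days=profile.times / 24.0, residues=profile.concentrations,
                dosing_end_day=regimen.n_days,
            )
            fit = fit_depletion(series)
            estimate = withdrawal_time(fit, mrl, method)
            report["groups"][group] = {
                "slope_per_day": fit.slope,
                "intercept_log_ugkg": fit.intercept,
                "r_squared": fit.r_squared,
                "wt_point_days": estimate.wt_point,
                "wt_tolerance_days": estimate.wt_tolerance,
                "final_day_compliant": mrl_compliance(series, mrl),
            }
        except (ResidueError, ValueError) as exc:
            logger.error("residue stage failed for group %s: %s", group, exc)
            report["groups"][group] = {"error": str(exc)}
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns the summary dictionary (also written to ``summary.json``).
    Deterministic for a fixed config and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = TerminalPhaseSpec(**config.nca)
    errors: list[dict] = []

    if config.input_csv is not None:
        dataset = fio.read_study(config.input_csv, dose=config.dose)
        sim_config = _build_simulation_config(config)
    else:
        sim_config = _build_simulation_config(config)
        dataset = simulate_study(sim_config)
        fio.write_study(dataset, outdir / "study.csv")

    # --- NCA, isolating per-profile failures -------------------------------
    results = []
    clean = StudyDataset(dose=dataset.dose, metadata=dataset.metadata)
    for profile in dataset:
        try:
            analyze_profile(profile, spec, bloq_policy=config.bloq_policy)
            clean.add(profile)
        except Exception as exc:  # noqa: BLE001 — fault isolation by design
            logger.error("NCA failed for %s: %s", profile.key, exc)
            errors.append({"stage": "nca", "tissue": profile.tissue,
                           "analyte": profile.analyte, "error": str(exc)})
    results = run_nca(clean, spec, bloq_policy=config.bloq_policy)

    by_analyte: dict[str, list] = {}
    for res in results:
        by_analyte.setdefault(res.analyte, []).append(res)

    # attach MR to metabolite results where the parent AUC exists
    parent_auc = {r.tissue: r.auc_0_last for r in by_analyte.get(ANALYTE_PARENT, [])}
    for res in by_analyte.get(ANALYTE_METABOLITE, []):
        auc_ff = parent_auc.get(res.tissue)
        basis = res.auc_0_last if config.auc_basis == "last" else res.auc_0_inf
        if auc_ff and basis is not None:
            res.mr = basis / auc_ff

    tables = {}
    for analyte, group in by_analyte.items():
        path = outdir / f"nca_{analyte}.csv"
        fio.write_parameter_table(group, path)
        tables[analyte] = path.name  # names, not paths: keeps summaries seed-deterministic

    # --- metabolite disposition table --------------------------------------
    try:
        dispositions = disposition_summary(clean, spec, auc_basis=config.auc_basis)
    except NCAError as exc:
        logger.error("metabolite stage failed: %s", exc)
        errors.append({"stage": "metabolite", "error": str(exc)})
        dispositions = []
    if dispositions:
        frame = pd.DataFrame(
            {d.tissue: {"AMR": d.amr, "MR": d.mr, "ADR": d.adr_summary}
             for d in sorted(dispositions, key=lambda d: tissue_sort_key(d.tissue))}
        )
        frame.index.name = "parameter"
        frame.to_csv(outdir / "metabolite.csv")
        tables["metabolite"] = "metabolite.csv"

    # --- residue / withdrawal ----------------------------------------------
    residue_report = _residue_report(config, sim_config)
    (outdir / "residue.json").write_text(json.dumps(residue_report, indent=2))

    summary = {
        "seed": config.seed,
        "dose_mgkg": dataset.dose,
        "n_profiles": len(dataset),
        "tables": tables,
        "residue": residue_report,
        "flags": {f"{r.tissue}/{r.analyte}": r.flags for r in results if r.flags},
        "errors": errors,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
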