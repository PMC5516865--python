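"""File-format glue: YAML configs and the CSV dialects of each stage."""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .calibration import READOUTS, DoseTimeMatrix
from .network_model import (
    Protocol,
    ReactionNetwork,
    SimulationResult,
    ValidationError,
    build_erbb_network,
)
from .pkpd import SerumProfile
from .screen import ScreenPlate
from .tumor_growth import TumorStudy

__all__ = [
    "load_cell_config",
    "load_drug_config",
    "load_protocol",
    "result_to_frame",
    "write_trajectory_csv",
    "read_dose_time_csv",
    "write_dose_time_csv",
    "read_serum_csv",
    "write_serum_csv",
    "read_tumor_csv",
    "read_screen_csv",
]


def load_cell_config(path) -> dict:
    """Cell-line YAML: {name, EGFR, HER2, ErbB3 [receptors/cell], parameter_overrides}."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    if not isinstance(config, dict):
        raise ValidationError(f"{path}: expected a mapping")
    return config


def load_drug_config(path) -> tuple:
    """Drug YAML: {mechanism, dose_nmol_l, params: {...}} -> (mechanism, params, dose)."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    mechanism = config.get("mechanism")
    if mechanism is None:
        raise ValidationError(f"{path}: missing 'mechanism'")
    dose = float(config.get("dose_nmol_l", 0.0))
    return mechanism, dict(config.get("params") or {}), dose


def load_protocol(path) -> Protocol:
    """Protocol YAML: {equilibration_min, events: [{time_min, species, amount, mode}], readout_times}."""
    with open(path) as fh:
        config = yaml.safe_load(fh) or {}
    events = tuple(
        (float(e["time_min"]), str(e["species"]), float(e["amount"]), e.get("mode", "add"))
        for e in config.get("events", ())
    )
    return Protocol(
        float(config.get("equilibration_min", 30.0)),
        events=tuple(sorted(events)),
        readout_times=tuple(float(t) for t in config.get("readout_times", ())),
    )


def result_to_frame(result: SimulationResult) -> pd.DataFrame:
    """time_min, one column per species, one per observable."""
    df = pd.DataFrame({"time_min": result.time_grid})
    for i, name in enumerate(result.species_names):
        df[name] = result.state_matrix[i, :]
    for obs, trace in result.observable_traces.items():
        df[obs] = trace
    return df


def write_trajectory_csv(result: SimulationResult, path):
    result_to_frame(result).to_csv(path, index=False)


def write_dose_time_csv(matrices: dict, path):
    """Tidy CSV: readout, ligand, dose_nmol_l, time_min, value."""
    pd.concat([m.to_tidy() for m in matrices.values()]).to_csv(path, index=False)


def read_dose_time_csv(path) -> dict:
    """Inverse of :func:`write_dose_time_csv`; returns ligand -> DoseTimeMatrix."""
    df = pd.read_csv(path)
    out = {}
    for ligand, sub in df.groupby("ligand"):
        readouts = tuple(sorted(sub["readout"].unique(), key=list(READOUTS).index))
        doses = tuple(sorted(sub["dose_nmol_l"].unique()))
        times = tuple(sorted(sub["time_min"].unique()))
        values = np.full((len(readouts), len(doses), len(times)), np.nan)
        pivot = sub.set_index(["readout", "dose_nmol_l", "time_min"])["value"]
        for i, r in enumerate(readouts):
            for j, d in enumerate(doses):
                for k, t in enumerate(times):
                    values[i, j, k] = pivot[(r, d, t)]
        if np.isnan(values).any():
            raise ValidationError(f"{path}: ragged dose-time grid for ligand {ligand!r}")
        out[ligand] = DoseTimeMatrix(readouts, ligand, doses, times, values)
    return out


def write_serum_csv(profiles, path):
    """CSV: dose_group_ug, time_h, conc_ug_ml."""
    rows = []
    for p in profiles:
        for t, c in zip(p.times, p.concentrations):
            rows.append((p.dose_group, t, c))
    pd.DataFrame(rows, columns=["dose_group_ug", "time_h", "conc_ug_ml"]).to_csv(path, index=False)


def read_serum_csv(path):
    df = pd.read_csv(path)
    return [
        SerumProfile(sub["time_h"].to_numpy(), sub["conc_ug_ml"].to_numpy(), float(dose))
        for dose, sub in df.groupby("dose_group_ug")
    ]


def read_tumor_csv(path, control_group: str = "PBS") -> TumorStudy:
    """CSV: mouse_id, group, day, width_mm, length_mm[, volume_mm3]."""
    return TumorStudy(pd.read_csv(path), control_group=control_group)


def read_screen_csv(path):
    """CSV: cell_line, ligand, replicate, value -> list of ScreenPlate."""
    df = pd.read_csv(path)
    return [
        ScreenPlate(str(cell), sub[["ligand", "replicate", "value"]].reset_index(drop=True))
        for cell, sub in df.groupby("cell_line")
    ]


def network_from_cell_config(config: dict) -> ReactionNetwork:
    return build_erbb_network(config)
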