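"""Inhibitor dose titrations, IC50 extraction and HER2 potency scans.

The simulated experiment mirrors the bench protocol: cells equilibrate for
30 min, the inhibitor is added for a 30-min incubation, the ligand
(1 nmol/l HRG by default) stimulates for 10 min, and the readout at the
end of stimulation is normalized to the zero-drug control.  IC50s come
from a four-parameter logistic fit in log-dose, and the potency scan
repeats the titration across HER2 expression levels to compare an
ErbB3 blocker (most potent at low HER2) with a HER2-anchored bispecific
(most potent at high HER2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import drug_mechanisms as dm
from .network_model import (
    CompiledNetwork,
    Protocol,
    ReactionNetwork,
    ValidationError,
    build_erbb_network,
    observable_timeseries,
    simulate,
)

__all__ = [
    "TitrationProtocol",
    "DoseResponseCurve",
    "HillFit",
    "default_doses",
    "apply_drug",
    "simulate_dose_response",
    "fit_ic50",
    "her2_potency_scan",
    "crossover_her2",
]

MECHANISMS = {
    "erbb3_blocker": (dm.extend_with_erbb3_blocker, dm.BlockerParams, "AB"),
    "her2_bispecific": (dm.extend_with_bispecific, dm.BispecificParams, "BS"),
    "egfr_tki": (dm.extend_with_egfr_tki, dm.TKIParams, "TKI"),
}


@dataclass(frozen=True)
class TitrationProtocol:
    """Timing of the simulated titration experiment (minutes)."""

    equilibration: float = 30.0
    drug_incubation: float = 30.0
    stimulation: float = 10.0
    ligands: tuple = (("HRG", 1.0),)  # (species, nmol/l) added after incubation

    def build(self, drug_species: str, dose: float, extra_readouts=()) -> Protocol:
        t_stim = self.drug_incubation
        t_read = self.drug_incubation + self.stimulation
        events = [(0.0, drug_species, float(dose), "set")]
        events += [(t_stim, lig, amt, "add") for lig, amt in self.ligands]
        return Protocol(
            self.equilibration,
            events=tuple(events),
            readout_times=(t_read,) + tuple(extra_readouts),
        )


@dataclass
class DoseResponseCurve:
    doses: np.ndarray  # nmol/l, strictly increasing
    responses: np.ndarray  # readout normalized to zero-drug control
    readout: str

    def __post_init__(self):
        self.doses = np.asarray(self.doses, float)
        self.responses = np.asarray(self.responses, float)
        if np.any(np.diff(self.doses) <= 0):
            raise ValidationError("doses must be strictly increasing")
        if len(self.doses) != len(self.responses):
            raise ValidationError("doses and responses must have equal length")


@dataclass(frozen=True)
class HillFit:
    ic50: float
    hill_slope: float
    top: float
    bottom: float
    converged: bool


def default_doses(n: int = 11, low: float = 1e-2, high: float = 1e3) -> np.ndarray:
    """Default titration grid: log-spaced nmol/l over five decades."""
    return np.logspace(np.log10(low), np.log10(high), n)


def apply_drug(network: ReactionNetwork, mechanism: str, params=None):
    """Extend the network with a named mechanism; returns (network, species)."""
    if mechanism not in MECHANISMS:
        raise ValidationError(
            f"unknown mechanism {mechanism!r}; known: {sorted(MECHANISMS)}"
        )
    extend, params_cls, species = MECHANISMS[mechanism]
    if params is None:
        params = params_cls()
    elif isinstance(params, dict):
        params = params_cls(**params)
    return extend(network, params), species


def simulate_dose_response(
    network: ReactionNetwork,
    drug,
    doses,
    protocol: TitrationProtocol | None = None,
    readout: str = "p-Akt",
    *,
    solver_opts=None,
) -> DoseResponseCurve:
    """Titrate an inhibitor and read out the control-normalized response.

    ``drug`` is either a mechanism name (``erbb3_blocker`` /
    ``her2_bispecific`` / ``egfr_tki``), a ``(mechanism, params)`` pair,
    or, for a pre-extended network, the drug species name.
    """
    protocol = protocol or TitrationProtocol()
    doses = np.asarray(doses, float)
    if isinstance(drug, tuple):
        network, species = apply_drug(network, *drug)
    elif drug in MECHANISMS:
        network, species = apply_drug(network, drug)
    elif drug in set(network.species_names):
        species = drug
    else:
        raise ValidationError(f"unknown drug {drug!r}")

    compiled = CompiledNetwork(network)
    t_read = protocol.drug_incubation + protocol.stimulation

    def readout_at(dose):
        prot = protocol.build(species, dose)
        res = simulate(network, prot, solver_opts, compiled=compiled, output_dt=t_read)
        trace = observable_timeseries(res, readout)
        return trace[np.argmin(np.abs(res.time_grid - t_read))]

    control = readout_at(0.0)
    if control == 0:
        raise ValidationError(f"zero-drug {readout!r} is zero; cannot normalize")
    responses = np.array([readout_at(d) for d in doses]) / control
    return DoseResponseCurve(doses, responses, readout)


def _four_pl(logd, log_ic50, hill, top, bottom):
    return bottom + (top - bottom) / (1.0 + 10 ** (hill * (logd - log_ic50)))


def fit_ic50(curve: DoseResponseCurve, *, min_span: float = 0.05) -> HillFit:
    """Four-parameter logistic fit in log-dose.

    Non-convergence (flat curve, failed optimization, or an IC50 outside
    the dose range) is flagged through ``converged=False``, never raised.
    """
    if len(curve.doses) < 5:
        raise ValidationError("need at least 5 dose points for a 4PL fit")
    logd = np.log10(curve.doses)
    y = curve.responses
    span = float(np.max(y) - np.min(y))
    if span < min_span:
        return HillFit(float("nan"), float("nan"), float(np.max(y)), float(np.min(y)), False)

    half = 0.5 * (np.max(y) + np.min(y))
    below = np.nonzero(y <= half)[0]
    guess_log_ic50 = logd[below[0]] if len(below) else float(np.median(logd))
    p0 = [guess_log_ic50, 1.0, float(np.max(y)), float(np.min(y))]
    bounds = (
        [logd[0] - 2.0, 0.05, -np.inf, -np.inf],
        [logd[-1] + 2.0, 10.0, np.inf, np.inf],
    )
    try:
        popt, _ = curve_fit(_four_pl, logd, y, p0=p0, bounds=bounds, maxfev=10000)
    except (RuntimeError, ValueError):
        return HillFit(float("nan"), float("nan"), float(np.max(y)), float(np.min(y)), False)
    log_ic50, hill, top, bottom = popt
    ic50 = 10.0 ** log_ic50
    converged = bool(curve.doses[0] <= ic50 <= curve.doses[-1] and top >= bottom)
    return HillFit(float(ic50), float(hill), float(top), float(bottom), converged)


def her2_potency_scan(
    base_config: dict | None,
    drug_list,
    her2_levels,
    *,
    doses=None,
    protocol: TitrationProtocol | None = None,
    readout: str = "p-Akt",
    solver_opts=None,
) -> pd.DataFrame:
    """IC50 of each drug as a function of HER2 expression.

    For every HER2 level the network is rebuilt with that receptor
    density, the titration is re-run, and a 4PL IC50 extracted; the result
    is a tidy table (her2_receptors_per_cell, drug, ic50_nmol_l,
    hill_slope, converged).

    ``drug_list`` entries are mechanism names or (mechanism, params).
    """
    her2_levels = np.asarray(her2_levels, float)
    if her2_levels.max() / max(her2_levels.min(), 1e-300) < 100:
        raise ValidationError("her2_levels should span at least two decades")
    doses = default_doses() if doses is None else np.asarray(doses, float)
    if doses.max() / doses.min() < 1e3:
        raise ValidationError("doses should span at least three decades")

    rows = []
    for her2 in her2_levels:
        config = dict(base_config or {})
        config["HER2"] = float(her2)
        network = build_erbb_network(config)
        for drug in drug_list:
            name = drug[0] if isinstance(drug, tuple) else drug
            curve = simulate_dose_response(
                network, drug, doses, protocol, readout, solver_opts=solver_opts
            )
            fit = fit_ic50(curve)
            rows.append({
                "her2_receptors_per_cell": float(her2),
                "drug": name,
                "ic50_nmol_l": fit.ic50,
                "hill_slope": fit.hill_slope,
                "converged": fit.converged,
            })
    return pd.DataFrame(rows)


def crossover_her2(scan: pd.DataFrame, drug_a: str, drug_b: str):
    """HER2 levels where the two drugs' IC50 curves cross.

    Log-log linear interpolation between scanned grid points; returns a
    list of HER2 values (receptors/cell), one per sign change.
    """
    a = scan[scan["drug"] == drug_a].sort_values("her2_receptors_per_cell")
    b = scan[scan["drug"] == drug_b].sort_values("her2_receptors_per_cell")
    her2 = a["her2_receptors_per_cell"].to_numpy()
    if not np.array_equal(her2, b["her2_receptors_per_cell"].to_numpy()):
        raise ValidationError("drugs were scanned on different HER2 grids")
    diff = np.log10(a["ic50_nmol_l"].to_numpy()) - np.log10(b["ic50_nmol_l"].to_numpy())
    crossings = []
    for i in range(len(diff) - 1):
        d0, d1 = diff[i], diff[i + 1]
        if np.isnan(d0) or np.isnan(d1):
            continue
        if d0 == 0.0:
            crossings.append(float(her2[i]))
        elif d0 * d1 < 0:
            x0, x1 = np.log10(her2[i]), np.log10(her2[i + 1])
            crossings.append(float(10 ** (x0 - d0 * (x1 - x0) / (d1 - d0))))
    if diff[-1] == 0.0:
        crossings.append(float(her2[-1]))
    return crossings
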