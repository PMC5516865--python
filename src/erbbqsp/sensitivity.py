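"""Local sensitivity analysis of network outputs to species amounts.

The question asked here is the target-identification one: which protein,
when its cellular amount is nudged, moves the pathway output the most?
For each species carrying a non-zero amount (an initial pool, or a ligand
added during the protocol) the initial/added amount is perturbed by a
small relative step in both directions, the output time course is
re-simulated, and the fully normalized local sensitivity

    S = (1/T) * integral_0^T  [O+(t) - O-(t)] / [2 * h * O0(t) + eps]  dt

is accumulated by trapezoidal quadrature over a two-hour horizon
(``O±``: output under a ±h relative perturbation, ``O0``: nominal trace).
S is dimensionless (d ln O / d ln X averaged over the time course), so the
ranking is invariant to rescaling of either the output or the species.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .network_model import (
    Protocol,
    ReactionNetwork,
    SimulationResult,
    ValidationError,
    observable_timeseries,
    simulate,
)

__all__ = [
    "SensitivityEntry",
    "UndefinedSensitivityError",
    "integrated_sensitivity",
    "sensitivity_ranking",
]

#: integration horizon (minutes): two-hour time course
DEFAULT_HORIZON_MIN = 120.0
_EPS = 1e-12


class UndefinedSensitivityError(ValueError):
    """The nominal output is identically zero; S is not defined."""


@dataclass(frozen=True)
class SensitivityEntry:
    species: str
    ligand_condition: str
    value: float
    perturbation: float


def _perturbable_amount(network: ReactionNetwork, protocol: Protocol, species: str) -> float:
    """Total nominal amount of a species: initial pool plus event additions."""
    total = 0.0
    for s in network.species:
        if s.name == species:
            total += s.initial_amount
            break
    else:
        raise KeyError(f"unknown species {species!r}")
    for _, sp, amount, _ in protocol.events:
        if sp == species:
            total += amount
    return total


def _scaled(network: ReactionNetwork, protocol: Protocol, species: str, factor: float):
    """Scale the species' initial amount and any event amounts by ``factor``."""
    initial = {
        s.name: s.initial_amount * factor for s in network.species if s.name == species
    }
    net = network.with_initial(initial)
    events = tuple(
        (t, sp, amount * factor if sp == species else amount, mode)
        for t, sp, amount, mode in protocol.events
    )
    return net, replace(protocol, events=events)


def integrated_sensitivity(
    network: ReactionNetwork,
    protocol: Protocol,
    output: str,
    species: str,
    rel_step: float = 0.01,
    *,
    horizon: float = DEFAULT_HORIZON_MIN,
    solver_opts=None,
    _nominal: SimulationResult | None = None,
) -> SensitivityEntry:
    """Normalized time-integrated sensitivity of ``output`` to ``species``.

    Central finite difference with relative step ``rel_step`` (must lie in
    (0, 0.1]); the species must carry a non-zero nominal amount and the
    nominal output must not be identically zero.
    """
    if not 0 < rel_step <= 0.1:
        raise ValidationError(f"rel_step must be in (0, 0.1], got {rel_step}")
    if max(protocol.readout_times, default=0.0) < horizon:
        protocol = replace(
            protocol, readout_times=tuple(protocol.readout_times) + (horizon,)
        )
    if _perturbable_amount(network, protocol, species) == 0:
        raise ValidationError(f"species {species!r} has zero nominal amount")

    nominal = _nominal if _nominal is not None else simulate(network, protocol, solver_opts)
    mask = nominal.time_grid <= horizon + 1e-9
    t = nominal.time_grid[mask]
    o0 = observable_timeseries(nominal, output)[mask]
    # points where the nominal output is exactly zero are 0/0 limits (e.g.
    # the instant of stimulation); they are excluded from the quadrature
    valid = o0 > 0
    if valid.sum() < 2:
        raise UndefinedSensitivityError(f"nominal {output!r} is identically zero")
    t = t[valid]
    o0 = o0[valid]

    traces = []
    for sign in (+1.0, -1.0):
        net, prot = _scaled(network, protocol, species, 1.0 + sign * rel_step)
        res = simulate(net, prot, solver_opts)
        traces.append(observable_timeseries(res, output)[mask][valid])
    integrand = (traces[0] - traces[1]) / (2.0 * rel_step * o0 + _EPS)
    horizon_span = t[-1] - t[0]
    value = float(np.trapezoid(integrand, t) / horizon_span)
    ligand = network.metadata.get("ligand_condition", "")
    return SensitivityEntry(species, ligand, value, rel_step)


def sensitivity_ranking(
    network: ReactionNetwork,
    protocol: Protocol | None = None,
    output: str = "p-Akt",
    ligand_doses: dict | None = None,
    rel_step: float = 0.01,
    *,
    horizon: float = DEFAULT_HORIZON_MIN,
    solver_opts=None,
) -> pd.DataFrame:
    """Rank every non-zero species by |S| for each ligand condition.

    For each ligand (default: 1 nmol/l HRG and 1 nmol/l BTC, added at the
    end of a 30-min equilibration) the sensitivity of ``output`` to every
    perturbable input is computed; the table carries one row per species
    per ligand, sorted by |S| under HRG stimulation.
    """
    ligand_doses = dict(ligand_doses or {"HRG": 1.0, "BTC": 1.0})
    base_protocol = protocol or Protocol(30.0, readout_times=(horizon,))

    rows = []
    for ligand, dose in ligand_doses.items():
        events = tuple(sorted(
            list(base_protocol.events) + [(0.0, ligand, dose, "add")]
        ))
        prot = replace(base_protocol, events=events)
        nominal = simulate(network, prot, solver_opts)
        perturbable = [
            s.name for s in network.species
            if _perturbable_amount(network, prot, s.name) > 0
        ]
        for species in perturbable:
            entry = integrated_sensitivity(
                network, prot, output, species, rel_step,
                horizon=horizon, solver_opts=solver_opts, _nominal=nominal,
            )
            rows.append({
                "species": species,
                "ligand": ligand,
                "sensitivity": entry.value,
                "abs_sensitivity": abs(entry.value),
                "perturbation": rel_step,
            })

    table = pd.DataFrame(rows)
    hrg_order = (
        table[table["ligand"] == "HRG"]
        .sort_values("abs_sensitivity", ascending=False)["species"]
        .tolist()
    )
    for sp in table["species"].unique():
        if sp not in hrg_order:
            hrg_order.append(sp)
    table["species"] = pd.Categorical(table["species"], categories=hrg_order, ordered=True)
    table = table.sort_values(["species", "ligand"]).reset_index(drop=True)
    table["species"] = table["species"].astype(str)
    table["rank"] = (
        table.groupby("ligand")["abs_sensitivity"].rank(ascending=False, method="first").astype(int)
    )
    return table
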