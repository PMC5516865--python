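"""Genetic-algorithm calibration of network parameters to dose-time data.

The training data are dose-time matrices of phospho-readouts under HRG or
BTC stimulation.  Because the assays are in arbitrary units, both data and
simulations are normalized per readout to the largest signal observed
under either stimulus, and the objective is the plain sum of squared
differences over the full readout x dose x time grid.  Optimization runs
in log-parameter space with a small elitist genetic algorithm (tournament
selection, uniform crossover, Gaussian mutation) — robust to the
multi-modal, poorly scaled landscapes that kinetic models produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .network_model import (
    CompiledNetwork,
    Protocol,
    ReactionNetwork,
    ValidationError,
    observable_timeseries,
    simulate,
)

__all__ = [
    "DoseTimeMatrix",
    "GAConfig",
    "ParameterFit",
    "NormalizationError",
    "ObjectiveError",
    "DEFAULT_FREE_PARAMETERS",
    "default_stimulation_protocol",
    "normalize_signals",
    "simulate_matrix",
    "residual_objective",
    "fit_parameters_ga",
]

READOUTS = ("p-EGFR", "p-HER2", "p-ErbB3", "p-Akt")

#: default free-parameter bounds (log-uniform): ligand off-rates, the
#: phosphorylation cycle and the effective PI3K on-rate — the "key"
#: kinetics that the dose-time matrices constrain
DEFAULT_FREE_PARAMETERS = {
    "koff_hrg": (1e-3, 10.0),
    "koff_btc": (1e-3, 10.0),
    "kphos": (0.1, 100.0),
    "kdephos": (0.01, 10.0),
    "kon_pi3k_eff": (1e-7, 1e-3),
}


class NormalizationError(ValueError):
    pass


class ObjectiveError(RuntimeError):
    """A simulation failed while evaluating the objective."""


@dataclass
class DoseTimeMatrix:
    """readout x dose x time block of signals for one stimulating ligand."""

    readouts: tuple
    ligand: str
    doses: tuple  # nmol/l
    times: tuple  # minutes
    values: np.ndarray  # shape (readouts, doses, times)
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, float)
        expected = (len(self.readouts), len(self.doses), len(self.times))
        if self.values.shape != expected:
            raise ValidationError(f"values shape {self.values.shape} != {expected}")
        if np.any(self.values < 0):
            raise ValidationError("signal values must be >= 0")

    def to_tidy(self):
        import pandas as pd

        rows = []
        for i, r in enumerate(self.readouts):
            for j, d in enumerate(self.doses):
                for k, t in enumerate(self.times):
                    rows.append((r, self.ligand, d, t, self.values[i, j, k]))
        return pd.DataFrame(rows, columns=["readout", "ligand", "dose_nmol_l", "time_min", "value"])


def normalize_signals(matrix: DoseTimeMatrix, partner_matrix: DoseTimeMatrix):
    """Joint per-readout max normalization across both ligand matrices.

    Each readout is divided by its maximum over doses, times *and* both
    stimuli, so exactly one of the two matrices attains 1.0 per readout.
    Idempotent on already-normalized input.
    """
    if matrix.readouts != partner_matrix.readouts:
        raise ValidationError("matrices must share readouts")
    scales = np.maximum(
        matrix.values.max(axis=(1, 2)), partner_matrix.values.max(axis=(1, 2))
    )
    if np.any(scales <= 0):
        dead = [r for r, s in zip(matrix.readouts, scales) if s <= 0]
        raise NormalizationError(f"all-zero readout(s): {dead}")
    scaled = scales[:, None, None]
    return (
        replace(matrix, values=matrix.values / scaled, normalized=True),
        replace(partner_matrix, values=partner_matrix.values / scaled, normalized=True),
    )


def default_stimulation_protocol(ligand: str, dose: float, times) -> Protocol:
    """Equilibrate 30 min, add the ligand, read out at the matrix times."""
    return Protocol(
        30.0,
        events=((0.0, ligand, float(dose), "add"),),
        readout_times=tuple(float(t) for t in times),
    )


def simulate_matrix(
    network: ReactionNetwork,
    ligand: str,
    doses,
    times,
    readouts=READOUTS,
    *,
    protocol_map=None,
    compiled: CompiledNetwork | None = None,
    solver_opts=None,
) -> DoseTimeMatrix:
    """Simulate the raw (un-normalized) dose-time block for one ligand."""
    protocol_map = protocol_map or default_stimulation_protocol
    compiled = compiled or CompiledNetwork(network)
    times = tuple(float(t) for t in times)
    values = np.empty((len(readouts), len(doses), len(times)))
    for j, dose in enumerate(doses):
        prot = protocol_map(ligand, dose, times)
        try:
            res = simulate(network, prot, solver_opts, compiled=compiled,
                           output_dt=max(times) or 1.0)
        except Exception as err:
            raise ObjectiveError(
                f"simulation failed at ligand={ligand} dose={dose}: {err}"
            ) from err
        idx = [int(np.argmin(np.abs(res.time_grid - t))) for t in times]
        for i, r in enumerate(readouts):
            values[i, j, :] = observable_timeseries(res, r)[idx]
    return DoseTimeMatrix(tuple(readouts), ligand, tuple(doses), times, values)


def residual_objective(
    network: ReactionNetwork,
    data: dict,
    protocol_map=None,
    *,
    solver_opts=None,
) -> float:
    """Sum of squared residuals between normalized simulation and data.

    ``data`` maps ligand -> normalized DoseTimeMatrix (both stimuli
    required so the joint-max normalization applied to the data can be
    applied identically to the simulations).
    """
    ligands = sorted(data)
    if len(ligands) != 2:
        raise ValidationError("need exactly two ligand matrices (joint normalization)")
    for m in data.values():
        if not m.normalized:
            raise ValidationError("data matrices must be normalized first")
    compiled = CompiledNetwork(network)
    sims = {
        lig: simulate_matrix(
            network, lig, data[lig].doses, data[lig].times, data[lig].readouts,
            protocol_map=protocol_map, compiled=compiled, solver_opts=solver_opts,
        )
        for lig in ligands
    }
    sim_a, sim_b = normalize_signals(sims[ligands[0]], sims[ligands[1]])
    sse = 0.0
    for sim, lig in ((sim_a, ligands[0]), (sim_b, ligands[1])):
        sse += float(np.sum((sim.values - data[lig].values) ** 2))
    return sse


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 40
    generations: int = 50
    crossover_rate: float = 0.7
    mutation_rate: float = 0.2
    mutation_sigma: float = 0.15  # log10 units
    tournament_size: int = 3
    parameter_bounds: dict = field(default_factory=lambda: dict(DEFAULT_FREE_PARAMETERS))
    seed: int = 0

    def __post_init__(self):
        if not self.parameter_bounds:
            raise ValidationError("parameter_bounds must not be empty")
        for name, (lo, hi) in self.parameter_bounds.items():
            if not 0 < lo < hi:
                raise ValidationError(f"bounds for {name!r} must satisfy 0 < lo < hi")
        for rate in (self.crossover_rate, self.mutation_rate):
            if not 0 <= rate <= 1:
                raise ValidationError("rates must lie in [0, 1]")


@dataclass
class ParameterFit:
    best_parameters: dict  # name -> value
    objective_value: float
    convergence_trace: np.ndarray  # best objective per generation
    seed: int


def fit_parameters_ga(
    network: ReactionNetwork,
    data: dict,
    ga_config: GAConfig | None = None,
    *,
    protocol_map=None,
    solver_opts=None,
) -> ParameterFit:
    """Elitist GA in log-parameter space minimizing :func:`residual_objective`.

    Log-uniform initialization inside the bounds, tournament selection,
    uniform crossover, per-gene Gaussian mutation (clipped to bounds) and
    single-individual elitism — which makes the best-so-far trace monotone
    non-increasing.  Fully reproducible from ``ga_config.seed``.
    """
    cfg = ga_config or GAConfig()
    names = sorted(cfg.parameter_bounds)
    lo = np.log10([cfg.parameter_bounds[n][0] for n in names])
    hi = np.log10([cfg.parameter_bounds[n][1] for n in names])
    rng = np.random.default_rng(cfg.seed)

    def evaluate(genome):
        overrides = {n: 10.0 ** g for n, g in zip(names, genome)}
        return residual_objective(
            network.with_parameters(overrides), data,
            protocol_map=protocol_map, solver_opts=solver_opts,
        )

    pop = rng.uniform(lo, hi, size=(cfg.population_size, len(names)))
    fitness = np.array([evaluate(g) for g in pop])
    trace = []
    for _ in range(cfg.generations):
        best_i = int(np.argmin(fitness))
        trace.append(float(fitness[best_i]))
        elite, elite_fit = pop[best_i].copy(), fitness[best_i]

        def tournament():
            idx = rng.integers(0, cfg.population_size, cfg.tournament_size)
            return pop[idx[np.argmin(fitness[idx])]]

        children = [elite]
        while len(children) < cfg.population_size:
            pa, pb = tournament(), tournament()
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(len(names)) < 0.5
                child = np.where(mask, pa, pb)
            else:
                child = pa.copy()
            mutate = rng.random(len(names)) < cfg.mutation_rate
            child = child + mutate * rng.normal(0.0, cfg.mutation_sigma, len(names))
            children.append(np.clip(child, lo, hi))
        pop = np.array(children)
        fitness = np.array([evaluate(g) for g in pop])
        # elitism: the elite re-enters unmutated at slot 0
        fitness[0] = elite_fit
        pop[0] = elite

    best_i = int(np.argmin(fitness))
    trace.append(float(fitness[best_i]))
    best = {n: float(10.0 ** g) for n, g in zip(names, pop[best_i])}
    return ParameterFit(best, float(fitness[best_i]), np.array(trace), cfg.seed)
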