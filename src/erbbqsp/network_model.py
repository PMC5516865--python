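"""Mass-action ODE model of the ErbB receptor network.

The model captures ligand-driven signaling to Akt in cells co-expressing
EGFR, HER2 and ErbB3 (ErbB4 is excluded): heregulin (HRG) binds ErbB3,
betacellulin (BTC) binds EGFR, and ligand-bound receptors heterodimerize.
Because ErbB3 is kinase-impaired, it is phosphorylated only in trans by a
kinase-active partner (EGFR or HER2); BTC-bound EGFR is routed to ErbB3
heterodimers, which is the only path from BTC to phospho-ErbB3.  Phospho
dimers recruit PI3K, PI3K-bound complexes activate Akt, and active dimers
internalize, recycle or degrade.

Unit conventions
----------------
* extracellular species: nmol/l
* membrane / endosome / cytosol species: molecules per cell
* unimolecular rate constants: 1/min
* bimolecular rate constants: 1/(nmol/l)/min when one partner is soluble,
  1/(molecules/cell)/min for membrane-membrane encounters

Internally every amount is converted to molecules per cell using the
extracellular volume per cell, so that mass conservation is exact by
construction; results are converted back on output.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "AVOGADRO",
    "PERICELLULAR_VOLUME_L",
    "EXTRACELLULAR_VOLUME_L",
    "SpeciesDef",
    "Reaction",
    "ParameterSet",
    "ReactionNetwork",
    "Protocol",
    "SimulationResult",
    "ConfigurationError",
    "ValidationError",
    "IntegrationError",
    "receptors_to_concentration",
    "default_parameters",
    "build_erbb_network",
    "simulate",
    "steady_state",
    "observable_timeseries",
    "network_to_sbml",
    "network_from_sbml",
]

AVOGADRO = 6.02214076e23
#: volume of the pericellular shell used to express surface densities as
#: local concentrations (receptors_to_concentration unit bridge)
PERICELLULAR_VOLUME_L = 1e-12
#: volume of medium per cell; sets the size of the soluble ligand/drug
#: reservoir (and hence how much a bound ligand depletes the medium)
EXTRACELLULAR_VOLUME_L = 1e-9

COMPARTMENTS = ("extracellular", "membrane", "endosome", "cytosol")


class ConfigurationError(ValueError):
    """Unknown parameter override or inconsistent model configuration."""


class ValidationError(ValueError):
    """Invalid species amount, protocol or reaction definition."""


class IntegrationError(RuntimeError):
    """The ODE solver failed; carries the solver diagnostic."""


def receptors_to_concentration(count: float, volume: float = PERICELLULAR_VOLUME_L) -> float:
    """Convert a surface density (receptors/cell) to nmol/l.

    ``count / (N_A * volume)`` expressed in nmol/l.  The default volume is
    the pericellular shell (1e-12 l/cell), the convention used to compare
    receptor densities with ligand doses.
    """
    if volume <= 0:
        raise ValidationError(f"volume must be positive, got {volume}")
    if count < 0:
        raise ValidationError(f"receptor count must be >= 0, got {count}")
    return count / (AVOGADRO * volume) * 1e9


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SpeciesDef:
    name: str
    compartment: str
    initial_amount: float = 0.0
    tags: frozenset = frozenset()

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(f"unknown compartment {self.compartment!r}")
        if self.initial_amount < 0:
            raise ValidationError(
                f"initial amount of {self.name} must be >= 0, got {self.initial_amount}"
            )


@dataclass(frozen=True)
class Reaction:
    """One (at most bimolecular) mass-action reaction.

    ``kf`` / ``kr`` are names resolved in the network's ParameterSet; a
    reaction is irreversible when ``kr`` is None.
    """

    reactants: tuple  # ((species, stoich), ...)
    products: tuple
    kf: str
    kr: str | None = None
    label: str = ""

    def __post_init__(self):
        for side in (self.reactants, self.products):
            for _, s in side:
                if not (isinstance(s, int) and s > 0):
                    raise ValidationError(f"stoichiometry must be a positive int, got {s}")
        if sum(s for _, s in self.reactants) > 2:
            raise ValidationError(f"reaction {self.label!r} is more than bimolecular")
        if self.kr is not None and sum(s for _, s in self.products) > 2:
            raise ValidationError(f"reversible reaction {self.label!r} has >bimolecular reverse")


class ParameterSet(Mapping):
    """Named rate constants with units and provenance notes."""

    def __init__(self, entries: dict | None = None):
        # name -> (value, unit, note)
        self._entries: dict[str, tuple[float, str, str]] = {}
        if entries:
            for name, (value, unit, note) in entries.items():
                self.set(name, value, unit, note)

    def set(self, name: str, value: float, unit: str, note: str = ""):
        if value < 0:
            raise ValidationError(f"parameter {name} must be >= 0, got {value}")
        self._entries[name] = (float(value), unit, note)

    def __getitem__(self, name: str) -> float:
        return self._entries[name][0]

    def unit(self, name: str) -> str:
        return self._entries[name][1]

    def note(self, name: str) -> str:
        return self._entries[name][2]

    def __iter__(self):
        return iter(self._entries)

    def __len__(self):
        return len(self._entries)

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self._entries))

    def updated(self, overrides: Mapping) -> "ParameterSet":
        new = self.copy()
        for name, value in overrides.items():
            if name not in new._entries:
                raise ConfigurationError(f"unknown parameter {name!r}")
            _, unit, note = new._entries[name]
            new.set(name, value, unit, note)
        return new


@dataclass
class Protocol:
    """Two-phase schedule: equilibration, then timed ligand/drug events.

    Event times and readout times are minutes after the end of the
    equilibration phase.  ``mode`` is ``"set"`` (replace the amount) or
    ``"add"`` (increment it).
    """

    equilibration_duration: float = 30.0
    events: tuple = ()  # (time_min, species, amount, mode)
    readout_times: tuple = ()

    def __post_init__(self):
        if self.equilibration_duration < 0:
            raise ValidationError("equilibration_duration must be >= 0")
        times = [e[0] for e in self.events]
        if any(t < 0 for t in times):
            raise ValidationError("event times must be >= 0")
        if list(times) != sorted(times):
            raise ValidationError("events must be sorted by time")
        for e in self.events:
            if e[3] not in ("set", "add"):
                raise ValidationError(f"unknown event mode {e[3]!r}")
        if any(t < 0 for t in self.readout_times):
            raise ValidationError("readout times must be >= 0")


@dataclass
class SimulationResult:
    time_grid: np.ndarray  # minutes, 0 = end of equilibration
    state_matrix: np.ndarray  # species x time, native units
    species_names: list
    observable_traces: dict

    def state_at(self, t: float) -> np.ndarray:
        i = int(np.argmin(np.abs(self.time_grid - t)))
        return self.state_matrix[:, i]


@dataclass
class ReactionNetwork:
    species: list
    reactions: list
    parameters: ParameterSet
    observables: dict  # name -> {species: weight}
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValidationError("species names must be unique")
        declared = set(names)
        for r in self.reactions:
            for side in (r.reactants, r.products):
                for sp, _ in side:
                    if sp not in declared:
                        raise ValidationError(f"reaction {r.label!r} references unknown species {sp!r}")
            if r.kf not in self.parameters:
                raise ConfigurationError(f"reaction {r.label!r}: unknown rate constant {r.kf!r}")
            if r.kr is not None and r.kr not in self.parameters:
                raise ConfigurationError(f"reaction {r.label!r}: unknown rate constant {r.kr!r}")
        for obs, weights in self.observables.items():
            for sp in weights:
                if sp not in declared:
                    raise ValidationError(f"observable {obs!r} references unknown species {sp!r}")

    # convenience -----------------------------------------------------
    @property
    def species_names(self):
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        try:
            return self.species_names.index(name)
        except ValueError:
            raise KeyError(f"unknown species {name!r}") from None

    def with_parameters(self, overrides: Mapping) -> "ReactionNetwork":
        return ReactionNetwork(
            species=list(self.species),
            reactions=list(self.reactions),
            parameters=self.parameters.updated(overrides),
            observables={k: dict(v) for k, v in self.observables.items()},
            metadata=dict(self.metadata),
        )

    def with_initial(self, amounts: Mapping) -> "ReactionNetwork":
        new_species = []
        amounts = dict(amounts)
        for s in self.species:
            if s.name in amounts:
                new_species.append(replace(s, initial_amount=float(amounts.pop(s.name))))
            else:
                new_species.append(s)
        if amounts:
            raise ValidationError(f"unknown species in initial amounts: {sorted(amounts)}")
        return ReactionNetwork(
            species=new_species,
            reactions=list(self.reactions),
            parameters=self.parameters,
            observables={k: dict(v) for k, v in self.observables.items()},
            metadata=dict(self.metadata),
        )


# --------------------------------------------------------------------------
# default parameter set
# --------------------------------------------------------------------------

_PER_NM_MIN = "1/(nmol/l)/min"
_PER_MOLEC_MIN = "1/(molec/cell)/min"
_PER_MIN = "1/min"


def default_parameters() -> ParameterSet:
    """Documented default rate constants.

    The printed record of this model contains no numeric rate table, so the
    defaults below are order-of-magnitude literature values for receptor
    tyrosine kinase systems (ligand kon ~1e6 /M/s, sub- to low-nanomolar
    ligand Kd, minutes-scale dimerization, phosphatase turnover ~1/min,
    trafficking on the tens-of-minutes scale), chosen once so that the
    default cell line signals in the qualitatively documented regime:
    ErbB3 is the scarce, limiting node, ligand-induced dimerization is
    strongly forward-driven, phospho-ErbB3 is PI3K-saturated and Akt
    activation runs near enzymatic saturation.  Every value can be
    overridden through ``build_erbb_network(parameter_overrides=...)``.
    """
    p = ParameterSet()
    # ligand capture (1e6 /M/s = 0.06 /(nmol/l)/min)
    p.set("kon_hrg", 0.06, _PER_NM_MIN, "HRG-ErbB3 association, ~1e6 /M/s")
    p.set("koff_hrg", 0.06, _PER_MIN, "HRG-ErbB3 dissociation, Kd ~1 nmol/l")
    p.set("kon_btc", 0.06, _PER_NM_MIN, "BTC-EGFR association, ~1e6 /M/s")
    p.set("koff_btc", 0.12, _PER_MIN, "BTC-EGFR dissociation, Kd ~2 nmol/l")
    # dimerization
    p.set("kon_dim_lig", 4e-6, _PER_MOLEC_MIN, "ligand-driven dimerization (strongly forward at ~1e5 partners)")
    p.set("koff_dim_lig", 0.1, _PER_MIN, "ligand-driven dimer dissociation")
    p.set("kon_dim_const", 1e-8, _PER_MOLEC_MIN, "constitutive (ligand-free) dimerization, weak")
    p.set("koff_dim_const", 0.1, _PER_MIN, "constitutive dimer dissociation")
    # phosphorylation cycle
    p.set("kphos", 5.0, _PER_MIN, "trans-phosphorylation inside kinase-active dimers")
    p.set("kdephos", 1.0, _PER_MIN, "phosphatase turnover")
    p.set("kdephos_complex", 1.0, _PER_MIN,
          "phosphatase turnover on PI3K-occupied phospho-dimers")
    # trafficking
    p.set("kint", 0.05, _PER_MIN, "internalization of active (phospho) dimers")
    p.set("krec", 0.05, _PER_MIN, "recycling of internalized receptors to the membrane")
    p.set("kdeg", 0.02, _PER_MIN, "lysosomal degradation of internalized dimers")
    # PI3K recruitment (multiplicity: ErbB3 carries six PI3K docking sites)
    p.set("kon_pi3k", 1e-5, _PER_MOLEC_MIN, "PI3K binding to phospho-ErbB3 (per site)")
    p.set("koff_pi3k", 0.1, _PER_MIN, "PI3K dissociation")
    p.set("pi3k_sites", 6.0, "dimensionless", "PI3K docking-site multiplicity on phospho-ErbB3")
    # Akt activation (enzymatic: complex binds Akt, converts, releases)
    p.set("kon_akt", 1e-4, _PER_MOLEC_MIN, "Akt recruitment to PI3K-bound complexes")
    p.set("koff_akt", 1.0, _PER_MIN, "Akt release without conversion")
    p.set("kcat_akt", 10.0, _PER_MIN, "Akt phosphorylation turnover")
    p.set("kdeact_akt", 0.3, _PER_MIN, "p-Akt dephosphorylation")
    return p


#: default cell-line receptor densities (receptors/cell) and cytosolic pools
DEFAULT_DENSITIES = {
    "EGFR": 1e5,
    "HER2": 2e5,
    "ErbB3": 2e4,
    "PI3K": 1e5,
    "Akt": 1e6,
}


# --------------------------------------------------------------------------
# network construction
# --------------------------------------------------------------------------

class NetworkBuilder:
    """Incremental constructor used by build_erbb_network and the drug
    extension functions; tracks receptor copy counts per species so that
    observables and conservation checks can be derived mechanically."""

    def __init__(self, parameters: ParameterSet):
        self.parameters = parameters
        self.species: dict[str, SpeciesDef] = {}
        self.reactions: list[Reaction] = []
        self.receptor_content: dict[str, dict] = {}  # species -> {receptor: copies}
        self.phospho: set[str] = set()
        self.observables: dict[str, dict] = {}
        self.metadata: dict = {}

    def add_species(self, name, compartment, initial=0.0, tags=(), receptors=None, phospho=False):
        if name in self.species:
            raise ValidationError(f"duplicate species {name!r}")
        self.species[name] = SpeciesDef(name, compartment, initial, frozenset(tags))
        self.receptor_content[name] = dict(receptors or {})
        if phospho:
            self.phospho.add(name)
        return name

    def add_reaction(self, reactants, products, kf, kr=None, label=""):
        self.reactions.append(Reaction(tuple(reactants), tuple(products), kf, kr, label))

    def build(self) -> ReactionNetwork:
        # phospho observables: one count per phosphorylated receptor copy
        for receptor, obs in (("EGFR", "p-EGFR"), ("HER2", "p-HER2"), ("ErbB3", "p-ErbB3")):
            weights = {}
            for name in self.phospho:
                copies = self.receptor_content[name].get(receptor, 0)
                if copies:
                    weights[name] = float(copies)
            self.observables[obs] = weights
        self.observables["p-Akt"] = {"pAkt": 1.0}
        total = {}
        for name, content in self.receptor_content.items():
            if content.get("ErbB3", 0):
                total[name] = float(content["ErbB3"])
        self.observables["total-ErbB3"] = total
        self.metadata["receptor_content"] = {
            n: dict(c) for n, c in self.receptor_content.items() if c
        }
        self.metadata["phospho"] = sorted(self.phospho)
        return ReactionNetwork(
            species=list(self.species.values()),
            reactions=list(self.reactions),
            parameters=self.parameters,
            observables=self.observables,
            metadata=self.metadata,
        )


def build_erbb_network(
    config: Mapping | None = None,
    *,
    parameter_overrides: Mapping | None = None,
    btc_erbb3_route: bool = True,
    btc_egfr_homodimer: bool = False,
    btc_egfr_her2: bool = False,
) -> ReactionNetwork:
    """Assemble the default HRG/BTC -> EGFR/HER2/ErbB3 -> PI3K/Akt network.

    Parameters
    ----------
    config
        Mapping with receptor densities in receptors/cell (keys ``EGFR``,
        ``HER2``, ``ErbB3``, optionally ``PI3K``, ``Akt``) and optionally
        ``parameter_overrides``; missing keys fall back to
        :data:`DEFAULT_DENSITIES`.
    btc_erbb3_route
        Keep the BTC:EGFR -> ErbB3 heterodimerization route (the only path
        from BTC to phospho-ErbB3).  Enabled by default.
    btc_egfr_homodimer, btc_egfr_her2
        Optional additional fates for BTC-bound EGFR, disabled by default
        (BTC-bound EGFR is routed to ErbB3).
    """
    config = dict(config or {})
    overrides = dict(parameter_overrides or {})
    overrides.update(config.pop("parameter_overrides", {}) or {})
    config.pop("name", None)
    densities = dict(DEFAULT_DENSITIES)
    for key, value in config.items():
        if key not in densities:
            raise ConfigurationError(f"unknown config entry {key!r}")
        if value < 0:
            raise ValidationError(f"density {key} must be >= 0, got {value}")
        densities[key] = float(value)

    params = default_parameters().updated(overrides)
    b = NetworkBuilder(params)

    # --- species ------------------------------------------------------
    b.add_species("HRG", "extracellular", 0.0, tags=("ligand",))
    b.add_species("BTC", "extracellular", 0.0, tags=("ligand",))
    for r in ("EGFR", "HER2", "ErbB3"):
        b.add_species(r, "membrane", densities[r], tags=("receptor",), receptors={r: 1})
    b.add_species("HRG:ErbB3", "membrane", tags=("receptor",), receptors={"ErbB3": 1})
    b.add_species("BTC:EGFR", "membrane", tags=("receptor",), receptors={"EGFR": 1})
    b.add_species("PI3K", "cytosol", densities["PI3K"], tags=("adaptor",))
    b.add_species("Akt", "cytosol", densities["Akt"], tags=("adaptor",))
    b.add_species("pAkt", "cytosol", tags=("adaptor", "phospho"))

    # dimers: (name, {receptor copies}) — ErbB3:ErbB3 deliberately absent
    constitutive = [
        ("EGFR:EGFR", {"EGFR": 2}, ("EGFR", "EGFR")),
        ("EGFR:HER2", {"EGFR": 1, "HER2": 1}, ("EGFR", "HER2")),
        ("EGFR:ErbB3", {"EGFR": 1, "ErbB3": 1}, ("EGFR", "ErbB3")),
        ("HER2:HER2", {"HER2": 2}, ("HER2", "HER2")),
        ("HER2:ErbB3", {"HER2": 1, "ErbB3": 1}, ("HER2", "ErbB3")),
    ]
    ligand_dimers = [
        ("HRG:ErbB3:EGFR", {"EGFR": 1, "ErbB3": 1}, ("HRG:ErbB3", "EGFR")),
        ("HRG:ErbB3:HER2", {"HER2": 1, "ErbB3": 1}, ("HRG:ErbB3", "HER2")),
    ]
    if btc_erbb3_route:
        ligand_dimers.append(("BTC:EGFR:ErbB3", {"EGFR": 1, "ErbB3": 1}, ("BTC:EGFR", "ErbB3")))
    if btc_egfr_homodimer:
        ligand_dimers.append(("BTC:EGFR:EGFR", {"EGFR": 2}, ("BTC:EGFR", "EGFR")))
    if btc_egfr_her2:
        ligand_dimers.append(("BTC:EGFR:HER2", {"EGFR": 1, "HER2": 1}, ("BTC:EGFR", "HER2")))

    all_dimers = []
    for name, content, pair in constitutive + ligand_dimers:
        b.add_species(name, "membrane", tags=("dimer",), receptors=content)
        b.add_species("p:" + name, "membrane", tags=("dimer", "phospho"), receptors=content, phospho=True)
        b.add_species("p:" + name + "@endo", "endosome", tags=("dimer", "phospho"),
                      receptors=content, phospho=True)
        all_dimers.append((name, content, pair))

    erbb3_dimers = [d for d in all_dimers if d[1].get("ErbB3")]
    for name, content, _ in erbb3_dimers:
        b.add_species("p:" + name + ":PI3K", "membrane", tags=("dimer", "phospho", "adaptor"),
                      receptors=content, phospho=True)
        b.add_species("p:" + name + ":PI3K:Akt", "membrane", tags=("dimer", "phospho", "adaptor"),
                      receptors=content, phospho=True)

    # --- reactions ----------------------------------------------------
    b.add_reaction([("HRG", 1), ("ErbB3", 1)], [("HRG:ErbB3", 1)],
                   "kon_hrg", "koff_hrg", "HRG binds ErbB3")
    b.add_reaction([("BTC", 1), ("EGFR", 1)], [("BTC:EGFR", 1)],
                   "kon_btc", "koff_btc", "BTC binds EGFR")

    for name, _, (a, bb) in constitutive:
        if a == bb:
            reactants = [(a, 2)]
        else:
            reactants = [(a, 1), (bb, 1)]
        b.add_reaction(reactants, [(name, 1)], "kon_dim_const", "koff_dim_const",
                       f"constitutive dimerization {name}")
    for name, _, (a, bb) in ligand_dimers:
        b.add_reaction([(a, 1), (bb, 1)], [(name, 1)], "kon_dim_lig", "koff_dim_lig",
                       f"ligand-induced dimerization {name}")

    for name, content, _ in all_dimers:
        # every default dimer contains a kinase-active partner (EGFR or HER2)
        b.add_reaction([(name, 1)], [("p:" + name, 1)], "kphos", None, f"phosphorylation {name}")
        b.add_reaction([("p:" + name, 1)], [(name, 1)], "kdephos", None, f"dephosphorylation {name}")
        b.add_reaction([("p:" + name, 1)], [("p:" + name + "@endo", 1)], "kint", None,
                       f"internalization {name}")
        # recycling returns the receptors to the membrane; ligand is lost
        recycled: dict[str, int] = {}
        for receptor, copies in content.items():
            recycled[receptor] = recycled.get(receptor, 0) + copies
        b.add_reaction([("p:" + name + "@endo", 1)], [(r, c) for r, c in recycled.items()],
                       "krec", None, f"recycling {name}")
        b.add_reaction([("p:" + name + "@endo", 1)], [], "kdeg", None, f"degradation {name}")

    for name, _, _ in erbb3_dimers:
        b.add_reaction([("p:" + name, 1), ("PI3K", 1)], [("p:" + name + ":PI3K", 1)],
                       "kon_pi3k_eff", "koff_pi3k", f"PI3K recruitment {name}")
        b.add_reaction([("p:" + name + ":PI3K", 1), ("Akt", 1)],
                       [("p:" + name + ":PI3K:Akt", 1)],
                       "kon_akt", "koff_akt", f"Akt recruitment {name}")
        b.add_reaction([("p:" + name + ":PI3K:Akt", 1)],
                       [("p:" + name + ":PI3K", 1), ("pAkt", 1)],
                       "kcat_akt", None, f"Akt activation {name}")
        # adaptor binding neither shields the dimer from the phosphatase
        # nor from internalization: both paths eject the bound adaptors
        b.add_reaction([("p:" + name + ":PI3K", 1)], [(name, 1), ("PI3K", 1)],
                       "kdephos_complex", None, f"dephosphorylation {name}:PI3K")
        b.add_reaction([("p:" + name + ":PI3K:Akt", 1)],
                       [(name, 1), ("PI3K", 1), ("Akt", 1)],
                       "kdephos_complex", None, f"dephosphorylation {name}:PI3K:Akt")
        b.add_reaction([("p:" + name + ":PI3K", 1)],
                       [("p:" + name + "@endo", 1), ("PI3K", 1)],
                       "kint", None, f"internalization {name}:PI3K")
        b.add_reaction([("p:" + name + ":PI3K:Akt", 1)],
                       [("p:" + name + "@endo", 1), ("PI3K", 1), ("Akt", 1)],
                       "kint", None, f"internalization {name}:PI3K:Akt")
    b.add_reaction([("pAkt", 1)], [("Akt", 1)], "kdeact_akt", None, "p-Akt dephosphorylation")

    # derived effective PI3K on-rate = per-site kon x site multiplicity
    params.set("kon_pi3k_eff", params["kon_pi3k"] * params["pi3k_sites"],
               _PER_MOLEC_MIN, "kon_pi3k x pi3k_sites (derived)")

    b.metadata.update(
        densities=densities,
        btc_erbb3_route=btc_erbb3_route,
        btc_egfr_homodimer=btc_egfr_homodimer,
        btc_egfr_her2=btc_egfr_her2,
    )
    return b.build()


# --------------------------------------------------------------------------
# compilation and integration
# --------------------------------------------------------------------------

class CompiledNetwork:
    """Index-based representation of a ReactionNetwork for fast ODE
    evaluation.  State is in molecules/cell for every compartment."""

    def __init__(self, network: ReactionNetwork, extracellular_volume_l: float = EXTRACELLULAR_VOLUME_L):
        self.network = network
        self.names = network.species_names
        self.index = {n: i for i, n in enumerate(self.names)}
        n = len(self.names)
        self.n_species = n
        # nmol/l per molecule for extracellular species
        self.conv = 1e9 / (AVOGADRO * extracellular_volume_l)
        self.is_extracellular = np.array(
            [s.compartment == "extracellular" for s in network.species]
        )

        params = network.parameters
        nr = len(network.reactions)
        S = np.zeros((n, nr))
        fa = np.full(nr, n, dtype=np.intp)  # dummy slot n holds 1.0
        fb = np.full(nr, n, dtype=np.intp)
        ra = np.full(nr, n, dtype=np.intp)
        rb = np.full(nr, n, dtype=np.intp)
        kf = np.zeros(nr)
        kr = np.zeros(nr)

        def _molecular_rate(kname):
            """Convert a rate constant to molecules/cell units."""
            value = params[kname]
            unit = params.unit(kname)
            if unit == _PER_NM_MIN:
                return value * self.conv
            if unit in (_PER_MOLEC_MIN, _PER_MIN):
                return value
            raise ConfigurationError(f"parameter {kname!r} has non-rate unit {unit!r}")

        for j, rxn in enumerate(network.reactions):
            slots = []
            for sp, st in rxn.reactants:
                slots.extend([self.index[sp]] * st)
            if len(slots) > 2:
                raise ValidationError("at most bimolecular reactions supported")
            if len(slots) >= 1:
                fa[j] = slots[0]
            if len(slots) == 2:
                fb[j] = slots[1]
            kf[j] = _molecular_rate(rxn.kf)
            for sp, st in rxn.reactants:
                S[self.index[sp], j] -= st
            for sp, st in rxn.products:
                S[self.index[sp], j] += st
            if rxn.kr is not None:
                pslots = []
                for sp, st in rxn.products:
                    pslots.extend([self.index[sp]] * st)
                if len(pslots) >= 1:
                    ra[j] = pslots[0]
                if len(pslots) == 2:
                    rb[j] = pslots[1]
                kr[j] = _molecular_rate(rxn.kr)

        self.S = S
        self.fa, self.fb, self.ra, self.rb = fa, fb, ra, rb
        self.kf, self.kr = kf, kr
        self.has_rev = kr > 0
        self._jac_buf = np.zeros((nr, n + 1))

    def initial_state(self) -> np.ndarray:
        y = np.zeros(self.n_species)
        for i, s in enumerate(self.network.species):
            y[i] = self.to_molecules(i, s.initial_amount)
        return y

    def to_molecules(self, i: int, amount: float) -> float:
        return amount / self.conv if self.is_extracellular[i] else amount

    def to_native(self, y: np.ndarray) -> np.ndarray:
        out = np.array(y, dtype=float, copy=True)
        if out.ndim == 1:
            out[self.is_extracellular] *= self.conv
        else:
            out[self.is_extracellular, :] *= self.conv
        return out

    def rhs(self, t, y):
        ye = np.append(y, 1.0)
        v = self.kf * ye[self.fa] * ye[self.fb] - self.kr * ye[self.ra] * ye[self.rb]
        return self.S @ v

    def jac(self, t, y):
        ye = np.append(y, 1.0)
        nr = len(self.kf)
        dv = self._jac_buf
        dv[:] = 0.0
        idx = np.arange(nr)
        np.add.at(dv, (idx, self.fa), self.kf * ye[self.fb])
        np.add.at(dv, (idx, self.fb), self.kf * ye[self.fa])
        np.add.at(dv, (idx, self.ra), -self.kr * ye[self.rb])
        np.add.at(dv, (idx, self.rb), -self.kr * ye[self.ra])
        return self.S @ dv[:, :-1]


DEFAULT_SOLVER_OPTS = {
    "method": "LSODA",
    "rtol": 1e-6,
    "atol": 1e-8,
}


def _integrate(compiled: CompiledNetwork, y0, t_span, t_eval, solver_opts):
    opts = dict(DEFAULT_SOLVER_OPTS)
    opts.update(solver_opts or {})
    method = opts.pop("method")
    sol = solve_ivp(
        compiled.rhs, t_span, y0, method=method, t_eval=t_eval,
        jac=compiled.jac, **opts,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed on {t_span}: {sol.message}")
    return sol


def simulate(
    network: ReactionNetwork,
    protocol: Protocol,
    solver_opts: Mapping | None = None,
    *,
    output_dt: float = 1.0,
    compiled: CompiledNetwork | None = None,
    initial_state: np.ndarray | None = None,
) -> SimulationResult:
    """Integrate the network through equilibration and all protocol events.

    Events are applied exactly: integration stops at each event time, the
    state is reset (``set``) or incremented (``add``) and integration
    restarts.  The returned time grid starts at 0 (end of equilibration)
    and covers all readout times at a resolution of ``output_dt`` minutes.
    """
    comp = compiled if compiled is not None else CompiledNetwork(network)
    for _, sp, _, _ in protocol.events:
        if sp not in comp.index:
            raise ValidationError(f"event references unknown species {sp!r}")

    y = comp.initial_state() if initial_state is None else np.array(initial_state, float)
    if protocol.equilibration_duration > 0:
        sol = _integrate(comp, y, (0.0, protocol.equilibration_duration), None, solver_opts)
        y = sol.y[:, -1]

    event_times = [t for t, *_ in protocol.events]
    horizon = max([0.0] + event_times + list(protocol.readout_times))
    grid = np.union1d(
        np.arange(0.0, horizon + 0.5 * output_dt, output_dt),
        np.array([0.0, horizon] + list(protocol.readout_times) + event_times),
    )

    def apply_events(state, at_time):
        state = state.copy()
        for t, sp, amount, mode in protocol.events:
            if t == at_time:
                i = comp.index[sp]
                amt = comp.to_molecules(i, float(amount))
                state[i] = amt if mode == "set" else state[i] + amt
        return state

    boundaries = sorted({0.0, horizon} | {t for t in event_times if 0.0 < t < horizon})
    states = np.empty((comp.n_species, len(grid)))
    y = apply_events(y, 0.0)
    states[:, 0] = y
    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        sel = np.nonzero((grid > t0) & (grid <= t1))[0]
        t_eval = np.unique(np.concatenate([[t0], grid[sel], [t1]]))
        sol = _integrate(comp, y, (t0, t1), t_eval, solver_opts)
        lookup = {round(t, 9): k for k, t in enumerate(sol.t)}
        for i in sel:
            states[:, i] = sol.y[:, lookup[round(grid[i], 9)]]
        y = apply_events(sol.y[:, -1], t1)
        if len(sel) and grid[sel[-1]] == t1:
            states[:, sel[-1]] = y

    native = comp.to_native(states)
    traces = {}
    for obs, weights in network.observables.items():
        tr = np.zeros(len(grid))
        for sp, w in weights.items():
            tr += w * native[comp.index[sp], :]
        traces[obs] = tr
    return SimulationResult(grid, native, list(comp.names), traces)


def steady_state(
    network: ReactionNetwork,
    parameter_overrides: Mapping | None = None,
    tol: float = 1e-6,
    *,
    max_time: float = 1e5,
    chunk: float = 500.0,
    solver_opts: Mapping | None = None,
):
    """Integrate until the relative time-derivative drops below ``tol``.

    Returns ``(state, converged)`` where state maps species to amounts in
    native units.  Non-convergence within ``max_time`` minutes is flagged,
    never silent.
    """
    if tol <= 0:
        raise ValidationError("tol must be > 0")
    net = network.with_parameters(parameter_overrides) if parameter_overrides else network
    comp = CompiledNetwork(net)
    y = comp.initial_state()
    t = 0.0
    converged = False
    while t < max_time:
        sol = _integrate(comp, y, (t, t + chunk), None, solver_opts)
        y = sol.y[:, -1]
        t += chunk
        dy = comp.rhs(t, y)
        rel = np.max(np.abs(dy) / (np.abs(y) + 1e-9))
        if rel < tol:
            converged = True
            break
    native = comp.to_native(y)
    return {n: native[i] for i, n in enumerate(comp.names)}, converged


def observable_timeseries(result: SimulationResult, name: str) -> np.ndarray:
    """Return the named observable trace (weighted species sum)."""
    if name not in result.observable_traces:
        raise KeyError(
            f"unknown observable {name!r}; declared: {sorted(result.observable_traces)}"
        )
    return result.observable_traces[name]


# --------------------------------------------------------------------------
# SBML-style XML serialization
# --------------------------------------------------------------------------
# A self-contained SBML Level 3 core writer/reader covering the subset this
# model uses (compartments, species with initial amounts, parameters,
# reversible mass-action reactions).  Rate-constant names, units and
# provenance ride in an annotation namespace so that a round trip is exact.

_SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
_ANN_NS = "https://erbbqsp.invalid/sbml-annotations"


def network_to_sbml(network: ReactionNetwork) -> str:
    """Serialize the network to an SBML Level 3 document (string)."""
    import xml.etree.ElementTree as ET

    ET.register_namespace("", _SBML_NS)
    ET.register_namespace("eq", _ANN_NS)
    root = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "3", "version": "2"})
    model = ET.SubElement(root, f"{{{_SBML_NS}}}model", {"id": "erbb_network"})

    loc = ET.SubElement(model, f"{{{_SBML_NS}}}listOfCompartments")
    for c in COMPARTMENTS:
        ET.SubElement(loc, f"{{{_SBML_NS}}}compartment",
                      {"id": c, "constant": "true", "spatialDimensions": "3"})

    ids = {}
    los = ET.SubElement(model, f"{{{_SBML_NS}}}listOfSpecies")
    for i, s in enumerate(network.species):
        sid = f"s{i}"
        ids[s.name] = sid
        el = ET.SubElement(los, f"{{{_SBML_NS}}}species", {
            "id": sid, "name": s.name, "compartment": s.compartment,
            "initialAmount": repr(float(s.initial_amount)),
            "hasOnlySubstanceUnits": "true", "boundaryCondition": "false",
            "constant": "false",
        })
        if s.tags:
            ann = ET.SubElement(el, f"{{{_SBML_NS}}}annotation")
            ET.SubElement(ann, f"{{{_ANN_NS}}}tags").text = ",".join(sorted(s.tags))

    lop = ET.SubElement(model, f"{{{_SBML_NS}}}listOfParameters")
    for name in network.parameters:
        el = ET.SubElement(lop, f"{{{_SBML_NS}}}parameter", {
            "id": name, "value": repr(float(network.parameters[name])), "constant": "true",
        })
        ann = ET.SubElement(el, f"{{{_SBML_NS}}}annotation")
        meta = ET.SubElement(ann, f"{{{_ANN_NS}}}meta")
        meta.set("unit", network.parameters.unit(name))
        meta.set("note", network.parameters.note(name))

    lor = ET.SubElement(model, f"{{{_SBML_NS}}}listOfReactions")
    for j, r in enumerate(network.reactions):
        el = ET.SubElement(lor, f"{{{_SBML_NS}}}reaction", {
            "id": f"r{j}", "name": r.label,
            "reversible": "true" if r.kr is not None else "false",
        })
        ann = ET.SubElement(el, f"{{{_SBML_NS}}}annotation")
        rates = ET.SubElement(ann, f"{{{_ANN_NS}}}massAction")
        rates.set("kf", r.kf)
        if r.kr is not None:
            rates.set("kr", r.kr)
        lre = ET.SubElement(el, f"{{{_SBML_NS}}}listOfReactants")
        for sp, st in r.reactants:
            ET.SubElement(lre, f"{{{_SBML_NS}}}speciesReference",
                          {"species": ids[sp], "stoichiometry": str(st), "constant": "true"})
        lpr = ET.SubElement(el, f"{{{_SBML_NS}}}listOfProducts")
        for sp, st in r.products:
            ET.SubElement(lpr, f"{{{_SBML_NS}}}speciesReference",
                          {"species": ids[sp], "stoichiometry": str(st), "constant": "true"})

    loo = ET.SubElement(model, f"{{{_SBML_NS}}}annotation")
    obs_el = ET.SubElement(loo, f"{{{_ANN_NS}}}observables")
    for obs, weights in network.observables.items():
        o = ET.SubElement(obs_el, f"{{{_ANN_NS}}}observable", {"name": obs})
        for sp, w in weights.items():
            ET.SubElement(o, f"{{{_ANN_NS}}}term", {"species": ids[sp], "weight": repr(float(w))})

    ET.indent(root)
    return ET.tostring(root, encoding="unicode", xml_declaration=True)


def network_from_sbml(document: str) -> ReactionNetwork:
    """Parse an SBML document produced by :func:`network_to_sbml`."""
    import xml.etree.ElementTree as ET

    root = ET.fromstring(document)
    model = root.find(f"{{{_SBML_NS}}}model")
    if model is None:
        raise ValidationError("not an SBML document: missing <model>")

    names = {}
    species = []
    for el in model.iter(f"{{{_SBML_NS}}}species"):
        tags = ()
        tag_el = el.find(f"{{{_SBML_NS}}}annotation/{{{_ANN_NS}}}tags")
        if tag_el is not None and tag_el.text:
            tags = tuple(tag_el.text.split(","))
        sdef = SpeciesDef(el.get("name"), el.get("compartment"),
                          float(el.get("initialAmount")), frozenset(tags))
        names[el.get("id")] = sdef.name
        species.append(sdef)

    params = ParameterSet()
    for el in model.iter(f"{{{_SBML_NS}}}parameter"):
        meta = el.find(f"{{{_SBML_NS}}}annotation/{{{_ANN_NS}}}meta")
        unit = meta.get("unit") if meta is not None else ""
        note = meta.get("note") if meta is not None else ""
        params.set(el.get("id"), float(el.get("value")), unit, note)

    reactions = []
    for el in model.iter(f"{{{_SBML_NS}}}reaction"):
        rates = el.find(f"{{{_SBML_NS}}}annotation/{{{_ANN_NS}}}massAction")
        kf = rates.get("kf")
        kr = rates.get("kr")

        def refs(list_tag):
            lst = el.find(f"{{{_SBML_NS}}}{list_tag}")
            if lst is None:
                return ()
            return tuple(
                (names[ref.get("species")], int(ref.get("stoichiometry")))
                for ref in lst
            )

        reactions.append(Reaction(refs("listOfReactants"), refs("listOfProducts"),
                                  kf, kr, el.get("name") or ""))

    observables = {}
    for o in model.iter(f"{{{_ANN_NS}}}observable"):
        observables[o.get("name")] = {
            names[t.get("species")]: float(t.get("weight")) for t in o
        }

    return ReactionNetwork(species, reactions, params, observables)
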