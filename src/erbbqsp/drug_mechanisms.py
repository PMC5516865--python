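"""Drug mechanisms layered onto the ErbB network.

Three inhibitor classes are supported, each as a purely additive extension
of a :class:`~erbbqsp.network_model.ReactionNetwork` (zero dose therefore
reproduces the unextended trajectories exactly):

* **ErbB3-blocking antibody** (seribantumab-class): reversible
  sub-nanomolar binding to free ErbB3; antibody-bound ErbB3 can neither
  bind HRG nor enter any dimerization reaction, and internalizes at a
  multiple of the basal active-dimer rate, with a configurable fraction
  degraded rather than recycled (receptor downregulation).
* **HER2/ErbB3 bispecific** (MM-111-class): docks onto HER2 in solution
  (3D kinetics), then crosslinks ErbB3 in the membrane with an
  avidity-boosted on-rate (2D kinetics); ternary-complex ErbB3 is
  signaling-dead.
* **EGFR tyrosine-kinase inhibitor** (erlotinib-class, modeled like
  lapatinib): reversible binding to EGFR in every unphosphorylated state
  with equal affinity; a dimer whose EGFR is TKI-bound performs no
  trans-phosphorylation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network_model import (
    AVOGADRO,
    EXTRACELLULAR_VOLUME_L,
    ReactionNetwork,
    Reaction,
    SpeciesDef,
    ValidationError,
)

__all__ = [
    "BlockerParams",
    "BispecificParams",
    "TKIParams",
    "TopologyError",
    "extend_with_erbb3_blocker",
    "extend_with_bispecific",
    "extend_with_egfr_tki",
]

#: nmol/l represented by one molecule in the extracellular volume
_CONV_EXT = 1e9 / (AVOGADRO * EXTRACELLULAR_VOLUME_L)

_PER_NM_MIN = "1/(nmol/l)/min"
_PER_MOLEC_MIN = "1/(molec/cell)/min"
_PER_MIN = "1/min"


class TopologyError(ValueError):
    """The network lacks a species the drug mechanism requires."""


@dataclass(frozen=True)
class BlockerParams:
    """ErbB3-blocking antibody (monovalent-equivalent binding)."""

    kd: float = 0.2  # nmol/l, sub-nanomolar monovalent affinity
    kon: float = 0.06  # 1/(nmol/l)/min (~1e6 /M/s)
    internalization_multiplier: float = 2.0  # x basal active-dimer rate
    degradation_fraction_on_internalization: float = 1.0

    def __post_init__(self):
        if self.kd <= 0 or self.kon <= 0:
            raise ValidationError("kd and kon must be positive")
        if self.internalization_multiplier < 1:
            raise ValidationError("internalization_multiplier must be >= 1")
        if not 0 <= self.degradation_fraction_on_internalization <= 1:
            raise ValidationError("degradation fraction must be in [0, 1]")


@dataclass(frozen=True)
class BispecificParams:
    """HER2-anchored ErbB3 crosslinker."""

    kd_her2_arm: float = 1.0  # nmol/l
    kd_erbb3_arm: float = 50.0  # nmol/l, deliberately weaker than the blocker
    kon: float = 0.06  # 1/(nmol/l)/min, both arms in 3D
    crosslink_factor: float = 1e3  # avidity boost of the tethered second arm

    def __post_init__(self):
        if min(self.kd_her2_arm, self.kd_erbb3_arm, self.kon) <= 0:
            raise ValidationError("affinities and kon must be positive")
        if self.crosslink_factor < 1:
            raise ValidationError("crosslink_factor must be >= 1")


@dataclass(frozen=True)
class TKIParams:
    """Reversible ATP-site EGFR kinase inhibitor."""

    ki: float = 50.0  # nmol/l
    kon: float = 0.6  # 1/(nmol/l)/min (small molecule, fast on)

    def __post_init__(self):
        if self.ki <= 0 or self.kon <= 0:
            raise ValidationError("ki and kon must be positive")


def _extended(network, new_species, new_reactions, new_params, extra_erbb3):
    """Assemble the extended network, keeping bookkeeping consistent."""
    params = network.parameters.copy()
    for name, value, unit, note in new_params:
        params.set(name, value, unit, note)
    observables = {k: dict(v) for k, v in network.observables.items()}
    for name, copies in extra_erbb3.items():
        observables["total-ErbB3"][name] = float(copies)
    metadata = dict(network.metadata)
    content = {k: dict(v) for k, v in metadata.get("receptor_content", {}).items()}
    metadata["receptor_content"] = content
    return ReactionNetwork(
        species=list(network.species) + new_species,
        reactions=list(network.reactions) + new_reactions,
        parameters=params,
        observables=observables,
        metadata=metadata,
    ), content


def extend_with_erbb3_blocker(network: ReactionNetwork, params: BlockerParams) -> ReactionNetwork:
    """Add the anti-ErbB3 antibody mechanism.

    The antibody (species ``AB``, extracellular, nmol/l) binds free ErbB3
    reversibly.  ``AB:ErbB3`` is excluded from HRG binding and from every
    dimerization route simply by adding no such reactions, which silences
    ligand-induced, BTC-routed and constitutive signaling through the
    occupied receptor.  The complex internalizes at
    ``internalization_multiplier x kint`` and the internalized pool is
    split between degradation and recycling according to
    ``degradation_fraction_on_internalization``.
    """
    names = set(network.species_names)
    if "ErbB3" not in names:
        raise TopologyError("network has no ErbB3 species")
    if "AB" in names:
        raise TopologyError("network already carries an ErbB3 blocker")

    frac = params.degradation_fraction_on_internalization
    kint_ab = network.parameters["kint"] * params.internalization_multiplier
    kexit = network.parameters["krec"]
    new_params = [
        ("kon_ab", params.kon, _PER_NM_MIN, "antibody-ErbB3 association"),
        ("koff_ab", params.kon * params.kd, _PER_MIN, f"kon x kd ({params.kd} nmol/l)"),
        ("kint_ab", kint_ab, _PER_MIN, "antibody-driven ErbB3 internalization"),
        ("kdeg_ab", kexit * frac, _PER_MIN, "degradation share of internalized AB:ErbB3"),
        ("krec_ab", kexit * (1 - frac), _PER_MIN, "recycling share of internalized AB:ErbB3"),
    ]
    new_species = [
        SpeciesDef("AB", "extracellular", 0.0, frozenset({"drug-bound"})),
        SpeciesDef("AB:ErbB3", "membrane", 0.0, frozenset({"drug-bound", "receptor"})),
        SpeciesDef("AB:ErbB3@endo", "endosome", 0.0, frozenset({"drug-bound", "receptor"})),
    ]
    new_reactions = [
        Reaction((("AB", 1), ("ErbB3", 1)), (("AB:ErbB3", 1),), "kon_ab", "koff_ab",
                 "antibody binds ErbB3"),
        Reaction((("AB:ErbB3", 1),), (("AB:ErbB3@endo", 1),), "kint_ab", None,
                 "antibody-driven internalization"),
        Reaction((("AB:ErbB3@endo", 1),), (), "kdeg_ab", None,
                 "degradation of internalized AB:ErbB3"),
        Reaction((("AB:ErbB3@endo", 1),), (("ErbB3", 1), ("AB", 1)), "krec_ab", None,
                 "recycling of internalized AB:ErbB3"),
    ]
    net, content = _extended(
        network, new_species, new_reactions, new_params,
        {"AB:ErbB3": 1, "AB:ErbB3@endo": 1},
    )
    content["AB:ErbB3"] = {"ErbB3": 1}
    content["AB:ErbB3@endo"] = {"ErbB3": 1}
    return net


def extend_with_bispecific(network: ReactionNetwork, params: BispecificParams) -> ReactionNetwork:
    """Add the HER2-anchored ErbB3-crosslinking bispecific mechanism.

    Binding is strictly two-step: ``BS + HER2 <-> BS:HER2`` with solution
    kinetics, then ``BS:HER2 + ErbB3 <-> BS:HER2:ErbB3`` with the second
    arm's on-rate boosted ``crosslink_factor``-fold over its 3D
    per-molecule value (membrane confinement).  Without HER2 anchors the
    drug therefore cannot engage ErbB3 at all.
    """
    names = set(network.species_names)
    if "HER2" not in names:
        raise TopologyError("network has no HER2 species")
    if "ErbB3" not in names:
        raise TopologyError("network has no ErbB3 species")
    if "BS" in names:
        raise TopologyError("network already carries a bispecific")

    kon2 = params.kon * _CONV_EXT * params.crosslink_factor
    new_params = [
        ("kon_bs", params.kon, _PER_NM_MIN, "bispecific HER2-arm association"),
        ("koff_bs_her2", params.kon * params.kd_her2_arm, _PER_MIN,
         f"kon x kd_her2_arm ({params.kd_her2_arm} nmol/l)"),
        ("kon_bs_xlink", kon2, _PER_MOLEC_MIN,
         f"tethered ErbB3-arm on-rate, {params.crosslink_factor:g}x avidity boost"),
        ("koff_bs_erbb3", params.kon * params.kd_erbb3_arm, _PER_MIN,
         f"kon x kd_erbb3_arm ({params.kd_erbb3_arm} nmol/l)"),
    ]
    new_species = [
        SpeciesDef("BS", "extracellular", 0.0, frozenset({"drug-bound"})),
        SpeciesDef("BS:HER2", "membrane", 0.0, frozenset({"drug-bound", "receptor"})),
        SpeciesDef("BS:HER2:ErbB3", "membrane", 0.0, frozenset({"drug-bound", "receptor"})),
    ]
    new_reactions = [
        Reaction((("BS", 1), ("HER2", 1)), (("BS:HER2", 1),), "kon_bs", "koff_bs_her2",
                 "bispecific docks onto HER2"),
        Reaction((("BS:HER2", 1), ("ErbB3", 1)), (("BS:HER2:ErbB3", 1),),
                 "kon_bs_xlink", "koff_bs_erbb3", "tethered arm crosslinks ErbB3"),
    ]
    net, content = _extended(
        network, new_species, new_reactions, new_params, {"BS:HER2:ErbB3": 1},
    )
    content["BS:HER2"] = {"HER2": 1}
    content["BS:HER2:ErbB3"] = {"HER2": 1, "ErbB3": 1}
    return net


def extend_with_egfr_tki(network: ReactionNetwork, params: TKIParams) -> ReactionNetwork:
    """Add the reversible EGFR kinase inhibitor mechanism.

    The TKI binds every unphosphorylated EGFR-containing membrane species
    with identical kinetics (no state selectivity).  TKI-bound dimers get
    no phosphorylation reaction and TKI-bound monomers no dimerization
    reaction, so a saturating dose silences all EGFR-driven signal while
    leaving HER2:ErbB3 signaling untouched.
    """
    content = network.metadata.get("receptor_content", {})
    targets = []
    phospho = set(network.metadata.get("phospho", ()))
    for s in network.species:
        if s.compartment != "membrane" or s.name in phospho:
            continue
        if "drug-bound" in s.tags or s.name.startswith("p:"):
            continue
        if content.get(s.name, {}).get("EGFR", 0):
            targets.append(s.name)
    if not targets:
        raise TopologyError("network has no EGFR-containing species")
    if "TKI" in set(network.species_names):
        raise TopologyError("network already carries an EGFR TKI")

    new_params = [
        ("kon_tki", params.kon, _PER_NM_MIN, "TKI-EGFR association (state-independent)"),
        ("koff_tki", params.kon * params.ki, _PER_MIN, f"kon x ki ({params.ki} nmol/l)"),
    ]
    new_species = [SpeciesDef("TKI", "extracellular", 0.0, frozenset({"drug-bound"}))]
    new_reactions = []
    extra_erbb3 = {}
    bound_content = {}
    for target in targets:
        bound = f"TKI:{target}"
        new_species.append(
            SpeciesDef(bound, "membrane", 0.0, frozenset({"drug-bound", "receptor"}))
        )
        new_reactions.append(
            Reaction((("TKI", 1), (target, 1)), ((bound, 1),), "kon_tki", "koff_tki",
                     f"TKI binds {target}")
        )
        copies = dict(content.get(target, {}))
        bound_content[bound] = copies
        if copies.get("ErbB3", 0):
            extra_erbb3[bound] = copies["ErbB3"]

    net, new_content = _extended(network, new_species, new_reactions, new_params, extra_erbb3)
    new_content.update(bound_content)
    return net
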