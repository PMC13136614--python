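"""Toy metabolic-network fixtures with controllable pathologies.

Builds a small CHO-like core network (glycolysis stub, glutaminolysis,
overflow lactate, amino-acid uptakes, antibody production and a growth
objective) whose exchange reactions map one-to-one onto synthetic analyte
names.  Requested pathologies are injected exactly once each:

``dead_end``
    a metabolite that is produced but never consumed (its producer is blocked)
``blocked``
    a reaction between two otherwise disconnected metabolites
``redundant_transport``
    an exact duplicate of the glucose transporter
``two_cycle``
    a pair of irreversible reactions forming a thermodynamically infeasible
    internal loop
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cobra import Metabolite, Model, Reaction

from .kinetics import KineticParameters
from .records import AMINO_ACID_ANALYTES, PRODUCT_ANALYTE

KNOWN_PATHOLOGIES = ("dead_end", "blocked", "redundant_transport", "two_cycle")


@dataclass(frozen=True)
class ToyNetworkSpec:
    """Descriptor for :func:`generate_toy_network`."""

    pathologies: tuple[str, ...] = ()
    n_aux_exchanges: int = 2        # amino-acid exchanges beyond the FLEX set
    include_product: bool = True
    uptake_bound: float = 10.0

    def __post_init__(self) -> None:
        for p in self.pathologies:
            if p not in KNOWN_PATHOLOGIES:
                raise ValueError(
                    f"unknown pathology {p!r}; known: {KNOWN_PATHOLOGIES}")
        if self.n_aux_exchanges > len(AMINO_ACID_ANALYTES):
            raise ValueError("not enough amino-acid analytes for n_aux_exchanges")


def _met(model: Model, mid: str, compartment: str) -> Metabolite:
    try:
        return model.metabolites.get_by_id(mid)
    except KeyError:
        m = Metabolite(mid, compartment=compartment)
        model.add_metabolites([m])
        return m


def _rxn(model: Model, rid: str, stoich: dict[str, float],
         lb: float = 0.0, ub: float = 1000.0) -> Reaction:
    r = Reaction(rid, lower_bound=lb, upper_bound=ub)
    model.add_reactions([r])
    r.add_metabolites({
        _met(model, mid, "e" if mid.endswith("_e") else "c"): coef
        for mid, coef in stoich.items()
    })
    return r


def _add_analyte(model: Model, analyte: str, uptake_bound: float,
                 secretion: bool = False) -> None:
    """Exchange + transporter for one analyte."""
    if secretion:
        _rxn(model, f"T_{analyte}", {f"{analyte}_c": -1, f"{analyte}_e": 1})
        _rxn(model, f"EX_{analyte}_e", {f"{analyte}_e": -1}, 0.0, 1000.0)
    else:
        _rxn(model, f"T_{analyte}", {f"{analyte}_e": -1, f"{analyte}_c": 1})
        _rxn(model, f"EX_{analyte}_e", {f"{analyte}_e": -1}, -uptake_bound, 1000.0)


def generate_toy_network(spec: ToyNetworkSpec | None = None) -> Model:
    """Build the toy network described by ``spec`` (a :class:`cobra.Model`).

    The growth objective ``BIOMASS`` consumes pyruvate, glutamine, glutamate
    and every auxiliary amino acid; ammonium and lactate can be secreted.
    """
    spec = spec or ToyNetworkSpec()
    model = Model("toy_cho")

    for analyte in ("glucose", "glutamine", "glutamate"):
        _add_analyte(model, analyte, spec.uptake_bound)
    _add_analyte(model, "lactate", spec.uptake_bound)
    model.reactions.T_lactate.lower_bound = -1000.0   # overflow secretion
    _add_analyte(model, "ammonium", 0.0, secretion=True)

    aux = list(AMINO_ACID_ANALYTES[: spec.n_aux_exchanges])
    for analyte in aux:
        _add_analyte(model, analyte, spec.uptake_bound)

    # Stoichiometry in mass units (g/g), with ammonium yields matching the
    # kinetic layer so kinetically generated exchange-rate patterns lie in
    # the network's feasible cone (as real metabolism does for real data).
    kp = KineticParameters()
    _rxn(model, "GLYC", {"glucose_c": -1, "pyruvate_c": 2})
    _rxn(model, "LDH", {"pyruvate_c": -1, "lactate_c": 1}, -1000.0, 1000.0)
    _rxn(model, "GLS", {"glutamine_c": -1, "glutamate_c": 1,
                        "ammonium_c": kp.YN_Gln})
    _rxn(model, "GDH", {"glutamate_c": -1, "pyruvate_c": 0.3,
                        "ammonium_c": kp.YN_Glu})
    # catabolic disposal (implicit CO2/water): absorbs uptake in excess of
    # biosynthetic demand so measured uptake rates can be pinned exactly
    _rxn(model, "PYR_OXID", {"pyruvate_c": -1})
    _rxn(model, "GLU_OXID", {"glutamate_c": -1, "pyruvate_c": 0.5})
    for analyte in aux:
        _rxn(model, f"{analyte.upper()}_OXID",
             {f"{analyte}_c": -1, "pyruvate_c": 0.3})

    biomass_stoich = {"pyruvate_c": -1.0, "glutamine_c": -0.05,
                      "glutamate_c": -0.02}
    for analyte in aux:
        biomass_stoich[f"{analyte}_c"] = -0.02
    biomass = _rxn(model, "BIOMASS", biomass_stoich)
    model.objective = biomass

    if spec.include_product:
        stoich = {"pyruvate_c": -0.5, f"{PRODUCT_ANALYTE}_c": 1}
        if aux:
            stoich[f"{aux[0]}_c"] = -0.2
        _rxn(model, "MAB_SYNTH", stoich)
        _add_analyte(model, PRODUCT_ANALYTE, 0.0, secretion=True)

    if "dead_end" in spec.pathologies:
        _rxn(model, "DEADEND_PROD", {"pyruvate_c": -1, "deadend_c": 1})
    if "blocked" in spec.pathologies:
        _rxn(model, "BLOCKED_RXN", {"orphan_a_c": -1, "orphan_b_c": 1})
    if "redundant_transport" in spec.pathologies:
        _rxn(model, "T_glucose_dup", {"glucose_e": -1, "glucose_c": 1})
    if "two_cycle" in spec.pathologies:
        _rxn(model, "CYC_A", {"pyruvate_c": -1, "cycle_c": 1})
        _rxn(model, "CYC_B", {"cycle_c": -1, "pyruvate_c": 1})
    return model
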