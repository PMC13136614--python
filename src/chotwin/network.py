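"""Thin stoichiometric-network wrapper around a COBRA model.

Exposes the matrices and index sets the hybrid-LP layer needs (stoichiometric
matrix, bounds, exchange subset, biomass/objective reaction) while keeping the
underlying :class:`cobra.Model` available for standard constraint-based
operations (FBA, pFBA, FVA, SBML I/O).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from cobra import Model
from cobra.util.array import create_stoichiometric_matrix


@dataclass
class MetabolicNetwork:
    model: Model

    @classmethod
    def from_cobra(cls, model: Model) -> "MetabolicNetwork":
        return cls(model=model)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.model.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.model.metabolites]

    @property
    def S(self) -> np.ndarray:
        return create_stoichiometric_matrix(self.model)

    @property
    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.model.reactions])
        ub = np.array([r.upper_bound for r in self.model.reactions])
        return lb, ub

    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.model.exchanges]

    @property
    def biomass_id(self) -> str:
        objs = [r.id for r in self.model.reactions
                if r.objective_coefficient != 0]
        if not objs:
            raise ValueError(f"model {self.model.id!r} has no objective reaction")
        return objs[0]

    @property
    def objective_vector(self) -> np.ndarray:
        return np.array([r.objective_coefficient for r in self.model.reactions])

    def index_of(self, reaction_id: str) -> int:
        return self.model.reactions.index(reaction_id)

    def exchange_for_analyte(self, analyte: str) -> str:
        """Exchange reaction id for a measured analyte (``EX_<analyte>_e``)."""
        rid = f"EX_{analyte}_e"
        if rid not in {r.id for r in self.model.reactions}:
            raise KeyError(f"no exchange reaction for analyte {analyte!r}")
        return rid

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(model=self.model.copy())
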