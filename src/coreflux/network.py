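"""In-memory representation of a stoichiometric metabolic network.

The central object is :class:`MetabolicNetwork`: N metabolites, M reactions,
an N x M sparse stoichiometric matrix S (column j holds reaction j's signed
coefficients, negative = consumed), flux bounds in mmol gDW^-1 h^-1, GPR
rules, and a designated biomass reaction whose flux is the growth rate.

Sign conventions follow the constraint-based-modeling standard: an exchange
reaction has a single metabolite with coefficient -1, so negative flux means
uptake and positive flux means secretion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy import sparse

from .gpr import GPRExpr

__all__ = [
    "MetaboliteRecord",
    "ReactionRecord",
    "MetabolicNetwork",
    "NetworkValidationError",
    "DEFAULT_BOUND",
]

#: Default flux-bound magnitude used as the model's numeric "infinity".
DEFAULT_BOUND = 1000.0


class NetworkValidationError(ValueError):
    """Raised when a network or one of its records violates an invariant."""


@dataclass(frozen=True)
class MetaboliteRecord:
    """A metabolite: id, display name, compartment, elemental formula, charge.

    ``formula`` maps element symbols to non-negative counts (``None`` when
    unknown, e.g. generic R-group species); ``charge`` is the molecular
    charge at neutral pH.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[Mapping[str, int]] = None
    charge: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("metabolite id must be non-empty")
        if self.formula is not None:
            for element, count in self.formula.items():
                if count < 0:
                    raise NetworkValidationError(
                        f"metabolite {self.id}: negative count for {element}"
                    )


@dataclass(frozen=True)
class ReactionRecord:
    """A reaction: stoichiometry, flux bounds, optional GPR rule.

    ``stoichiometry`` maps metabolite ids to signed coefficients (negative =
    consumed).  Reversibility is not stored separately: a reaction is
    reversible exactly when its lower bound is negative.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: Optional[GPRExpr] = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise NetworkValidationError(f"reaction {self.id}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise NetworkValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        """Boundary pseudo-reaction: exactly one participating metabolite."""
        return len(self.stoichiometry) == 1

    def with_bounds(self, lower: float, upper: float) -> "ReactionRecord":
        return replace(self, lower_bound=float(lower), upper_bound=float(upper))


class MetabolicNetwork:
    """A genome-scale (or toy) metabolic network.

    Parameters
    ----------
    metabolites, reactions:
        The network's records; ids must be unique within each list.
    biomass_reaction:
        Id of the biomass drain whose flux is the growth rate, or ``None``
        for networks without one (e.g. cycle-detection fixtures).
    """

    def __init__(
        self,
        metabolites: Iterable[MetaboliteRecord],
        reactions: Iterable[ReactionRecord],
        biomass_reaction: Optional[str] = None,
        id: str = "model",
    ):
        self.id = id
        self.metabolites: list[MetaboliteRecord] = list(metabolites)
        self.reactions: list[ReactionRecord] = list(reactions)
        self.biomass_reaction = biomass_reaction
        self._met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        self._rxn_index = {r.id: j for j, r in enumerate(self.reactions)}
        self._validate()
        self._S: Optional[sparse.csc_matrix] = None

    # -- construction / validation --------------------------------------
    def _validate(self) -> None:
        if not self.metabolites or not self.reactions:
            raise NetworkValidationError("network needs at least one metabolite and reaction")
        if len(self._met_index) != len(self.metabolites):
            dup = _first_duplicate(m.id for m in self.metabolites)
            raise NetworkValidationError(f"duplicate metabolite id {dup!r}")
        if len(self._rxn_index) != len(self.reactions):
            dup = _first_duplicate(r.id for r in self.reactions)
            raise NetworkValidationError(f"duplicate reaction id {dup!r}")
        for r in self.reactions:
            for met_id in r.stoichiometry:
                if met_id not in self._met_index:
                    raise NetworkValidationError(
                        f"reaction {r.id} references unknown metabolite {met_id!r}"
                    )
        if self.biomass_reaction is not None and self.biomass_reaction not in self._rxn_index:
            raise NetworkValidationError(
                f"biomass reaction {self.biomass_reaction!r} not in network"
            )

    # -- indexing --------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def metabolite(self, met_id: str) -> MetaboliteRecord:
        return self.metabolites[self._met_index[met_id]]

    def reaction(self, rxn_id: str) -> ReactionRecord:
        return self.reactions[self._rxn_index[rxn_id]]

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def has_reaction(self, rxn_id: str) -> bool:
        return rxn_id in self._rxn_index

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            if r.gpr is not None:
                out |= r.gpr.genes()
        return frozenset(out)

    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions if r.is_exchange]

    # -- stoichiometric matrix ------------------------------------------
    @property
    def S(self) -> sparse.csc_matrix:
        """N x M sparse stoichiometric matrix, built column-by-column."""
        if self._S is None:
            rows, cols, data = [], [], []
            for j, r in enumerate(self.reactions):
                for met_id, coeff in r.stoichiometry.items():
                    rows.append(self._met_index[met_id])
                    cols.append(j)
                    data.append(float(coeff))
            self._S = sparse.csc_matrix(
                (data, (rows, cols)), shape=(self.n_metabolites, self.n_reactions)
            )
        return self._S

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    # -- derived networks -----------------------------------------------
    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            self.metabolites, self.reactions, self.biomass_reaction, id=self.id
        )

    def with_bounds(self, bounds: Mapping[str, tuple[float, float]]) -> "MetabolicNetwork":
        """New network with the given reactions' bounds replaced."""
        new_reactions = []
        for r in self.reactions:
            if r.id in bounds:
                lo, hi = bounds[r.id]
                new_reactions.append(r.with_bounds(lo, hi))
            else:
                new_reactions.append(r)
        return MetabolicNetwork(
            self.metabolites, new_reactions, self.biomass_reaction, id=self.id
        )

    def without_reactions(self, rxn_ids: Iterable[str]) -> "MetabolicNetwork":
        drop = set(rxn_ids)
        missing = drop - set(self._rxn_index)
        if missing:
            raise NetworkValidationError(f"cannot remove absent reactions: {sorted(missing)}")
        kept = [r for r in self.reactions if r.id not in drop]
        biomass = self.biomass_reaction if self.biomass_reaction not in drop else None
        return MetabolicNetwork(self.metabolites, kept, biomass, id=self.id)

    def with_extra(
        self,
        metabolites: Iterable[MetaboliteRecord] = (),
        reactions: Iterable[ReactionRecord] = (),
    ) -> "MetabolicNetwork":
        return MetabolicNetwork(
            list(self.metabolites) + list(metabolites),
            list(self.reactions) + list(reactions),
            self.biomass_reaction,
            id=self.id,
        )

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return (
            f"<MetabolicNetwork {self.id}: {self.n_metabolites} metabolites, "
            f"{self.n_reactions} reactions, {len(self.genes)} genes>"
        )


def _first_duplicate(ids: Iterable[str]) -> str:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return ""
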