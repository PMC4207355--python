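"""Detection and curation of thermodynamically infeasible cycles.

An internal loop that can carry flux with every exchange closed violates
energy balance: it corresponds to a nonzero vector in the null space of the
stoichiometric matrix with no boundary exchange.  Detection follows the
loop-law strategy: (1) close all exchanges and run FVA with no biomass
constraint — reactions whose flux range hits the numeric "infinity" bound
are cycle candidates; (2) compute a null-space basis of the stoichiometric
matrix restricted to the candidate columns by rank-revealing Gaussian
elimination; each basis vector is one independent cycle.

Two-reaction cycles are duplicate (equivalent) reactions — same reactants,
products, and cofactors, possibly written in opposite orientations — and
are resolved by deleting one of the pair.  Larger cycles need a judgement
call (remove a poorly supported member, or restrict a direction), so this
module only proposes and applies explicit curation actions; it never
auto-deletes.  Gibbs free-energy estimates with error bars supply one
mechanical restriction rule: if the whole interval dG ± error lies more
than a threshold (default 4 kcal/mol) away from zero, the reaction is
restricted to the direction the free energy dictates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .flux_core import fva
from .network import DEFAULT_BOUND, MetabolicNetwork

__all__ = [
    "CycleVector",
    "GibbsRecord",
    "CurationAction",
    "find_cycle_candidates",
    "null_space_cycles",
    "classify_cycle",
    "gibbs_restrict",
    "apply_actions",
    "curate_until_closed",
]

_CANDIDATE_TOL = 1e-6
_NULL_TOL = 1e-9


@dataclass(frozen=True)
class CycleVector:
    """One independent internal loop: reaction coefficients with S·v = 0."""

    coefficients: dict[str, float]

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.coefficients)

    def embed(self, network: MetabolicNetwork) -> np.ndarray:
        v = np.zeros(network.n_reactions)
        for rxn_id, coeff in self.coefficients.items():
            v[network.reaction_index(rxn_id)] = coeff
        return v


@dataclass(frozen=True)
class GibbsRecord:
    """Reaction Gibbs free energy estimate in kcal/mol with half-width error."""

    reaction_id: str
    dG: float
    error: float

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError(f"{self.reaction_id}: negative error {self.error}")


@dataclass(frozen=True)
class CurationAction:
    """A curation decision: remove a reaction or restrict its direction."""

    reaction_id: str
    action: str  # "remove" | "forward_only" | "reverse_only"
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.action not in ("remove", "forward_only", "reverse_only"):
            raise ValueError(f"unknown curation action {self.action!r}")


def close_exchanges(network: MetabolicNetwork) -> MetabolicNetwork:
    """All exchange reactions pinned to zero flux — only internal loops remain."""
    return network.with_bounds({r.id: (0.0, 0.0) for r in network.reactions if r.is_exchange})


def find_cycle_candidates(
    network: MetabolicNetwork,
    bound_magnitude: float = DEFAULT_BOUND,
    tol: float = _CANDIDATE_TOL,
) -> set[str]:
    """Reactions whose FVA extrema hit the default bound with exchanges closed.

    No biomass constraint is applied: with all exchanges shut, any reaction
    still able to carry flux at the bound magnitude B can only do so inside
    an internal loop.
    """
    closed = close_exchanges(network)
    internal = [r.id for r in network.reactions if not r.is_exchange]
    ranges = fva(closed, internal)
    return {
        rxn_id
        for rxn_id, fr in ranges.items()
        if max(abs(fr.minimum), abs(fr.maximum)) >= bound_magnitude - tol
    }


def null_space_cycles(
    network: MetabolicNetwork, candidates: Iterable[str]
) -> list[CycleVector]:
    """Null-space basis of S restricted to candidate columns, one vector per loop.

    Uses rank-revealing Gaussian elimination (reduced row echelon form) so
    each basis vector is tied to one free column, keeping supports sparse;
    vectors are normalized so the largest-magnitude coefficient is +1 and
    returned smallest support first.
    """
    cand = sorted(candidates, key=network.reaction_index)
    if not cand:
        return []
    cols = [network.reaction_index(rxn_id) for rxn_id in cand]
    A = network.S.toarray()[:, cols]
    basis = _rref_nullspace(A)
    out = []
    for vec in basis:
        k = int(np.argmax(np.abs(vec)))
        vec = vec / vec[k]
        coeffs = {
            cand[i]: float(vec[i]) for i in range(len(cand)) if abs(vec[i]) > _NULL_TOL
        }
        out.append(CycleVector(coeffs))
    out.sort(key=lambda c: (len(c.support), sorted(c.support)))
    return out


def _rref_nullspace(A: np.ndarray, tol: float = 1e-10) -> list[np.ndarray]:
    A = np.array(A, dtype=float)
    m, n = A.shape
    pivot_cols: list[int] = []
    row = 0
    for col in range(n):
        if row >= m:
            break
        piv = row + int(np.argmax(np.abs(A[row:, col])))
        if abs(A[piv, col]) < tol:
            continue
        A[[row, piv]] = A[[piv, row]]
        A[row] = A[row] / A[row, col]
        for r in range(m):
            if r != row and abs(A[r, col]) > tol:
                A[r] -= A[r, col] * A[row]
        pivot_cols.append(col)
        row += 1
    free_cols = [c for c in range(n) if c not in pivot_cols]
    basis = []
    for fc in free_cols:
        v = np.zeros(n)
        v[fc] = 1.0
        for r, pc in enumerate(pivot_cols):
            v[pc] = -A[r, fc]
        basis.append(v)
    return basis


def classify_cycle(cycle: CycleVector, network: MetabolicNetwork) -> str:
    """``"equivalent_pair"`` for duplicate two-reaction cycles, else ``"multi_reaction"``.

    A pair is equivalent when the two stoichiometry columns are equal or
    negated entry-for-entry — same reactants, products, and cofactors,
    differing at most in orientation.  A two-reaction candidate whose
    columns differ (e.g. NAD- vs NADP-coupled variants) is multi_reaction.
    """
    if len(cycle.support) != 2:
        return "multi_reaction"
    a_id, b_id = sorted(cycle.support)
    a = dict(network.reaction(a_id).stoichiometry)
    b = dict(network.reaction(b_id).stoichiometry)
    if set(a) != set(b):
        return "multi_reaction"
    for sign in (1.0, -1.0):
        if all(abs(a[m] - sign * b[m]) < 1e-9 for m in a):
            return "equivalent_pair"
    return "multi_reaction"


def gibbs_restrict(
    network: MetabolicNetwork,
    records: Sequence[GibbsRecord],
    threshold: float = 4.0,
) -> list[CurationAction]:
    """Directionality restrictions from Gibbs free energies.

    A reaction whose entire interval dG ± error lies below -threshold is
    restricted to the forward direction (negative free energy drives the
    reaction forward); entirely above +threshold, to the reverse direction.
    Reactions whose bounds already agree with the free-energy direction get
    no action, making the rule idempotent.
    """
    actions = []
    for rec in records:
        if not network.has_reaction(rec.reaction_id):
            raise KeyError(f"Gibbs record references unknown reaction {rec.reaction_id!r}")
        rxn = network.reaction(rec.reaction_id)
        if rec.dG + rec.error < -threshold and rxn.lower_bound < 0:
            actions.append(
                CurationAction(
                    rec.reaction_id,
                    "forward_only",
                    f"dG = {rec.dG:g} ± {rec.error:g} kcal/mol entirely below -{threshold:g}",
                )
            )
        elif rec.dG - rec.error > threshold and rxn.upper_bound > 0:
            actions.append(
                CurationAction(
                    rec.reaction_id,
                    "reverse_only",
                    f"dG = {rec.dG:g} ± {rec.error:g} kcal/mol entirely above +{threshold:g}",
                )
            )
    return actions


def apply_actions(
    network: MetabolicNetwork, actions: Sequence[CurationAction]
) -> MetabolicNetwork:
    for action in actions:
        if not network.has_reaction(action.reaction_id):
            raise KeyError(f"curation action targets absent reaction {action.reaction_id!r}")
        rxn = network.reaction(action.reaction_id)
        if action.action == "remove":
            network = network.without_reactions([action.reaction_id])
        elif action.action == "forward_only":
            network = network.with_bounds(
                {rxn.id: (max(rxn.lower_bound, 0.0), max(rxn.upper_bound, 0.0))}
            )
        else:  # reverse_only
            network = network.with_bounds(
                {rxn.id: (min(rxn.lower_bound, 0.0), min(rxn.upper_bound, 0.0))}
            )
    return network


@dataclass
class CurationPass:
    """State after applying one curation action and re-detecting loops."""

    applied: Optional[CurationAction]
    candidates: set[str]
    cycles: list[CycleVector] = field(default_factory=list)


@dataclass
class CurationReport:
    passes: list[CurationPass]
    closed: bool

    @property
    def remaining_cycles(self) -> list[CycleVector]:
        return self.passes[-1].cycles if self.passes else []


def curate_until_closed(
    network: MetabolicNetwork,
    actions: Sequence[CurationAction],
    bound_magnitude: float = DEFAULT_BOUND,
) -> tuple[MetabolicNetwork, CurationReport]:
    """Apply curation actions one at a time, re-detecting loops after each.

    Every supplied action is applied (the list is the curator's decision);
    after the list is exhausted, any surviving cycles are reported
    (closed = False), never silently dropped.
    """
    passes: list[CurationPass] = []

    def detect(applied: Optional[CurationAction]) -> CurationPass:
        candidates = find_cycle_candidates(network, bound_magnitude)
        cycles = null_space_cycles(network, candidates) if candidates else []
        return CurationPass(applied, candidates, cycles)

    current = detect(None)
    passes.append(current)
    for action in actions:
        network = apply_actions(network, [action])
        current = detect(action)
        passes.append(current)
    return network, CurationReport(passes, closed=not current.candidates)
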