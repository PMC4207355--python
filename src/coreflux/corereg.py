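"""Hierarchical core-set extraction from transcriptomic bound contraction.

The method explains stress-induced flux redirection as the consequence of a
multiplicative bound contraction on a small set of reactions.  Procedure:

1. FVA on the unregulated model with no biomass constraint gives each
   reaction's loosest attainable bounds [v_j^L,UR, v_j^U,UR].
2. For every reaction whose expression fold change c_j is below 1, both
   bounds are multiplied by c_j (for a reversible reaction this also
   shrinks the attainable reverse flux).
3. Maximum biomass is computed for the unregulated and the regulated
   model; if the regulated optimum is within 2% of the unregulated one the
   remaining regulation is considered inconsequential and iteration stops.
4. FVA on the regulated model with biomass pinned at its regulated maximum
   gives achieved ranges [v_j^l,R, v_j^u,R].
5. Reactions whose achieved range touches its imposed regulatory bound are
   the core set of order k: their contraction is what binds the optimum.
   Their c_j is then reset to 1 and the loop repeats with k+1 for the
   secondary, tertiary, ... core sets.

The defining property — checked by :func:`verify_core_sufficiency` — is
that contracting only the core set's bounds reproduces the flux ranges of
the fully regulated model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .expression import FoldChangeMap
from .flux_core import FLUX_ATOL, FluxRange, fba, fva
from .network import MetabolicNetwork

__all__ = [
    "RegulatedBounds",
    "CoreSet",
    "CoreIteration",
    "CoreRegResult",
    "unregulated_ranges",
    "regulate_bounds",
    "biomass_attenuation",
    "identify_core_set",
    "corereg_run",
    "verify_core_sufficiency",
]

#: Relative slack when pinning biomass at an LP optimum; exact equality
#: pins invite solver-level infeasibility.
PIN_SLACK = 1e-6

#: Relative biomass-attenuation threshold below which remaining regulation
#: is treated as inconsequential.
DEFAULT_THRESHOLD = 0.02

#: Maximum core-set order explored by default.
DEFAULT_MAX_K = 6


def _bound_tol(imposed: float) -> float:
    return max(1e-6, 1e-6 * abs(imposed))


@dataclass(frozen=True)
class RegulatedBounds:
    """Unregulated FVA bounds and their fold-change-contracted counterparts.

    ``active`` holds the reactions with c_j < 1; inactive reactions keep
    their unregulated bounds.
    """

    unregulated: Mapping[str, FluxRange]
    regulated: Mapping[str, FluxRange]
    active: frozenset[str]

    def regulated_bound_map(self) -> dict[str, tuple[float, float]]:
        return {r: (fr.minimum, fr.maximum) for r, fr in self.regulated.items()}

    def core_bound_map(self, core: frozenset[str]) -> dict[str, tuple[float, float]]:
        """Contracted bounds on the core only; everything else unregulated."""
        out = {}
        for rxn_id, fr in self.unregulated.items():
            src = self.regulated[rxn_id] if rxn_id in core else fr
            out[rxn_id] = (src.minimum, src.maximum)
        return out


@dataclass(frozen=True)
class CoreSet:
    """Core set of order k: the reactions whose contraction binds the optimum."""

    order: int
    reactions: frozenset[str]
    genes: frozenset[str]
    biomass_effect: str  # "substantial" | "minimal"


@dataclass(frozen=True)
class CoreIteration:
    order: int
    v_biomass_unregulated: float
    v_biomass_regulated: float
    rel_change: float
    core_set: CoreSet


@dataclass(frozen=True)
class CoreRegResult:
    iterations: tuple[CoreIteration, ...]
    fva_regulated: Mapping[str, FluxRange]  # achieved ranges at k = 1
    terminated_reason: str  # "attenuation_below_threshold" | "empty_core_set" | "max_order_reached"

    @property
    def core_sets(self) -> list[CoreSet]:
        return [it.core_set for it in self.iterations if it.core_set.reactions]

    def core_set(self, order: int) -> Optional[CoreSet]:
        for it in self.iterations:
            if it.order == order:
                return it.core_set
        return None


# ---------------------------------------------------------------------------
# Steps
# ---------------------------------------------------------------------------

def unregulated_ranges(network: MetabolicNetwork) -> dict[str, FluxRange]:
    """Step 1: loosest attainable bounds — FVA with no biomass constraint.

    Nutrient-uptake limits stay in force (they are part of the growth
    condition); only the biomass flux is left free.
    """
    return fva(network)


def regulate_bounds(
    ur: Mapping[str, FluxRange], c: FoldChangeMap
) -> RegulatedBounds:
    """Step 2: contract both bounds of every down-regulated reaction by c_j.

    The contraction is applied verbatim to lower and upper bounds alike —
    for a reversible reaction the negative lower bound shrinks toward zero,
    reducing the attainable reverse flux; a forced-flux reaction (positive
    lower bound) scales down as well.
    """
    regulated = {}
    active = set()
    for rxn_id, fr in ur.items():
        cj = c.get(rxn_id)
        if cj <= 0:
            raise ValueError(f"fold change for {rxn_id!r} must be positive, got {cj}")
        if cj < 1.0:
            active.add(rxn_id)
            regulated[rxn_id] = FluxRange(rxn_id, fr.minimum * cj, fr.maximum * cj)
        else:
            regulated[rxn_id] = fr
    return RegulatedBounds(dict(ur), regulated, frozenset(active))


def biomass_attenuation(
    network: MetabolicNetwork, reg: RegulatedBounds
) -> tuple[float, float, float]:
    """Step 3: maximum biomass unregulated vs regulated, and the relative drop."""
    sol_ur = fba(network)
    if not sol_ur.optimal or sol_ur.objective_value <= FLUX_ATOL:
        raise ValueError("model cannot grow unregulated; attenuation undefined")
    regulated_model = network.with_bounds(reg.regulated_bound_map())
    sol_r = fba(regulated_model)
    if not sol_r.optimal:
        raise ValueError(f"regulated model FBA not optimal: {sol_r.status}")
    v_ur = sol_ur.objective_value
    v_r = sol_r.objective_value
    return v_ur, v_r, (v_ur - v_r) / v_ur


def identify_core_set(
    network: MetabolicNetwork,
    reg: RegulatedBounds,
    v_r: float,
    order: int,
    biomass_effect: str = "substantial",
) -> tuple[CoreSet, dict[str, FluxRange]]:
    """Steps 4-5: FVA at the regulated biomass optimum; collect bound-touching reactions.

    A down-regulated reaction enters the core set when its achieved FVA
    range attains the imposed regulatory bound at either end (the imposed
    constraint is binding at the optimum).  Equality is taken to tolerance
    max(1e-6, 1e-6 * |imposed|) — exact floating-point equality is
    unattainable.
    """
    if network.biomass_reaction is None:
        raise ValueError("network has no biomass reaction")
    regulated_model = network.with_bounds(reg.regulated_bound_map())
    biomass_ub = regulated_model.reaction(network.biomass_reaction).upper_bound
    pin = {network.biomass_reaction: (v_r * (1.0 - PIN_SLACK), biomass_ub)}
    achieved = fva(regulated_model, fixed=pin)
    members = set()
    for rxn_id in reg.active:
        imposed = reg.regulated[rxn_id]
        got = achieved[rxn_id]
        if (
            abs(got.maximum - imposed.maximum) <= _bound_tol(imposed.maximum)
            or abs(got.minimum - imposed.minimum) <= _bound_tol(imposed.minimum)
        ):
            members.add(rxn_id)
    genes: set[str] = set()
    for rxn_id in members:
        gpr = network.reaction(rxn_id).gpr
        if gpr is not None:
            genes |= gpr.genes()
    core = CoreSet(order, frozenset(members), frozenset(genes), biomass_effect)
    return core, achieved


def corereg_run(
    network: MetabolicNetwork,
    c: FoldChangeMap,
    threshold: float = DEFAULT_THRESHOLD,
    max_k: int = DEFAULT_MAX_K,
) -> CoreRegResult:
    """The full iterative procedure: primary, secondary, ... core sets.

    Each iteration contracts bounds with the current fold changes, measures
    the biomass attenuation, extracts the core set at the regulated
    optimum, then neutralizes the core set's fold changes (c_j <- 1) for
    the next order.  Iteration stops after recording the current core set
    when the attenuation falls below ``threshold`` (the set is flagged
    ``biomass_effect="minimal"``), when the core set comes out empty, or at
    ``max_k``.
    """
    ur = unregulated_ranges(network)
    iterations: list[CoreIteration] = []
    fva_regulated: dict[str, FluxRange] = {}
    reason = "max_order_reached"
    current = c
    for k in range(1, max_k + 1):
        reg = regulate_bounds(ur, current)
        v_ur, v_r, rel = biomass_attenuation(network, reg)
        effect = "minimal" if rel < threshold else "substantial"
        core, achieved = identify_core_set(network, reg, v_r, k, effect)
        if k == 1:
            fva_regulated = achieved
        iterations.append(CoreIteration(k, v_ur, v_r, rel, core))
        if rel < threshold:
            reason = "attenuation_below_threshold"
            break
        if not core.reactions:
            reason = "empty_core_set"
            break
        current = current.deactivated(core.reactions)
    return CoreRegResult(tuple(iterations), fva_regulated, reason)


def verify_core_sufficiency(
    network: MetabolicNetwork,
    c: FoldChangeMap,
    core: CoreSet | frozenset[str],
    tol: float = FLUX_ATOL,
) -> tuple[bool, float]:
    """Does contracting only the core set reproduce the fully regulated ranges?

    Builds two models from the unregulated FVA bounds — one with all
    down-regulated reactions contracted, one with only the core members
    contracted — runs FVA on each at its own pinned biomass maximum, and
    returns (all ranges match within ``tol``, max elementwise deviation).
    """
    members = core.reactions if isinstance(core, CoreSet) else frozenset(core)
    ur = unregulated_ranges(network)
    reg = regulate_bounds(ur, c)

    def pinned_ranges(bound_map: dict[str, tuple[float, float]]) -> dict[str, FluxRange]:
        model = network.with_bounds(bound_map)
        sol = fba(model)
        if not sol.optimal:
            raise ValueError(f"FBA not optimal during sufficiency check: {sol.status}")
        biomass_ub = model.reaction(network.biomass_reaction).upper_bound
        pin = {
            network.biomass_reaction: (
                sol.objective_value * (1.0 - PIN_SLACK),
                biomass_ub,
            )
        }
        return fva(model, fixed=pin)

    full = pinned_ranges(reg.regulated_bound_map())
    core_only = pinned_ranges(reg.core_bound_map(members))
    max_dev = 0.0
    for rxn_id in full:
        a, b = full[rxn_id], core_only[rxn_id]
        max_dev = max(max_dev, abs(a.minimum - b.minimum), abs(a.maximum - b.maximum))
    return max_dev <= tol, max_dev
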