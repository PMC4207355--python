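"""Flux balance analysis (FBA) and flux variability analysis (FVA).

FBA maximizes (or minimizes) one reaction's flux — typically the biomass
drain, whose flux is the growth rate in h^-1 — over the steady-state flux
polytope {v : S v = 0, lb <= v <= ub}.  FVA solves the same LP twice per
reaction (max and min of v_j) to report the attainable flux interval of
every reaction under the constraints.

All LPs are solved with the HiGHS solvers behind
:func:`scipy.optimize.linprog`, which are deterministic for a fixed model,
so repeated runs return identical extrema.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Union

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .network import MetabolicNetwork

__all__ = [
    "FluxRange",
    "LPSolution",
    "InfeasiblePinError",
    "fba",
    "fva",
    "apply_gene_deletion",
    "normalize_fluxes",
    "FLUX_ATOL",
]

#: Absolute tolerance for flux-value comparisons (mmol gDW^-1 h^-1).
#: Bounds of magnitude 1000 make purely relative comparisons fragile.
FLUX_ATOL = 1e-6


@dataclass(frozen=True)
class FluxRange:
    """Attainable flux interval [minimum, maximum] of one reaction."""

    reaction_id: str
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if self.minimum > self.maximum + FLUX_ATOL:
            raise ValueError(
                f"{self.reaction_id}: flux minimum {self.minimum} exceeds "
                f"maximum {self.maximum}"
            )

    def contains(self, value: float, tol: float = FLUX_ATOL) -> bool:
        return self.minimum - tol <= value <= self.maximum + tol

    @property
    def width(self) -> float:
        return self.maximum - self.minimum

    def scaled(self, factor: float) -> "FluxRange":
        lo, hi = sorted((self.minimum * factor, self.maximum * factor))
        return FluxRange(self.reaction_id, lo, hi)


@dataclass(frozen=True)
class LPSolution:
    """Outcome of one FBA solve."""

    status: str  # "optimal" | "infeasible" | "unbounded"
    objective_value: Optional[float] = None
    fluxes: Mapping[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


class InfeasiblePinError(ValueError):
    """Raised when pinned constraints make the flux polytope empty."""

    def __init__(self, message: str, conflicting: Optional[str] = None):
        super().__init__(message)
        self.conflicting = conflicting


BoundsLike = Union[float, tuple[float, float]]

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _resolve_pins(
    network: MetabolicNetwork, fixed: Optional[Mapping[str, BoundsLike]]
) -> dict[int, tuple[float, float]]:
    pins: dict[int, tuple[float, float]] = {}
    if fixed:
        for rxn_id, value in fixed.items():
            j = network.reaction_index(rxn_id)
            if isinstance(value, (int, float)):
                pins[j] = (float(value), float(value))
            else:
                lo, hi = value
                pins[j] = (float(lo), float(hi))
    return pins


def _solve(
    A_eq: sparse.csr_matrix,
    bounds: list[tuple[float, float]],
    c: np.ndarray,
    sense: str,
) -> tuple[str, Optional[float], Optional[np.ndarray]]:
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(sign * c, A_eq=A_eq, b_eq=np.zeros(A_eq.shape[0]), bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return status, None, None
    return "optimal", sign * res.fun, res.x


def _problem(
    network: MetabolicNetwork, fixed: Optional[Mapping[str, BoundsLike]] = None
) -> tuple[sparse.csr_matrix, list[tuple[float, float]]]:
    lb, ub = network.bounds_arrays()
    for j, (lo, hi) in _resolve_pins(network, fixed).items():
        lb[j], ub[j] = lo, hi
    return network.S.tocsr(), list(zip(lb, ub))


def fba(
    network: MetabolicNetwork,
    objective: Optional[str] = None,
    sense: str = "max",
    fixed: Optional[Mapping[str, BoundsLike]] = None,
) -> LPSolution:
    """Maximize or minimize one reaction's flux at steady state.

    Parameters
    ----------
    objective:
        Reaction id to optimize; defaults to the network's biomass reaction.
    sense:
        ``"max"`` or ``"min"``.
    fixed:
        Optional bound overrides (reaction id -> value or (lo, hi)).

    Infeasibility and unboundedness are reported through the solution's
    ``status``, never as exceptions.
    """
    if objective is None:
        objective = network.biomass_reaction
    if objective is None:
        raise ValueError("no objective given and network has no biomass reaction")
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    j_obj = network.reaction_index(objective)
    A_eq, bounds = _problem(network, fixed)
    c = np.zeros(network.n_reactions)
    c[j_obj] = 1.0
    status, value, x = _solve(A_eq, bounds, c, sense)
    if status != "optimal":
        return LPSolution(status="infeasible" if status == "infeasible" else "unbounded"
                          if status == "unbounded" else status)
    fluxes = dict(zip(network.reaction_ids, map(float, x)))
    return LPSolution(status="optimal", objective_value=float(value), fluxes=fluxes)


def fva(
    network: MetabolicNetwork,
    reactions: Optional[Iterable[str]] = None,
    fixed: Optional[Mapping[str, BoundsLike]] = None,
) -> dict[str, FluxRange]:
    """Minimum and maximum attainable flux for each target reaction.

    Two LPs are solved per reaction over {S v = 0, bounds} with the
    optional pinned constraints applied.  Raises
    :class:`InfeasiblePinError` (naming the first conflicting pin) if the
    pins empty the polytope.
    """
    targets = list(reactions) if reactions is not None else network.reaction_ids
    A_eq, bounds = _problem(network, fixed)
    # Feasibility probe before the per-reaction scan.
    status, _, _ = _solve(A_eq, bounds, np.zeros(network.n_reactions), "min")
    if status == "infeasible":
        raise InfeasiblePinError(*_diagnose_pins(network, fixed))
    out: dict[str, FluxRange] = {}
    c = np.zeros(network.n_reactions)
    for rxn_id in targets:
        j = network.reaction_index(rxn_id)
        c[j] = 1.0
        lo_status, lo, _ = _solve(A_eq, bounds, c, "min")
        hi_status, hi, _ = _solve(A_eq, bounds, c, "max")
        c[j] = 0.0
        if lo_status != "optimal" or hi_status != "optimal":  # pragma: no cover
            raise RuntimeError(f"FVA solve failed for {rxn_id}: {lo_status}/{hi_status}")
        if lo > hi:  # solver noise on a point range
            lo = hi = 0.5 * (lo + hi)
        out[rxn_id] = FluxRange(rxn_id, float(lo), float(hi))
    return out


def _diagnose_pins(
    network: MetabolicNetwork, fixed: Optional[Mapping[str, BoundsLike]]
) -> tuple[str, Optional[str]]:
    """Find the first pin whose addition makes the polytope empty."""
    if not fixed:
        return "flux polytope is empty under the model's own bounds", None
    applied: dict[str, BoundsLike] = {}
    for rxn_id, value in fixed.items():
        applied[rxn_id] = value
        A_eq, bounds = _problem(network, applied)
        status, _, _ = _solve(A_eq, bounds, np.zeros(network.n_reactions), "min")
        if status == "infeasible":
            return (
                f"pinned constraint on {rxn_id!r} ({value!r}) makes the model infeasible",
                rxn_id,
            )
    return "pinned constraints jointly infeasible", None


def apply_gene_deletion(
    network: MetabolicNetwork, deleted: Iterable[str]
) -> MetabolicNetwork:
    """Knock out genes: reactions whose GPR evaluates false get bounds [0, 0].

    AND nodes are conjunctions (losing any complex subunit blocks the
    reaction), OR nodes disjunctions (one surviving isozyme keeps it open).
    Reactions without a GPR are untouched.  Unknown gene ids trigger a
    warning and are ignored.
    """
    deleted = set(deleted)
    unknown = deleted - set(network.genes)
    if unknown:
        warnings.warn(f"ignoring unknown gene ids: {sorted(unknown)}", stacklevel=2)
        deleted -= unknown
    present = frozenset(network.genes - deleted)
    blocked = {
        r.id: (0.0, 0.0)
        for r in network.reactions
        if r.gpr is not None and not r.gpr.evaluate(present)
    }
    return network.with_bounds(blocked)


def normalize_fluxes(
    values: Union[LPSolution, Mapping[str, FluxRange]],
    reference: str,
    target: float,
) -> Union[LPSolution, dict[str, FluxRange]]:
    """Rescale all fluxes so the reference reaction's magnitude equals ``target``.

    Used to report fluxes per 10 mmol gDW^-1 h^-1 of substrate uptake.  For
    an :class:`LPSolution` the reference value is that solution's flux; for
    a map of ranges it is the reference range's endpoint of largest
    magnitude.  Scaling preserves S v = 0 (linearity).  A zero reference
    flux is an error.
    """
    if isinstance(values, LPSolution):
        ref = values.fluxes.get(reference)
        if ref is None:
            raise KeyError(f"reference reaction {reference!r} not in solution")
        if abs(ref) < FLUX_ATOL:
            raise ValueError(f"reference flux of {reference!r} is zero")
        factor = target / abs(ref)
        return LPSolution(
            status=values.status,
            objective_value=None
            if values.objective_value is None
            else values.objective_value * factor,
            fluxes={k: v * factor for k, v in values.fluxes.items()},
        )
    ref_range = values.get(reference)
    if ref_range is None:
        raise KeyError(f"reference reaction {reference!r} not in ranges")
    ref = max((ref_range.minimum, ref_range.maximum), key=abs)
    if abs(ref) < FLUX_ATOL:
        raise ValueError(f"reference flux of {reference!r} is zero")
    factor = target / abs(ref)
    return {k: r.scaled(factor) for k, r in values.items()}
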