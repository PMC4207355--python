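"""Synthetic fixture generation and brute-force oracles.

Everything here exists so the rest of the package is testable without any
external model or data download: small branched toy networks with GPR
rules, expression profiles with regulation planted to a prescribed
per-reaction fold change, cycle motifs embedding two- to seven-reaction
thermodynamically infeasible loops, and an LP-free vertex-enumeration
oracle for flux extrema on networks small enough to enumerate.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping, Optional

import numpy as np

from .expression import ExpressionProfile, reaction_fold_change
from .flux_core import fba, fva
from .gpr import GPRExpr
from .network import DEFAULT_BOUND, MetabolicNetwork, MetaboliteRecord, ReactionRecord

__all__ = [
    "FixtureSpec",
    "PlantedRegulation",
    "make_toy_network",
    "plant_regulation",
    "figure_cycle_fixtures",
    "random_network",
    "random_loop_network",
    "bottleneck_fixture",
    "brute_force_flux_extrema",
    "brute_force_ranges",
    "enumerate_vertices",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated toy network.

    The layout is: substrate exchange -> transport -> a mandatory trunk
    chain -> ``n_branches`` parallel chains of ``branch_length`` reactions
    -> a biomass drain consuming one unit of each branch terminus.  GPR
    rules cycle through single genes, two-subunit complexes (AND) and
    isozyme pairs (OR) as enabled.
    """

    n_branches: int = 2
    branch_length: int = 2
    trunk_length: int = 0
    uptake: float = 10.0
    with_isozymes: bool = True
    with_complexes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_branches < 1 or self.branch_length < 1 or self.trunk_length < 0:
            raise ValueError("branches >= 1, branch_length >= 1, trunk_length >= 0")
        if self.uptake <= 0:
            raise ValueError("uptake must be positive")


@dataclass(frozen=True)
class PlantedRegulation:
    """Down-regulation to plant on bottleneck reactions.

    ``fold`` may be a single value in (0, 1) for all targets or a
    per-reaction mapping.  ``decoy_folds`` assigns inert (>= 1) fold
    changes to non-target reactions.  Targets must lie on every
    maximal-biomass pathway — checked at planting time via FVA at the
    pinned biomass optimum.
    """

    targets: frozenset[str]
    fold: float | Mapping[str, float] = 0.5
    decoy_folds: Mapping[str, float] = field(default_factory=dict)

    def fold_for(self, rxn_id: str) -> float:
        value = self.fold[rxn_id] if isinstance(self.fold, Mapping) else self.fold
        if not 0.0 < value < 1.0:
            raise ValueError(f"target fold for {rxn_id!r} must be in (0, 1), got {value}")
        return value

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError("at least one target reaction required")
        bad = {r: f for r, f in self.decoy_folds.items() if f < 1.0}
        if bad:
            raise ValueError(f"decoy folds must be >= 1: {bad}")


_MET_X = {"X": 1}


def _met(met_id: str, compartment: str = "c") -> MetaboliteRecord:
    return MetaboliteRecord(met_id, compartment=compartment, formula=_MET_X, charge=0)


def make_toy_network(spec: FixtureSpec) -> MetabolicNetwork:
    """Generate a feasible branched toy network with positive max biomass.

    For one branch of length 2 (no trunk) this is the 5-reaction chain
    exchange -> transport -> two chain steps -> biomass, with max biomass
    equal to the uptake bound times the unit stoichiometric yield.
    """
    mets = [_met("S_e", "e"), _met("S_c")]
    rxns: list[ReactionRecord] = [
        ReactionRecord("EX_S", {"S_e": -1.0}, -spec.uptake, 0.0),
    ]
    gpr_styles = ["gene"]
    if spec.with_complexes:
        gpr_styles.append("and")
    if spec.with_isozymes:
        gpr_styles.append("or")

    counter = 0

    def next_gpr(rxn_id: str) -> GPRExpr:
        nonlocal counter
        style = gpr_styles[counter % len(gpr_styles)]
        counter += 1
        if style == "gene":
            return GPRExpr.leaf(f"g_{rxn_id}")
        if style == "and":
            return GPRExpr.and_(GPRExpr.leaf(f"g_{rxn_id}_a"), GPRExpr.leaf(f"g_{rxn_id}_b"))
        return GPRExpr.or_(GPRExpr.leaf(f"g_{rxn_id}_a"), GPRExpr.leaf(f"g_{rxn_id}_b"))

    def chain(prefix: str, start: str, length: int) -> str:
        """Append a linear chain of unit reactions; return the last metabolite."""
        prev = start
        for i in range(1, length + 1):
            met_id = f"{prefix}{i}"
            mets.append(_met(met_id))
            rxn_id = f"R_{prefix}{i}"
            rxns.append(
                ReactionRecord(
                    rxn_id,
                    {prev: -1.0, met_id: 1.0},
                    0.0,
                    DEFAULT_BOUND,
                    gpr=next_gpr(rxn_id),
                )
            )
            prev = met_id
        return prev

    rxns.append(
        ReactionRecord("T_S", {"S_e": -1.0, "S_c": 1.0}, 0.0, DEFAULT_BOUND, gpr=next_gpr("T_S"))
    )
    hub = chain("Y", "S_c", spec.trunk_length) if spec.trunk_length else "S_c"
    termini = [chain(f"B{b}_", hub, spec.branch_length) for b in range(1, spec.n_branches + 1)]
    rxns.append(
        ReactionRecord("BIOMASS", {t: -1.0 for t in termini}, 0.0, DEFAULT_BOUND)
    )
    network = MetabolicNetwork(mets, rxns, "BIOMASS", id=f"toy_seed{spec.seed}")
    sol = fba(network)
    if not sol.optimal or sol.objective_value <= 0:  # pragma: no cover - by construction
        raise ValueError(f"generated fixture is infeasible: {spec}")
    return network


# ---------------------------------------------------------------------------
# Planted regulation
# ---------------------------------------------------------------------------

def plant_regulation(
    network: MetabolicNetwork,
    plan: PlantedRegulation,
    seed: int = 0,
) -> tuple[ExpressionProfile, ExpressionProfile]:
    """Build control/stress profiles realizing the planted fold changes.

    Control levels are drawn uniformly from [50, 150].  The GPR combination
    rules are inverted per node: an OR target scales every isozyme's level
    by the fold; an AND target scales only the lowest-expressed subunit
    (still the minimum after scaling down, so the combined level scales
    exactly).  Decoys scale all their leaves, exact for any fold.
    """
    rng = np.random.default_rng(seed)
    control_levels = {g: float(rng.uniform(50.0, 150.0)) for g in sorted(network.genes)}
    stress_levels = dict(control_levels)

    for rxn_id in sorted(plan.targets):
        if not network.has_reaction(rxn_id):
            raise KeyError(f"target reaction {rxn_id!r} not in network")
        gpr = network.reaction(rxn_id).gpr
        if gpr is None:
            raise ValueError(f"target reaction {rxn_id!r} has no GPR")
        _scale_min_path(gpr, plan.fold_for(rxn_id), control_levels, stress_levels)

    for rxn_id, fold in sorted(plan.decoy_folds.items()):
        gpr = network.reaction(rxn_id).gpr
        if gpr is None:
            raise ValueError(f"decoy reaction {rxn_id!r} has no GPR")
        for gene in gpr.genes():
            stress_levels[gene] = control_levels[gene] * fold

    control = ExpressionProfile("control", control_levels)
    stress = ExpressionProfile("stress", stress_levels)

    # Generation-time checks: folds realized exactly; targets forced at optimum.
    for rxn_id in plan.targets:
        gpr = network.reaction(rxn_id).gpr
        got = reaction_fold_change(gpr, control, stress)
        want = plan.fold_for(rxn_id)
        if abs(got - want) > 1e-9:  # pragma: no cover - defensive
            raise RuntimeError(f"planted fold for {rxn_id!r}: wanted {want}, realized {got}")
    _check_targets_on_optimum(network, plan.targets)
    return control, stress


def _scale_min_path(
    gpr: GPRExpr, fold: float, control: dict[str, float], stress: dict[str, float]
) -> None:
    if gpr.kind == "gene":
        stress[gpr.gene] = control[gpr.gene] * fold
    elif gpr.kind == "or":
        for child in gpr.children:
            _scale_min_path(child, fold, control, stress)
    else:  # and: scale the lowest-expressed child; stays minimal after scaling down
        low = min(gpr.children, key=lambda c: c.level(control))
        _scale_min_path(low, fold, control, stress)


def _check_targets_on_optimum(network: MetabolicNetwork, targets: frozenset[str]) -> None:
    if network.biomass_reaction is None:
        raise ValueError("network has no biomass reaction")
    sol = fba(network)
    pin = {network.biomass_reaction: sol.objective_value * (1.0 - 1e-6)}
    biomass_ub = network.reaction(network.biomass_reaction).upper_bound
    ranges = fva(network, targets, fixed={network.biomass_reaction: (pin[network.biomass_reaction], biomass_ub)})
    off = [r for r, fr in ranges.items() if fr.minimum <= 1e-6]
    if off:
        raise ValueError(
            f"targets not on every maximal-biomass pathway (zero flux allowed): {sorted(off)}"
        )


# ---------------------------------------------------------------------------
# Cycle motifs
# ---------------------------------------------------------------------------

def figure_cycle_fixtures() -> dict[str, MetabolicNetwork]:
    """Two networks embedding canonical thermodynamically infeasible loops.

    ``three_cycle``: an aggregate reaction (ACLM) written reversibly next
    to the two elementary steps it lumps (RDMBO, DMBO); running the pair
    forward and the aggregate backward cycles with no net conversion.
    Removing the aggregate reaction eliminates the loop.

    ``seven_cycle``: a seven-reaction loop through aspartate / fumarate /
    malate analogues (ASPA, FH, MDH, MS, SDH, SCS, AAT).  Removing MDH and
    restricting ASPA to the aspartate -> fumarate direction eliminates it.
    """
    B = DEFAULT_BOUND
    three = MetabolicNetwork(
        [_met("S_e", "e"), _met("alac"), _met("dhmb_i"), _met("dhmb")],
        [
            ReactionRecord("EX_S", {"S_e": -1.0}, -10.0, 0.0),
            ReactionRecord("UP", {"S_e": -1.0, "alac": 1.0}, 0.0, B),
            ReactionRecord("RDMBO", {"alac": -1.0, "dhmb_i": 1.0}, 0.0, B),
            ReactionRecord("DMBO", {"dhmb_i": -1.0, "dhmb": 1.0}, 0.0, B),
            ReactionRecord("ACLM", {"alac": -1.0, "dhmb": 1.0}, -B, B),
            ReactionRecord("EX_P", {"dhmb": -1.0}, 0.0, B),
        ],
        id="three_cycle",
    )
    loop_mets = ["asp", "fum", "mal", "oaa", "succ", "succoa", "akg"]
    loop_names = ["ASPA", "FH", "MDH", "MS", "SDH", "SCS", "AAT"]
    mets = [_met("S_e", "e")] + [_met(m) for m in loop_mets]
    rxns = [
        ReactionRecord("EX_S", {"S_e": -1.0}, -10.0, 0.0),
        ReactionRecord("UP", {"S_e": -1.0, "asp": 1.0}, 0.0, B),
        ReactionRecord("EX_P", {"oaa": -1.0}, 0.0, B),
    ]
    for name, src, dst in zip(loop_names, loop_mets, loop_mets[1:] + loop_mets[:1]):
        lb = -B if name == "ASPA" else 0.0
        rxns.append(ReactionRecord(name, {src: -1.0, dst: 1.0}, lb, B))
    seven = MetabolicNetwork(mets, rxns, id="seven_cycle")
    return {"three_cycle": three, "seven_cycle": seven}


# ---------------------------------------------------------------------------
# Random fixtures
# ---------------------------------------------------------------------------

def random_network(seed: int, n_reactions: int = 8) -> MetabolicNetwork:
    """A random bounded network for LP-vs-enumeration cross-checks.

    Random sparse stoichiometry with small integer coefficients, a few
    exchange columns, and bounds containing zero (so the zero flux vector
    keeps the polytope nonempty).
    """
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(3, 6))
    met_ids = [f"m{i}" for i in range(n_mets)]
    mets = [_met(m) for m in met_ids]
    rxns = []
    n_exchanges = max(2, n_reactions // 3)
    for j in range(n_reactions):
        rid = f"r{j}"
        if j < n_exchanges:
            stoich = {met_ids[int(rng.integers(n_mets))]: -1.0}
        else:
            size = int(rng.integers(2, min(4, n_mets) + 1))
            chosen = rng.choice(n_mets, size=size, replace=False)
            stoich = {}
            for i in chosen:
                coeff = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
                stoich[met_ids[int(i)]] = coeff
        lb = float(rng.choice([-10.0, -5.0, 0.0]))
        ub = float(rng.choice([0.0, 5.0, 10.0]))
        if lb > ub:
            lb, ub = ub, lb
        rxns.append(ReactionRecord(rid, stoich, lb, ub))
    return MetabolicNetwork(mets, rxns, id=f"random_{seed}")


def random_loop_network(seed: int) -> tuple[MetabolicNetwork, frozenset[str]]:
    """An acyclic scaffold with one planted internal loop; returns (network, loop ids).

    Half of the seeds plant a duplicate-reaction two-cycle (the equivalent
    pair case), the rest a directed loop of three to five reactions.
    """
    rng = np.random.default_rng(seed)
    B = DEFAULT_BOUND
    mets = [_met("S_e", "e"), _met("a"), _met("b")]
    rxns = [
        ReactionRecord("EX_S", {"S_e": -1.0}, -10.0, 0.0),
        ReactionRecord("UP", {"S_e": -1.0, "a": 1.0}, 0.0, B),
        ReactionRecord("CONV", {"a": -1.0, "b": 1.0}, 0.0, B),
        ReactionRecord("EX_B", {"b": -1.0}, 0.0, B),
    ]
    if rng.random() < 0.5:
        loop = ["DUP_F", "DUP_R"]
        mets.append(_met("c"))
        rxns.append(ReactionRecord("DUP_F", {"a": -1.0, "c": 1.0}, 0.0, B))
        rxns.append(ReactionRecord("DUP_R", {"c": -1.0, "a": 1.0}, 0.0, B))
    else:
        length = int(rng.integers(3, 6))
        loop_mets = [f"l{i}" for i in range(length)]
        mets.extend(_met(m) for m in loop_mets)
        loop = [f"LOOP{i}" for i in range(length)]
        for name, src, dst in zip(loop, loop_mets, loop_mets[1:] + loop_mets[:1]):
            rxns.append(ReactionRecord(name, {src: -1.0, dst: 1.0}, 0.0, B))
        # optional feed from the scaffold into the loop (cannot carry flux
        # at steady state once exchanges are closed)
        if rng.random() < 0.5:
            rxns.append(ReactionRecord("FEED", {"a": -1.0, loop_mets[0]: 1.0}, 0.0, B))
    return MetabolicNetwork(mets, rxns, id=f"loop_{seed}"), frozenset(loop)


def bottleneck_fixture(
    seed: int,
) -> tuple[MetabolicNetwork, ExpressionProfile, ExpressionProfile, str, float]:
    """A toy network with one down-regulated bottleneck on the mandatory trunk.

    Returns (network, control, stress, target reaction id, planted fold).
    The target sits upstream of the branch point, so it lies on every
    maximal-biomass pathway and must surface in the primary core set.
    """
    rng = np.random.default_rng(seed)
    spec = FixtureSpec(
        n_branches=int(rng.integers(1, 4)),
        branch_length=int(rng.integers(1, 4)),
        trunk_length=int(rng.integers(1, 3)),
        uptake=float(rng.choice([5.0, 10.0, 20.0])),
        seed=seed,
    )
    network = make_toy_network(spec)
    trunk = ["T_S"] + [f"R_Y{i}" for i in range(1, spec.trunk_length + 1)]
    target = str(rng.choice(trunk))
    fold = float(rng.uniform(0.2, 0.8))
    decoys = {
        r.id: float(rng.uniform(1.0, 2.0))
        for r in network.reactions
        if r.gpr is not None and r.id != target and rng.random() < 0.5
    }
    plan = PlantedRegulation(frozenset([target]), fold, decoys)
    control, stress = plant_regulation(network, plan, seed=seed + 1)
    return network, control, stress, target, fold


# ---------------------------------------------------------------------------
# Vertex-enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_vertices(network: MetabolicNetwork, tol: float = 1e-9) -> np.ndarray:
    """All vertices of {v : S v = 0, lb <= v <= ub} by basis enumeration.

    A vertex is a basic feasible solution: rank(S) basic variables solved
    from the mass balance with the remaining variables fixed at a bound.
    Exhaustive over variable subsets and bound sign patterns — only viable
    for networks of a dozen reactions or so, which is the point: the
    result is independent of any LP solver.
    """
    S = network.S.toarray()
    lb, ub = network.bounds_arrays()
    M = network.n_reactions
    if M > 14:
        raise ValueError(f"vertex enumeration limited to small networks, got M={M}")
    r = int(np.linalg.matrix_rank(S, tol=1e-9))
    vertices: list[np.ndarray] = []
    for fixed in combinations(range(M), M - r):
        basic = [j for j in range(M) if j not in fixed]
        B = S[:, basic]
        if np.linalg.matrix_rank(B, tol=1e-9) < len(basic):
            continue
        for pattern in product((0, 1), repeat=len(fixed)):
            v = np.empty(M)
            for idx, j in enumerate(fixed):
                v[j] = lb[j] if pattern[idx] == 0 else ub[j]
            rhs = -S[:, list(fixed)] @ v[list(fixed)] if fixed else np.zeros(S.shape[0])
            sol, *_ = np.linalg.lstsq(B, rhs, rcond=None)
            v[basic] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                vertices.append(v)
    if not vertices:
        raise ValueError("flux polytope has no vertices (empty or degenerate)")
    return np.unique(np.round(np.array(vertices), 9), axis=0)


def brute_force_flux_extrema(
    network: MetabolicNetwork, reaction: str
) -> tuple[float, float]:
    """Flux extrema of one reaction over the enumerated vertex set."""
    vertices = enumerate_vertices(network)
    j = network.reaction_index(reaction)
    return float(vertices[:, j].min()), float(vertices[:, j].max())


def brute_force_ranges(network: MetabolicNetwork) -> dict[str, tuple[float, float]]:
    """Flux extrema of every reaction from one vertex enumeration."""
    vertices = enumerate_vertices(network)
    return {
        rxn_id: (float(vertices[:, j].min()), float(vertices[:, j].max()))
        for j, rxn_id in enumerate(network.reaction_ids)
    }
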