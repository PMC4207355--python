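"""Reusable simulation scenarios: phase configuration, redox-unconstrained
variants, gene-knockout yield spaces, and comparison against measured fluxes.

ABE (acetone-butanol-ethanol) fermentation is biphasic: an acidogenic
growth phase producing acetate and butyrate, then a solventogenic phase
that re-assimilates the acids and produces solvents.  The two phases are
modeled as static configurations — the solventogenic one supplies acetate
and butyrate as additional nutrients and blocks acid and amino-acid
export.  Further scenarios cap hydrogenase flux (CO gassing), restrict
ammonia/phosphate uptake to a fraction of the attainable range (cell
recycle), or add free NAD(P)/NAD(P)H interconversion to probe how redox
availability limits production.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import yaml

from .flux_core import FLUX_ATOL, FluxRange, InfeasiblePinError, apply_gene_deletion, fba, fva
from .network import DEFAULT_BOUND, MetabolicNetwork, MetaboliteRecord, ReactionRecord

__all__ = [
    "ScenarioConfig",
    "YieldPoint",
    "MFAComparison",
    "run_scenario",
    "redox_free_variant",
    "restrict_uptake_fraction",
    "yield_space",
    "compare_to_mfa",
    "load_preset",
    "preset_names",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """Declarative description of one simulation condition.

    ``pinned_growth`` is a growth rate in h^-1, the string ``"max"`` (run
    FBA first, then pin the optimum), or ``None`` (no growth constraint).
    ``nutrient_bounds`` override exchange bounds (negative = uptake);
    ``blocked_reactions`` are forced to zero; ``redox_free`` adds the
    cofactor interconversion reactions of :func:`redox_free_variant`.
    """

    phase: str = "acidogenic"  # "acidogenic" | "solventogenic"
    pinned_growth: Optional[float | str] = None
    nutrient_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    blocked_reactions: frozenset[str] = frozenset()
    deleted_genes: frozenset[str] = frozenset()
    redox_free: bool = False
    extra_reactions: tuple[ReactionRecord, ...] = ()
    extra_metabolites: tuple[MetaboliteRecord, ...] = ()

    def __post_init__(self) -> None:
        if self.phase not in ("acidogenic", "solventogenic"):
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass(frozen=True)
class YieldPoint:
    """One grid point of a yield space: product mol per mol substrate taken up."""

    yields: Mapping[str, float]
    feasible: bool
    degenerate: bool = False  # feasible but zero substrate uptake


@dataclass(frozen=True)
class MFAComparison:
    """Verdict for one measured flux against a model-predicted range."""

    reaction_id: str
    measured: float
    range: Optional[FluxRange]
    inside: bool
    distance: float  # 0 when inside; distance to the nearest endpoint otherwise


def _configure(network: MetabolicNetwork, config: ScenarioConfig) -> MetabolicNetwork:
    if config.extra_metabolites or config.extra_reactions:
        network = network.with_extra(config.extra_metabolites, config.extra_reactions)
    if config.redox_free:
        network = redox_free_variant(network)
    if config.deleted_genes:
        network = apply_gene_deletion(network, config.deleted_genes)
    overrides: dict[str, tuple[float, float]] = {}
    for rxn_id in config.blocked_reactions:
        if not network.has_reaction(rxn_id):
            raise KeyError(f"blocked reaction {rxn_id!r} not in network")
        overrides[rxn_id] = (0.0, 0.0)
    for rxn_id, (lo, hi) in config.nutrient_bounds.items():
        if not network.has_reaction(rxn_id):
            raise KeyError(f"nutrient exchange {rxn_id!r} not in network")
        overrides[rxn_id] = (float(lo), float(hi))
    return network.with_bounds(overrides) if overrides else network


def _growth_pin(
    network: MetabolicNetwork, config: ScenarioConfig
) -> Optional[dict[str, tuple[float, float]]]:
    if config.pinned_growth is None:
        return None
    if network.biomass_reaction is None:
        raise ValueError("cannot pin growth: network has no biomass reaction")
    if config.pinned_growth == "max":
        sol = fba(network)
        if not sol.optimal:
            raise InfeasiblePinError(
                f"scenario infeasible before growth pin: FBA status {sol.status}"
            )
        rate = sol.objective_value * (1.0 - 1e-6)
    else:
        rate = float(config.pinned_growth)
    upper = network.reaction(network.biomass_reaction).upper_bound
    return {network.biomass_reaction: (rate, upper)}


def run_scenario(
    network: MetabolicNetwork,
    config: ScenarioConfig,
    products: Sequence[str],
) -> dict[str, FluxRange]:
    """Apply a scenario configuration and report product flux ranges by FVA.

    With an empty config this is plain FVA over the products.  Production
    is a positive exchange flux; a negative range means net consumption.
    """
    model = _configure(network, config)
    pin = _growth_pin(model, config)
    return fva(model, products, fixed=pin)


def redox_free_variant(
    network: MetabolicNetwork,
    nad: str = "nad_c",
    nadh: str = "nadh_c",
    nadp: str = "nadp_c",
    nadph: str = "nadph_c",
    proton: str = "h_c",
) -> MetabolicNetwork:
    """Add unbounded reversible NAD <-> NADH and NADP <-> NADPH interconversion.

    Electrons are implicitly sourced from the environment; the proton
    consumed alongside the hydride keeps H and charge balanced for the
    conventional cofactor formulas (electron balance is deliberately open —
    that is what "no redox constraint" means).  Raises if any cofactor id
    is missing, listing the absences.
    """
    pairs = [("FREE_NADH", nad, nadh), ("FREE_NADPH", nadp, nadph)]
    needed = [m for _, ox, red in pairs for m in (ox, red)]
    missing = [m for m in needed if m not in set(network.metabolite_ids)]
    if missing:
        raise KeyError(f"cofactor metabolites missing from network: {missing}")
    has_proton = proton in set(network.metabolite_ids)
    extra = []
    for rxn_id, ox, red in pairs:
        stoich = {ox: -1.0, red: 1.0}
        if has_proton:
            stoich[proton] = -1.0
        extra.append(ReactionRecord(rxn_id, stoich, -DEFAULT_BOUND, DEFAULT_BOUND))
    return network.with_extra(reactions=extra)


def restrict_uptake_fraction(
    network: MetabolicNetwork,
    exchanges: Iterable[str],
    fraction: float = 0.8,
) -> dict[str, tuple[float, float]]:
    """Cap uptake magnitude at a fraction of the attainable maximum.

    For each exchange, FVA at the wild-type growth optimum gives the most
    negative attainable flux (maximal uptake); the returned bound override
    sets the lower bound to ``fraction`` of that value.  Used for
    cell-recycle conditions (nutrient-limited continuous culture).
    """
    pin = None
    if network.biomass_reaction is not None:
        sol = fba(network)
        if sol.optimal and sol.objective_value > FLUX_ATOL:
            upper = network.reaction(network.biomass_reaction).upper_bound
            pin = {network.biomass_reaction: (sol.objective_value * (1.0 - 1e-6), upper)}
    ranges = fva(network, exchanges, fixed=pin)
    out = {}
    for rxn_id, fr in ranges.items():
        rxn = network.reaction(rxn_id)
        out[rxn_id] = (fraction * fr.minimum, rxn.upper_bound)
    return out


def yield_space(
    network: MetabolicNetwork,
    config: ScenarioConfig,
    nutrient: str,
    products: Sequence[str],
    resolution: int = 5,
) -> list[YieldPoint]:
    """Grid the products' attainable ranges and report yields per substrate.

    At the configured (pinned) growth rate, FVA gives each product's flux
    range; over a regular grid of product flux combinations, the nutrient
    uptake needed to support the point is minimized and the yield is the
    product flux divided by that minimal uptake magnitude.  Infeasible
    grid points are flagged rather than dropped; feasible points with zero
    uptake are flagged degenerate.
    """
    if config.pinned_growth is None:
        raise ValueError("yield_space requires a pinned growth rate")
    if not 2 <= len(products) <= 3:
        raise ValueError("yield_space takes 2 or 3 product exchanges")
    model = _configure(network, config)
    pin = _growth_pin(model, config)
    ranges = fva(model, products, fixed=pin)
    axes = [
        np.linspace(ranges[p].minimum, ranges[p].maximum, resolution) for p in products
    ]
    points: list[YieldPoint] = []
    for combo in np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, len(products)):
        fixed = dict(pin or {})
        for p, value in zip(products, combo):
            fixed[p] = float(value)
        try:
            sol = fba(model, objective=nutrient, sense="max", fixed=fixed)
        except ValueError:  # pragma: no cover - defensive
            sol = None
        if sol is None or not sol.optimal:
            points.append(YieldPoint({p: float("nan") for p in products}, feasible=False))
            continue
        uptake = -sol.objective_value  # least-negative exchange flux = minimal uptake
        if uptake <= FLUX_ATOL:
            points.append(
                YieldPoint({p: float(v) for p, v in zip(products, combo)}, True, degenerate=True)
            )
            continue
        points.append(
            YieldPoint({p: float(v) / uptake for p, v in zip(products, combo)}, True)
        )
    return points


def compare_to_mfa(
    fva_ranges: Mapping[str, FluxRange],
    mfa_values: Mapping[str, float],
) -> list[MFAComparison]:
    """Check measured fluxes against model-predicted ranges.

    Measurements inside their range get distance 0; outside, the distance
    to the nearest endpoint.  Measurements with no matching reaction are
    listed with ``range=None`` rather than raising.
    """
    out = []
    for rxn_id, measured in mfa_values.items():
        fr = fva_ranges.get(rxn_id)
        if fr is None:
            out.append(MFAComparison(rxn_id, measured, None, False, float("nan")))
            continue
        inside = fr.contains(measured)
        if inside:
            distance = 0.0
        else:
            distance = min(abs(measured - fr.minimum), abs(measured - fr.maximum))
        out.append(MFAComparison(rxn_id, measured, fr, inside, distance))
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def preset_names() -> list[str]:
    root = resources.files("coreflux") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str, overrides: Optional[Mapping] = None) -> ScenarioConfig:
    """Load a named scenario preset, optionally overriding fields.

    Presets carry the structure of each condition (phase, growth pin,
    nutrient bounds, blocks); reaction and exchange ids are placeholders
    meant to be overridden to the id namespace of the model in use.
    """
    path = resources.files("coreflux") / "presets" / f"{name}.yaml"
    if not path.is_file():
        raise KeyError(f"unknown preset {name!r}; available: {preset_names()}")
    data = yaml.safe_load(path.read_text())
    if overrides:
        data.update(overrides)
    return ScenarioConfig(
        phase=data.get("phase", "acidogenic"),
        pinned_growth=data.get("pinned_growth"),
        nutrient_bounds={
            k: (float(v[0]), float(v[1])) for k, v in (data.get("nutrient_bounds") or {}).items()
        },
        blocked_reactions=frozenset(data.get("blocked_reactions") or ()),
        deleted_genes=frozenset(data.get("deleted_genes") or ()),
        redox_free=bool(data.get("redox_free", False)),
    )
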