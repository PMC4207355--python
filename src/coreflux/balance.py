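"""Elemental and charge balance checking and H/O/charge rebalancing.

Every proper metabolic reaction must conserve each element and the total
molecular charge.  When a model's curation leaves a reaction short only of
protons, hydroxide, or water, the deficit can be repaired mechanically:
those three species span exactly the (H, O, charge) imbalances satisfying
H = charge + 2*O, so a consistent imbalance has a canonical fix (water for
oxygen, protons for charge) and anything else is flagged for a human.

Metabolites whose formula is unknown or contains generic R-group tokens are
never auto-repaired: R tokens are opaque and must cancel one-to-one across
a reaction, otherwise the reaction is marked unbalanceable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, MutableMapping, Optional

from .network import MetaboliteRecord, ReactionRecord

__all__ = ["BalanceReport", "RebalanceFailure", "check_balance", "rebalance"]

#: Element symbols treated as opaque generic side-chain tokens.
GENERIC_TOKENS = frozenset({"R", "X"})

_ATOL = 1e-9


@dataclass(frozen=True)
class BalanceReport:
    """Per-element and charge imbalance of a reaction (products minus reactants).

    An all-zero report means the reaction is balanced.  ``unbalanceable``
    marks reactions that cannot be assessed or repaired mechanically
    (missing formulas, non-cancelling generic R groups); the ``notes`` say
    why.
    """

    element_imbalance: Mapping[str, float] = field(default_factory=dict)
    charge_imbalance: float = 0.0
    unbalanceable: bool = False
    notes: str = ""

    @property
    def balanced(self) -> bool:
        if self.unbalanceable:
            return False
        return abs(self.charge_imbalance) < _ATOL and all(
            abs(v) < _ATOL for v in self.element_imbalance.values()
        )


@dataclass(frozen=True)
class RebalanceFailure:
    """Why a reaction could not be auto-repaired."""

    reaction_id: str
    reason: str
    offending_elements: tuple[str, ...] = ()


def check_balance(
    reaction: ReactionRecord, metabolites: Mapping[str, MetaboliteRecord]
) -> BalanceReport:
    """Sum coefficient x element-count and coefficient x charge over a reaction.

    Generic R-group tokens are tallied like elements; a nonzero R tally (the
    tokens fail to cancel one-to-one) marks the reaction unbalanceable, as
    does any participating metabolite without a formula or charge.
    """
    element: dict[str, float] = {}
    charge = 0.0
    missing: list[str] = []
    for met_id, coeff in reaction.stoichiometry.items():
        record = metabolites.get(met_id)
        if record is None or record.formula is None or record.charge is None:
            missing.append(met_id)
            continue
        for sym, count in record.formula.items():
            element[sym] = element.get(sym, 0.0) + coeff * count
        charge += coeff * record.charge
    element = {k: v for k, v in element.items() if abs(v) > _ATOL}
    if missing:
        return BalanceReport(
            element, charge, unbalanceable=True,
            notes=f"metabolites without formula/charge: {sorted(missing)}",
        )
    bad_tokens = sorted(set(element) & GENERIC_TOKENS)
    if bad_tokens:
        return BalanceReport(
            element, charge, unbalanceable=True,
            notes=f"generic group tokens do not cancel: {bad_tokens}",
        )
    return BalanceReport(element, charge)


def rebalance(
    reaction: ReactionRecord,
    metabolites: MutableMapping[str, MetaboliteRecord],
    proton_id: str = "h",
    water_id: str = "h2o",
    hydroxide_id: str = "oh",
) -> ReactionRecord | RebalanceFailure:
    """Repair a reaction imbalanced only in H, O, and charge.

    Adds integer multiples of H+ / OH- / H2O so the amended reaction passes
    :func:`check_balance`.  The three species are linearly dependent
    (H2O = H+ + OH-), so a solution exists iff the imbalance satisfies
    H = charge + 2*O; the canonical repair uses water for the oxygen deficit
    and protons for the charge deficit.  Positive additions go to the
    product side, negative to the reactant side.

    The helper species are looked up in ``metabolites`` by formula and
    charge; records are created under the conventional ids if absent (the
    mapping is updated in place).
    """
    report = check_balance(reaction, metabolites)
    if report.unbalanceable:
        return RebalanceFailure(reaction.id, report.notes)
    if report.balanced:
        return reaction

    extra = sorted(set(report.element_imbalance) - {"H", "O"})
    if extra:
        return RebalanceFailure(
            reaction.id,
            f"imbalance in elements other than H/O: {extra}",
            tuple(extra),
        )

    d_h = report.element_imbalance.get("H", 0.0)
    d_o = report.element_imbalance.get("O", 0.0)
    d_q = report.charge_imbalance
    # Additions a*H+ + c*H2O must cancel (d_h, d_o, d_q); consistency
    # requires d_h == d_q + 2*d_o because every helper species obeys
    # H = charge + 2*O.
    if abs(d_h - (d_q + 2.0 * d_o)) > 1e-6:
        return RebalanceFailure(
            reaction.id,
            "H/O/charge imbalance inconsistent with proton/hydroxide/water additions "
            f"(H={d_h:g}, O={d_o:g}, charge={d_q:g})",
        )
    n_water = -d_o
    n_proton = -d_q
    if abs(n_water - round(n_water)) > 1e-6 or abs(n_proton - round(n_proton)) > 1e-6:
        return RebalanceFailure(reaction.id, "no integer proton/water solution")
    n_water = round(n_water)
    n_proton = round(n_proton)

    additions: dict[str, float] = {}
    if n_proton:
        additions[_ensure(metabolites, proton_id, {"H": 1}, 1, "H+")] = n_proton
    if n_water:
        additions[_ensure(metabolites, water_id, {"H": 2, "O": 1}, 0, "H2O")] = n_water

    stoich = dict(reaction.stoichiometry)
    for met_id, n in additions.items():
        stoich[met_id] = stoich.get(met_id, 0.0) + n
        if abs(stoich[met_id]) < _ATOL:
            del stoich[met_id]
    amended = ReactionRecord(
        id=reaction.id,
        stoichiometry=stoich,
        lower_bound=reaction.lower_bound,
        upper_bound=reaction.upper_bound,
        gpr=reaction.gpr,
        name=reaction.name,
    )
    final = check_balance(amended, metabolites)
    if not final.balanced:  # pragma: no cover - defensive
        return RebalanceFailure(reaction.id, f"repair failed to close balance: {final}")
    return amended


def _ensure(
    metabolites: MutableMapping[str, MetaboliteRecord],
    preferred_id: str,
    formula: dict[str, int],
    charge: int,
    name: str,
) -> str:
    """Find a metabolite matching formula+charge, or register one."""
    for record in metabolites.values():
        if record.formula is not None and dict(record.formula) == formula and record.charge == charge:
            return record.id
    if preferred_id not in metabolites:
        metabolites[preferred_id] = MetaboliteRecord(
            id=preferred_id, name=name, formula=formula, charge=charge
        )
    return preferred_id
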