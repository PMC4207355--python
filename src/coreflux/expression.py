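"""Mapping gene expression onto per-reaction fold changes through GPR rules.

Expression levels measured under a control and a stress condition are
combined over each reaction's GPR tree — minimum over complex subunits
(the scarcest subunit limits the enzyme pool), sum over isozyme
transcripts (any isozyme contributes capacity) — and the reaction fold
change c_j is the ratio of the combined stress level to the combined
control level.  Only down-regulation (c_j < 1) tightens flux bounds;
values >= 1 are kept in the map but marked inert, because the unregulated
flux-variability bounds are already the loosest attainable and relaxing
them further changes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

from .gpr import GPRExpr
from .network import MetabolicNetwork

__all__ = [
    "ExpressionProfile",
    "FoldChangeMap",
    "gpr_level",
    "reaction_fold_change",
    "build_fold_change_map",
    "read_expression_tsv",
    "read_fold_change_tsv",
]


@dataclass(frozen=True)
class ExpressionProfile:
    """Non-negative expression levels per gene under one condition."""

    condition: str
    levels: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = {g: v for g, v in self.levels.items() if v < 0}
        if bad:
            raise ValueError(f"negative expression levels in {self.condition!r}: {bad}")

    def get(self, gene: str) -> Optional[float]:
        return self.levels.get(gene)

    def masked(self, significant: Iterable[str]) -> "ExpressionProfile":
        """Keep only significant genes' levels; see build_fold_change_map."""
        keep = set(significant)
        return ExpressionProfile(
            self.condition, {g: v for g, v in self.levels.items() if g in keep}
        )


@dataclass(frozen=True)
class FoldChangeMap:
    """Per-reaction fold changes c_j; unmapped reactions default to 1.

    Regulation acts only through values below 1 (``active``); the full map
    is retained for reporting.
    """

    values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {r: c for r, c in self.values.items() if c <= 0}
        if bad:
            raise ValueError(f"fold changes must be positive: {bad}")

    def get(self, rxn_id: str) -> float:
        return self.values.get(rxn_id, 1.0)

    def is_active(self, rxn_id: str) -> bool:
        return self.get(rxn_id) < 1.0

    @property
    def active_reactions(self) -> frozenset[str]:
        return frozenset(r for r, c in self.values.items() if c < 1.0)

    def deactivated(self, rxn_ids: Iterable[str]) -> "FoldChangeMap":
        """Copy with the given reactions' fold changes reset to 1 (inert)."""
        reset = set(rxn_ids)
        return FoldChangeMap(
            {r: (1.0 if r in reset else c) for r, c in self.values.items()}
        )


def gpr_level(gpr: GPRExpr, profile: ExpressionProfile) -> Optional[float]:
    """Combined expression level of a reaction's gene rule.

    Leaf -> the gene's level; AND -> minimum over children (complex
    subunits); OR -> sum over children (isozymes).  Returns None
    ("undefined") if any needed gene is missing from the profile.
    """
    return gpr.level(profile.levels)


def reaction_fold_change(
    gpr: GPRExpr, control: ExpressionProfile, stress: ExpressionProfile
) -> float:
    """c_j = combined stress level / combined control level.

    Undefined levels (missing genes) and a zero control level both yield
    the neutral c_j = 1: an infinite up-fold is inert anyway, and missing
    data must not invent regulation.
    """
    stress_level = gpr_level(gpr, stress)
    control_level = gpr_level(gpr, control)
    if stress_level is None or control_level is None or control_level == 0.0:
        return 1.0
    return stress_level / control_level


def build_fold_change_map(
    network: MetabolicNetwork,
    control: ExpressionProfile,
    stress: ExpressionProfile,
    significant: Optional[Iterable[str]] = None,
) -> FoldChangeMap:
    """Fold change per GPR-bearing reaction of the network.

    ``significant`` optionally restricts regulation to a set of genes that
    passed upstream differential-expression filtering: genes outside the
    mask contribute their control level under stress, so rules touching
    only unmasked genes come out neutral.
    """
    if significant is not None:
        keep = set(significant)
        merged = dict(control.levels)
        merged.update({g: v for g, v in stress.levels.items() if g in keep})
        stress = ExpressionProfile(stress.condition, merged)
    values = {}
    for rxn in network.reactions:
        if rxn.gpr is None:
            continue
        values[rxn.id] = reaction_fold_change(rxn.gpr, control, stress)
    return FoldChangeMap(values)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str) -> dict[str, ExpressionProfile]:
    """Read a gene-by-condition expression table.

    First column: gene id; each remaining column: one condition's levels.
    Returns a profile per condition keyed by the column label.
    """
    df = pd.read_csv(path, sep="\t")
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    return {
        str(cond): ExpressionProfile(str(cond), df[cond].astype(float).to_dict())
        for cond in df.columns
    }


def read_fold_change_tsv(path: str, condition: str = "stress") -> tuple[ExpressionProfile, ExpressionProfile]:
    """Read a two-column per-gene fold-change table (gene_id, fold_change).

    Interpreted as stress levels against a control of 1 for every gene, so
    the GPR combination rules apply to the fold changes directly.
    """
    df = pd.read_csv(path, sep="\t")
    genes = df.iloc[:, 0].astype(str)
    folds = df.iloc[:, 1].astype(float)
    stress = ExpressionProfile(condition, dict(zip(genes, folds)))
    control = ExpressionProfile("control", {g: 1.0 for g in genes})
    return control, stress
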