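"""Core domain types: metabolites, reactions, genome-scale models.

A :class:`Model` holds the stoichiometric matrix implicitly as per-reaction
metabolite→coefficient maps (negative = consumed).  Flux units are
mmol/gCDW/h throughout; growth rate is 1/h.  Exchange reactions follow the
FBC convention: one extracellular metabolite, negative flux = uptake,
ids prefixed ``EX_``.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from .errors import ModelStructureError, UnknownIdentifierError
from .gpr import GPRExpression, evaluate_gpr

DEFAULT_BOUND = 1000.0

#: canonical biomass-variant keys → reaction-id suffix convention
BIOMASS_VARIANT_KEYS = ("cellobiose", "cellulose", "no_cellulosome")


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: Optional[Dict[str, int]] = None
    charge: Optional[int] = None
    compartment: str = "c"


@dataclass
class Reaction:
    id: str
    name: str = ""
    stoichiometry: Dict[str, float] = field(default_factory=dict)
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gpr: GPRExpression = field(default_factory=GPRExpression)
    is_exchange: bool = False
    subsystem: str = ""

    @property
    def bounds(self) -> Tuple[float, float]:
        return (self.lower_bound, self.upper_bound)

    @bounds.setter
    def bounds(self, lu: Tuple[float, float]) -> None:
        self.lower_bound, self.upper_bound = lu


@dataclass
class Model:
    id: str = "model"
    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    genes: set = field(default_factory=set)
    #: variant key (e.g. "cellobiose") → biomass reaction id
    biomass_variants: Dict[str, str] = field(default_factory=dict)
    #: NGAM pseudo-reaction (ATP hydrolysis), if present
    atp_hydrolysis_reaction: Optional[str] = None
    #: cellodextrin glucose-equivalent pseudo-reactions (cellulose growth)
    cellodextrin_reactions: List[str] = field(default_factory=list)
    compartments: set = field(default_factory=lambda: {"c", "e"})

    # -- construction -------------------------------------------------
    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelStructureError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelStructureError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn
        self.genes |= rxn.gpr.genes()

    # -- views ---------------------------------------------------------
    @property
    def exchanges(self) -> List[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def reaction_ids(self) -> List[str]:
        return list(self.reactions)

    @property
    def active_biomass(self) -> Optional[str]:
        """The biomass variant with open bounds, if exactly one is open."""
        open_ = [
            rid
            for rid in self.biomass_variants.values()
            if self.reactions[rid].upper_bound > 0
        ]
        return open_[0] if len(open_) == 1 else None

    def copy(self) -> "Model":
        return _copy.deepcopy(self)

    # -- stoichiometric matrix -----------------------------------------
    def stoichiometric_matrix(self):
        """Return ``(S, met_index, rxn_index)`` with S sparse CSC (mets × rxns)."""
        met_index = {m: i for i, m in enumerate(self.metabolites)}
        rxn_index = {r: j for j, r in enumerate(self.reactions)}
        rows, cols, vals = [], [], []
        for rid, rxn in self.reactions.items():
            j = rxn_index[rid]
            for mid, coef in rxn.stoichiometry.items():
                rows.append(met_index[mid])
                cols.append(j)
                vals.append(coef)
        S = sp.csc_matrix(
            (vals, (rows, cols)), shape=(len(met_index), len(rxn_index))
        )
        return S, met_index, rxn_index

    def bound_arrays(self):
        lb = np.array([r.lower_bound for r in self.reactions.values()])
        ub = np.array([r.upper_bound for r in self.reactions.values()])
        return lb, ub

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        """Check structural invariants; raise ModelStructureError naming offenders."""
        for rid, rxn in self.reactions.items():
            if not rxn.stoichiometry:
                raise ModelStructureError(f"reaction {rid!r} has empty stoichiometry")
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelStructureError(
                    f"reaction {rid!r} has lower bound {rxn.lower_bound} > "
                    f"upper bound {rxn.upper_bound}"
                )
            for mid, coef in rxn.stoichiometry.items():
                if mid not in self.metabolites:
                    raise ModelStructureError(
                        f"reaction {rid!r} references undeclared species {mid!r}"
                    )
                if coef == 0:
                    raise ModelStructureError(
                        f"reaction {rid!r} has zero coefficient for {mid!r}"
                    )
            if rxn.is_exchange:
                mets = list(rxn.stoichiometry)
                if len(mets) != 1:
                    raise ModelStructureError(
                        f"exchange {rid!r} must reference exactly one metabolite"
                    )
                if self.metabolites[mets[0]].compartment != "e":
                    raise ModelStructureError(
                        f"exchange {rid!r} references non-extracellular {mets[0]!r}"
                    )
            missing = rxn.gpr.genes() - self.genes
            if missing:
                raise ModelStructureError(
                    f"reaction {rid!r} GPR references unknown genes {sorted(missing)}"
                )
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                raise ModelStructureError(
                    f"metabolite {met.id!r} in undeclared compartment "
                    f"{met.compartment!r}"
                )
            if met.formula:
                for elem, cnt in met.formula.items():
                    if cnt < 0:
                        raise ModelStructureError(
                            f"metabolite {met.id!r} has negative {elem} count"
                        )
        for key, rid in self.biomass_variants.items():
            if rid not in self.reactions:
                raise ModelStructureError(
                    f"biomass variant {key!r} points at missing reaction {rid!r}"
                )


def disabled_reactions(model: Model, deleted_genes: Iterable[str]) -> FrozenSet[str]:
    """Reaction ids rendered inactive by the deletion genotype (GPR false)."""
    deleted = frozenset(deleted_genes)
    return frozenset(
        rid
        for rid, rxn in model.reactions.items()
        if not rxn.gpr.is_empty and not evaluate_gpr(rxn.gpr, deleted)
    )


def apply_gene_deletions(model: Model, genes: Iterable[str]) -> Model:
    """Return a copy with bounds (0, 0) on every reaction whose GPR turns false.

    Raises :class:`UnknownIdentifierError` for gene ids absent from the model.
    """
    genes = set(genes)
    unknown = genes - model.genes
    if unknown:
        raise UnknownIdentifierError(
            f"unknown gene id(s): {sorted(unknown)}"
        )
    out = model.copy()
    for rid in disabled_reactions(model, genes):
        out.reactions[rid].bounds = (0.0, 0.0)
    return out


def detect_pseudo_reactions(model: Model) -> None:
    """Populate biomass variants, ATP-hydrolysis and cellodextrin fields by id.

    Conventions: ``BIOMASS_<VARIANT>`` for biomass reactions, ``ATPM`` for the
    ATP-hydrolysis (NGAM) pseudo-reaction, ``CLDX*`` for cellodextrin
    glucose-equivalent pseudo-reactions.
    """
    for rid in model.reactions:
        if rid.startswith("BIOMASS_"):
            key = rid[len("BIOMASS_"):].lower()
            model.biomass_variants[key] = rid
        elif rid == "ATPM":
            model.atp_hydrolysis_reaction = rid
        elif rid.startswith("CLDX"):
            model.cellodextrin_reactions.append(rid)
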