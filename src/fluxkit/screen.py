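"""Mutant growth, medium-supplement rescue, and single-reaction-deletion scans.

Lethality follows the standard 20%-of-wild-type convention: a mutant whose
maximum growth rate falls below 20% of the simulated wild-type value is
called lethal.  Supplement rescues open additional exchange uptakes on top
of the base medium; the reported percentage stays relative to the
*unsupplemented* wild type, which is why rescues can exceed 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .conditions import Condition, set_condition
from .core import DEFAULT_BOUND, Model, apply_gene_deletions
from .errors import FluxkitError, InfeasibleError, UnknownIdentifierError
from .simulate import ObjectiveSpec, fba

LETHALITY_THRESHOLD = 0.20


@dataclass
class MutantSpec:
    label: str
    deleted_genes: Tuple[str, ...] = ()
    base_medium: str = ""
    #: exchange id → max uptake magnitude (default unbounded)
    supplements: Dict[str, float] = None

    def __post_init__(self):
        if self.supplements is None:
            self.supplements = {}


@dataclass
class ScreenResult:
    label: str
    wt_growth: float  # 1/h
    mutant_growth: float  # 1/h
    percent_of_wt: float
    lethal: bool
    threshold: float = LETHALITY_THRESHOLD


def _max_growth(model: Model, biomass_id: str) -> float:
    try:
        sol = fba(model, ObjectiveSpec.single(biomass_id))
    except InfeasibleError:
        return 0.0
    return max(float(sol.objective_value), 0.0)


def _configured(model: Model, condition: Condition) -> Tuple[Model, str]:
    configured = set_condition(model, condition)
    biomass_id = configured.biomass_variants[condition.biomass_variant]
    return configured, biomass_id


def mutant_growth_percent(
    model: Model,
    condition: Condition,
    deleted_genes: Sequence[str],
    threshold: float = LETHALITY_THRESHOLD,
    label: Optional[str] = None,
) -> ScreenResult:
    """Mutant maximum growth as a percentage of wild type, same condition.

    Raises if the wild-type reference itself cannot grow (the percentage
    would be undefined).
    """
    configured, biomass_id = _configured(model, condition)
    wt = _max_growth(configured, biomass_id)
    if wt <= 0:
        raise FluxkitError(
            f"wild type has zero/invalid growth under {condition.name!r}; "
            "percent of WT is undefined"
        )
    mutant = apply_gene_deletions(configured, deleted_genes)
    mut = _max_growth(mutant, biomass_id)
    percent = 100.0 * mut / wt
    return ScreenResult(
        label=label or "+".join(deleted_genes) or "wild-type",
        wt_growth=wt,
        mutant_growth=mut,
        percent_of_wt=percent,
        lethal=percent < 100.0 * threshold,
        threshold=threshold,
    )


def rescue_screen(
    model: Model,
    condition: Condition,
    deleted_genes: Sequence[str],
    supplements: Dict[str, Optional[float]],
    threshold: float = LETHALITY_THRESHOLD,
) -> List[ScreenResult]:
    """Re-screen the mutant with each supplement's uptake opened.

    ``supplements`` maps exchange ids to a maximum uptake magnitude (None =
    unbounded, i.e. the global 1000 mmol/gCDW/h).  Percentages remain
    relative to the unsupplemented wild type.
    """
    configured, biomass_id = _configured(model, condition)
    wt = _max_growth(configured, biomass_id)
    if wt <= 0:
        raise FluxkitError("wild-type reference has zero growth")
    mutant = apply_gene_deletions(configured, deleted_genes)
    results = []
    for rid, magnitude in supplements.items():
        if rid not in mutant.reactions or not mutant.reactions[rid].is_exchange:
            raise UnknownIdentifierError(
                f"supplement {rid!r} is not an exchange reaction of the model"
            )
        supplemented = mutant.copy()
        mag = DEFAULT_BOUND if magnitude is None else float(magnitude)
        rxn = supplemented.reactions[rid]
        rxn.lower_bound = -mag
        growth = _max_growth(supplemented, biomass_id)
        percent = 100.0 * growth / wt
        results.append(
            ScreenResult(
                label=f"{'+'.join(deleted_genes)} + {rid}",
                wt_growth=wt,
                mutant_growth=growth,
                percent_of_wt=percent,
                lethal=percent < 100.0 * threshold,
                threshold=threshold,
            )
        )
    return results


@dataclass
class DeletionCandidate:
    reaction_id: str
    growth: float
    percent_of_wt: float


def single_reaction_deletion_scan(
    model: Model,
    condition: Condition,
    base_deleted_genes: Sequence[str] = (),
    threshold: float = LETHALITY_THRESHOLD,
) -> List[DeletionCandidate]:
    """Additional single-reaction deletions that push growth below threshold·WT.

    Every reaction not already disabled in the base mutant is zeroed in
    turn and growth re-maximised; per-reaction infeasibility is recorded as
    zero growth.  Candidates are returned sorted by residual growth
    (ascending), ties by reaction id.
    """
    configured, biomass_id = _configured(model, condition)
    wt = _max_growth(configured, biomass_id)
    if wt <= 0:
        raise FluxkitError("wild-type reference has zero growth")
    base = apply_gene_deletions(configured, base_deleted_genes)
    candidates = []
    for rid, rxn in base.reactions.items():
        if rid == biomass_id:
            continue
        if rxn.lower_bound == 0 and rxn.upper_bound == 0:
            continue  # already disabled (or blocked by bounds)
        probe = base.copy()
        probe.reactions[rid].bounds = (0.0, 0.0)
        growth = _max_growth(probe, biomass_id)
        if growth < threshold * wt:
            candidates.append(
                DeletionCandidate(
                    reaction_id=rid,
                    growth=growth,
                    percent_of_wt=100.0 * growth / wt,
                )
            )
    candidates.sort(key=lambda c: (c.growth, c.reaction_id))
    return candidates
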