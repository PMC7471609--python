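"""Fold-change-based multi-omics integration.

The protocol compares gene-level log2 fold changes (case vs control, e.g.
from proteomics) against flux fold changes simulated under the two
conditions:

1. bound each condition with its measured exchange fluxes (μ±σ) and apply
   the mutant's gene deletions;
2. compute the unique quadratic-pFBA distribution and (optionally loopless)
   FVA ranges in both conditions;
3. normalise fluxes by the substrate uptake rate, floor tiny magnitudes at
   ε, and form log2 fold changes (pFBA flux and FVA interval centre);
4. map measured gene fold changes onto reactions through the GPR as the
   plain mean over genes with nonzero fold change;
5. a reaction is *consistent* when its measured fold change shares a
   (strict) sign with at least one simulated fold change;
6. report Pearson correlations over the consistent set for both simulation
   types, plus a reaction→measured-FC table consumable by map viewers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import Condition, apply_bound_overrides, build_measured_bounds, set_condition
from .core import Model, apply_gene_deletions
from .errors import FluxkitError, UnknownIdentifierError
from .simulate import FluxDistribution, FluxRange, fva, pfba_quadratic

DEFAULT_EPSILON = 0.0001


@dataclass
class FCProtocolConfig:
    epsilon: float = DEFAULT_EPSILON
    #: designated carbon-source exchange per condition name
    uptake_reaction: Dict[str, str] = field(default_factory=dict)
    loopless: bool = True

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass
class ReactionFCRecord:
    reaction_id: str
    fc_meas: Optional[float]
    fc_pfba: Optional[float]
    fc_fva: Optional[float]
    mapped: bool
    consistent: bool
    genes: Tuple[str, ...] = ()
    flags: Tuple[str, ...] = ()  # "floored_zero", "sign_reversal_pfba", ...


@dataclass
class ConsistencyReport:
    records: List[ReactionFCRecord]
    n_total: int
    n_mapped: int
    n_consistent: int
    pearson_pfba: Optional[float]
    pearson_fva: Optional[float]

    @property
    def consistent_set(self) -> Set[str]:
        return {r.reaction_id for r in self.records if r.consistent}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "reaction_id": r.reaction_id,
                    "fc_meas": r.fc_meas,
                    "fc_pfba": r.fc_pfba,
                    "fc_fva": r.fc_fva,
                    "mapped": r.mapped,
                    "consistent": r.consistent,
                    "genes": ";".join(r.genes),
                    "flags": ";".join(r.flags),
                }
                for r in self.records
            ]
        )

    def escher_table(self) -> pd.DataFrame:
        """Two-column reaction→measured-FC table restricted to the consistent set."""
        return pd.DataFrame(
            [
                {"reaction_id": r.reaction_id, "fc": r.fc_meas}
                for r in self.records
                if r.consistent
            ]
        )


# ---------------------------------------------------------------- arithmetic

def floor_value(x: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """Push magnitudes below ε away from zero, preserving sign.

    Exactly zero maps to +ε — the continuous extension of the positive
    branch — so that "zero in both conditions" yields a fold change of 0.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if x == 0:
        return epsilon
    if 0 < x < epsilon:
        return x + epsilon
    if -epsilon < x < 0:
        return x - epsilon
    return x


def simulated_fc(
    v_mut: float,
    v_wt: float,
    uptake_mut: float,
    uptake_wt: float,
    epsilon: float = DEFAULT_EPSILON,
) -> Tuple[float, Tuple[str, ...]]:
    """log2 fold change of uptake-normalised, floored fluxes (mut vs wt).

    Returns ``(fc, flags)``.  Both normalised fluxes are floored first; when
    their signs agree the fold change is log2(|mut|) − log2(|wt|) (identical
    to the plain log-ratio for positive values).  A sign flip between
    conditions has no defined log ratio; it is reported with the same
    magnitude plus a ``"sign_reversal"`` flag and is excluded from
    correlation downstream.
    """
    if uptake_mut == 0 or uptake_wt == 0:
        raise ValueError("substrate uptake rate must be nonzero")
    flags: List[str] = []
    a = v_mut / abs(uptake_mut)
    b = v_wt / abs(uptake_wt)
    if a == 0 or b == 0:
        flags.append("floored_zero")
    fa = floor_value(a, epsilon)
    fb = floor_value(b, epsilon)
    if (fa > 0) != (fb > 0):
        flags.append("sign_reversal")
    fc = math.log2(abs(fa)) - math.log2(abs(fb))
    return fc, tuple(flags)


def fva_center(v_min: float, v_max: float) -> float:
    """Midpoint of an FVA interval — the scalar used for range shifts."""
    if v_min > v_max + 1e-9:
        raise ValueError(f"v_min {v_min} > v_max {v_max}")
    return 0.5 * (v_min + v_max)


# ---------------------------------------------------------------- mapping

@dataclass
class GeneFCTable:
    """Gene-id → measured log2 fold change; absent genes are unmeasured."""

    values: Dict[str, float]

    def __post_init__(self):
        bad = [g for g, v in self.values.items() if not math.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite fold change for genes {bad[:5]}")

    @classmethod
    def from_tsv(cls, path) -> "GeneFCTable":
        df = pd.read_csv(path, sep="\t")
        if not {"gene_id", "log2fc"} <= set(df.columns):
            raise ValueError("gene FC table needs columns (gene_id, log2fc)")
        return cls({str(r.gene_id): float(r.log2fc) for r in df.itertuples()})

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"gene_id": list(self.values), "log2fc": list(self.values.values())}
        ).to_csv(path, sep="\t", index=False)


def map_gene_fc_to_reactions(
    model: Model, gene_fc: GeneFCTable
) -> Dict[str, Tuple[Optional[float], Tuple[str, ...]]]:
    """Reaction-id → (measured FC, contributing genes G_j).

    G_j is the set of GPR genes with nonzero measured fold change; the
    reaction fold change is their plain mean regardless of AND/OR structure.
    Reactions with empty G_j are unmapped (FC None).  Unmeasured genes are
    treated exactly like measured-but-unchanged ones.
    """
    out = {}
    for rid, rxn in model.reactions.items():
        contributing = tuple(
            sorted(
                g
                for g in rxn.gpr.genes()
                if gene_fc.values.get(g, 0.0) != 0.0
            )
        )
        if contributing:
            fc = float(np.mean([gene_fc.values[g] for g in contributing]))
            out[rid] = (fc, contributing)
        else:
            out[rid] = (None, ())
    return out


def is_consistent(
    fc_meas: Optional[float], fc_pfba: Optional[float], fc_fva: Optional[float]
) -> bool:
    """Strict sign agreement between the measured FC and at least one simulated FC."""
    if fc_meas is None:
        return False
    sims = [s for s in (fc_pfba, fc_fva) if s is not None]
    if fc_meas < 0:
        return any(s < 0 for s in sims)
    if fc_meas > 0:
        return any(s > 0 for s in sims)
    return False


def find_consistent_reactions(records: Iterable[ReactionFCRecord]) -> Set[str]:
    """The consistent set M over a collection of reaction FC records."""
    return {
        r.reaction_id
        for r in records
        if is_consistent(r.fc_meas, r.fc_pfba, r.fc_fva)
    }


# ---------------------------------------------------------------- protocol

def _condition_state(
    model: Model,
    condition: Condition,
    deletions: Sequence[str],
    config: FCProtocolConfig,
) -> Tuple[FluxDistribution, FluxRange, Model]:
    configured = set_condition(model, condition)
    if deletions:
        configured = apply_gene_deletions(configured, deletions)
    overrides = build_measured_bounds(configured, condition)
    constrained = apply_bound_overrides(configured, overrides)
    dist = pfba_quadratic(constrained)
    ranges = fva(constrained, loopless=config.loopless)
    return dist, ranges, constrained


def _pearson(pairs: List[Tuple[float, float]]) -> Optional[float]:
    if len(pairs) < 2:
        return None
    xs, ys = zip(*pairs)
    if len(set(xs)) < 2 or len(set(ys)) < 2:
        return None
    r, _ = stats.pearsonr(xs, ys)
    return float(r)


def run_fc_protocol(
    model: Model,
    condition_wt: Condition,
    condition_mut: Condition,
    deletions_mut: Sequence[str],
    gene_fc: GeneFCTable,
    config: Optional[FCProtocolConfig] = None,
) -> ConsistencyReport:
    """Execute the full fold-change integration pipeline (see module docs)."""
    config = config or FCProtocolConfig()
    eps = config.epsilon

    dist_wt, fva_wt, _ = _condition_state(model, condition_wt, (), config)
    dist_mut, fva_mut, _ = _condition_state(
        model, condition_mut, deletions_mut, config
    )

    def uptake_id(cond: Condition) -> str:
        rid = config.uptake_reaction.get(cond.name)
        if rid is None:
            if len(cond.medium.uptake) == 1:
                rid = next(iter(cond.medium.uptake))
            else:
                raise FluxkitError(
                    f"condition {cond.name!r}: designate the substrate uptake "
                    "exchange in FCProtocolConfig.uptake_reaction"
                )
        if rid not in model.reactions:
            raise UnknownIdentifierError(f"uptake reaction {rid!r} not in model")
        return rid

    up_wt_id, up_mut_id = uptake_id(condition_wt), uptake_id(condition_mut)
    up_pfba_wt = dist_wt[up_wt_id]
    up_pfba_mut = dist_mut[up_mut_id]
    up_fva_wt = fva_center(*fva_wt[up_wt_id])
    up_fva_mut = fva_center(*fva_mut[up_mut_id])
    for val, label in (
        (up_pfba_wt, "wt pFBA"),
        (up_pfba_mut, "mutant pFBA"),
        (up_fva_wt, "wt FVA"),
        (up_fva_mut, "mutant FVA"),
    ):
        if val == 0:
            raise FluxkitError(f"substrate uptake is zero in the {label} solution")

    mapping = map_gene_fc_to_reactions(model, gene_fc)
    records: List[ReactionFCRecord] = []
    for rid in model.reactions:
        fc_p, flags_p = simulated_fc(
            dist_mut[rid], dist_wt[rid], up_pfba_mut, up_pfba_wt, eps
        )
        fc_f, flags_f = simulated_fc(
            fva_center(*fva_mut[rid]),
            fva_center(*fva_wt[rid]),
            up_fva_mut,
            up_fva_wt,
            eps,
        )
        fc_m, genes = mapping[rid]
        flags = tuple(
            sorted(
                {f"{fl}_pfba" for fl in flags_p} | {f"{fl}_fva" for fl in flags_f}
            )
        )
        consistent = is_consistent(fc_m, fc_p, fc_f)
        records.append(
            ReactionFCRecord(
                reaction_id=rid,
                fc_meas=fc_m,
                fc_pfba=fc_p,
                fc_fva=fc_f,
                mapped=fc_m is not None,
                consistent=consistent,
                genes=genes,
                flags=flags,
            )
        )

    consistent_records = [r for r in records if r.consistent]
    pairs_pfba = [
        (r.fc_meas, r.fc_pfba)
        for r in consistent_records
        if "sign_reversal_pfba" not in r.flags
    ]
    pairs_fva = [
        (r.fc_meas, r.fc_fva)
        for r in consistent_records
        if "sign_reversal_fva" not in r.flags
    ]
    return ConsistencyReport(
        records=records,
        n_total=len(records),
        n_mapped=sum(r.mapped for r in records),
        n_consistent=len(consistent_records),
        pearson_pfba=_pearson(pairs_pfba),
        pearson_fva=_pearson(pairs_fva),
    )
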