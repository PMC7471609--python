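"""Growth conditions: media, biomass variants, GAM/NGAM, measured fluxes.

A :class:`Condition` captures one fermentation state k: reactor mode,
carbon source, which biomass variant is active, the growth- and
non-growth-associated maintenance parameters, the medium (allowed uptakes
with maximum magnitudes and allowed secretions), and the table of measured
exchange fluxes (mean μ_jk ± sd σ_jk, mmol/gCDW/h; growth rate in 1/h).

Measured fluxes constrain the model as l = μ − σ, u = μ + σ, which for
triplicate normally-distributed measurements gives better than 90%
confidence coverage.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Set, Tuple, Union

import pandas as pd
import yaml

from .core import DEFAULT_BOUND, Model
from .errors import ModelStructureError, UnknownIdentifierError

#: species adjusted when installing GAM into a biomass reaction
#: (ATP hydrolysis: atp + h2o -> adp + pi + h); species absent from the
#: model are skipped so reduced toy models still work.
GAM_SPECIES = {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1}

#: measured-table alias resolving to the condition's active biomass reaction
GROWTH_ALIASES = ("growth", "biomass")


@dataclass
class Medium:
    #: exchange id → maximum uptake magnitude (mmol/gCDW/h)
    uptake: Dict[str, float] = field(default_factory=dict)
    #: exchange ids allowed to secrete
    secretion: Set[str] = field(default_factory=set)


@dataclass
class Condition:
    name: str
    reactor_mode: str = "batch"  # "batch" | "chemostat"
    carbon_source: str = "cellobiose"  # "cellobiose" | "cellulose"
    biomass_variant: str = "cellobiose"
    gam: Optional[float] = None  # mmol ATP/gCDW
    ngam: Optional[float] = None  # mmol ATP/gCDW/h
    #: reaction id (or growth alias) → (mean, sd)
    measured: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    medium: Medium = field(default_factory=Medium)

    def replace(self, **kw) -> "Condition":
        return replace(self, **kw)

    def validate(self, model: Model) -> None:
        if self.biomass_variant not in model.biomass_variants:
            raise ModelStructureError(
                f"condition {self.name!r} names biomass variant "
                f"{self.biomass_variant!r}, not in model "
                f"{sorted(model.biomass_variants)}"
            )
        if self.gam is not None and self.gam < 0:
            raise ModelStructureError("gam must be >= 0")
        if self.ngam is not None and self.ngam < 0:
            raise ModelStructureError("ngam must be >= 0")
        exchange_ids = set(model.exchanges)
        for rid in list(self.medium.uptake) + list(self.medium.secretion):
            if rid not in exchange_ids:
                raise UnknownIdentifierError(
                    f"medium references unknown exchange {rid!r}"
                )
        biomass_ids = set(model.biomass_variants.values())
        for rid, (mean, sd) in self.measured.items():
            if sd < 0:
                raise ModelStructureError(f"measured sd for {rid!r} is negative")
            if rid in GROWTH_ALIASES:
                continue
            if rid not in exchange_ids and rid not in biomass_ids:
                raise UnknownIdentifierError(
                    f"measured flux references unknown reaction {rid!r} "
                    "(must be an exchange or biomass reaction)"
                )


# ---------------------------------------------------------------- file I/O

def read_measured_fluxes(path: Union[str, os.PathLike]) -> Dict[str, Tuple[float, float]]:
    """TSV with columns (reaction_id, mean, sd) → measured-flux map."""
    df = pd.read_csv(path, sep="\t")
    required = {"reaction_id", "mean", "sd"}
    if not required <= set(df.columns):
        raise ValueError(f"measured flux table needs columns {sorted(required)}")
    return {
        str(r.reaction_id): (float(r.mean), float(r.sd)) for r in df.itertuples()
    }


def load_condition(path: Union[str, os.PathLike]) -> Condition:
    """Load a condition from YAML or JSON.

    Expected keys: name, reactor_mode, carbon_source, biomass_variant, gam,
    ngam, medium.uptake (map), medium.secretion (list), measured (map of
    reaction_id → [mean, sd], or a path to a TSV flux table relative to the
    condition file).
    """
    path = os.fspath(path)
    with open(path) as fh:
        raw = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    med = raw.get("medium", {}) or {}
    medium = Medium(
        uptake={k: float(v) for k, v in (med.get("uptake") or {}).items()},
        secretion=set(med.get("secretion") or []),
    )
    measured_raw = raw.get("measured", {}) or {}
    if isinstance(measured_raw, str):
        measured = read_measured_fluxes(
            os.path.join(os.path.dirname(path), measured_raw)
        )
    else:
        measured = {
            k: (float(v[0]), float(v[1])) for k, v in measured_raw.items()
        }
    return Condition(
        name=raw.get("name", os.path.basename(path)),
        reactor_mode=raw.get("reactor_mode", "batch"),
        carbon_source=raw.get("carbon_source", "cellobiose"),
        biomass_variant=raw.get("biomass_variant", "cellobiose"),
        gam=None if raw.get("gam") is None else float(raw["gam"]),
        ngam=None if raw.get("ngam") is None else float(raw["ngam"]),
        measured=measured,
        medium=medium,
    )


def save_condition(condition: Condition, path: Union[str, os.PathLike]) -> None:
    raw = {
        "name": condition.name,
        "reactor_mode": condition.reactor_mode,
        "carbon_source": condition.carbon_source,
        "biomass_variant": condition.biomass_variant,
        "gam": condition.gam,
        "ngam": condition.ngam,
        "medium": {
            "uptake": dict(condition.medium.uptake),
            "secretion": sorted(condition.medium.secretion),
        },
        "measured": {k: [m, s] for k, (m, s) in condition.measured.items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


# ---------------------------------------------------------------- application

def install_gam(model: Model, biomass_id: str, gam: float) -> None:
    """Set the ATP-hydrolysis stoichiometry inside a biomass reaction to ``gam``.

    The current ATP coefficient magnitude is replaced by ``gam``; the
    partner species (h2o, adp, pi, h) that exist in the model are adjusted
    by the same delta so the hydrolysis stays internally consistent.
    Mutates ``model`` in place.
    """
    rxn = model.reactions[biomass_id]
    current = -rxn.stoichiometry.get("atp_c", 0.0)
    delta = gam - current
    if delta == 0:
        return
    for species, sign in GAM_SPECIES.items():
        if species in model.metabolites:
            new = rxn.stoichiometry.get(species, 0.0) + sign * delta
            if new == 0:
                rxn.stoichiometry.pop(species, None)
            else:
                rxn.stoichiometry[species] = new


def set_condition(model: Model, condition: Condition) -> Model:
    """Return a copy of ``model`` configured for ``condition``.

    Activates the condition's biomass variant (others closed), installs GAM
    into its stoichiometry and NGAM as the ATP-hydrolysis lower bound,
    closes every exchange uptake/secretion not allowed by the medium, and
    for cellulose growth opens the cellodextrin glucose-equivalent
    pseudo-reactions.
    """
    condition.validate(model)
    out = model.copy()
    # biomass variants: exactly one active
    active = out.biomass_variants[condition.biomass_variant]
    for key, rid in out.biomass_variants.items():
        out.reactions[rid].bounds = (0.0, DEFAULT_BOUND if rid == active else 0.0)
    if condition.gam is not None:
        install_gam(out, active, condition.gam)
    if condition.ngam is not None and out.atp_hydrolysis_reaction:
        atpm = out.reactions[out.atp_hydrolysis_reaction]
        atpm.bounds = (condition.ngam, max(DEFAULT_BOUND, condition.ngam))
    for rid in out.exchanges:
        rxn = out.reactions[rid]
        lb = -condition.medium.uptake.get(rid, 0.0)
        ub = DEFAULT_BOUND if rid in condition.medium.secretion else 0.0
        rxn.bounds = (lb, ub)
    if condition.carbon_source == "cellulose":
        for rid in out.cellodextrin_reactions:
            out.reactions[rid].bounds = (0.0, DEFAULT_BOUND)
    else:
        for rid in out.cellodextrin_reactions:
            out.reactions[rid].bounds = (0.0, 0.0)
    return out


def resolve_measured_id(model: Model, condition: Condition, rid: str) -> str:
    if rid in GROWTH_ALIASES:
        return model.biomass_variants[condition.biomass_variant]
    return rid


def build_measured_bounds(
    model: Model, condition: Condition
) -> Dict[str, Tuple[float, float]]:
    """Bound overrides l = μ − σ, u = μ + σ for each measured reaction.

    Growth aliases resolve to the condition's biomass variant.  The model
    itself is not mutated.  Unknown reaction ids raise
    :class:`UnknownIdentifierError`.
    """
    if not condition.measured:
        raise ValueError(f"condition {condition.name!r} has no measured fluxes")
    overrides = {}
    for rid, (mean, sd) in condition.measured.items():
        resolved = resolve_measured_id(model, condition, rid)
        if resolved not in model.reactions:
            raise UnknownIdentifierError(
                f"measured reaction {resolved!r} absent from model"
            )
        overrides[resolved] = (mean - sd, mean + sd)
    return overrides


def apply_bound_overrides(
    model: Model, overrides: Mapping[str, Tuple[float, float]]
) -> Model:
    """Return a copy with the given (lower, upper) overrides applied."""
    out = model.copy()
    for rid, (lb, ub) in overrides.items():
        if rid not in out.reactions:
            raise UnknownIdentifierError(f"unknown reaction {rid!r}")
        out.reactions[rid].bounds = (lb, ub)
    return out
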