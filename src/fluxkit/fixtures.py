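"""Deterministic toy models and synthetic datasets.

Two toy topologies are generated:

* a **linear chain with parallel routes** — substrate uptake drives a chain
  of conversions generating ATP, then splits across parallel routes before
  secretion; used for LP/QP contract tests and maintenance training data.
* a **redox fermentation core** — a miniature of the *C. thermocellum*
  pyruvate/redox node: lumped glycolysis, pyruvate-ferredoxin
  oxidoreductase vs pyruvate-formate lyase, ethanol and acetate branches,
  three hydrogenases (ferredoxin-dependent ECH, electron-bifurcating BIF
  and an NADPH-linked H2ASE, the latter two requiring a shared maturase
  gene, mimicking *hydG* genotypes), RNF and NFN oxidoreductases, and a
  ketoisovalerate→isobutanol NADPH sink usable as a medium-supplement
  rescue.  Stoichiometries are simplified (proton/water-free) versions of
  the corresponding genome-scale reactions.

Generators are pure functions of their spec and seed.  Fluxes are
mmol/gCDW/h; fixture magnitudes encode topology and statistics, not
quantitative realism of the organism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .conditions import Condition, Medium, apply_bound_overrides, build_measured_bounds, set_condition
from .core import DEFAULT_BOUND, Metabolite, Model, Reaction, apply_gene_deletions, detect_pseudo_reactions
from .errors import FluxkitError
from .gpr import parse_gpr
from .omics import GeneFCTable, simulated_fc
from .simulate import ObjectiveSpec, fba, pfba_quadratic

DEFAULT_GAM = 12.0  # mmol ATP/gCDW, toy biomass ATP coefficient
DEFAULT_NGAM = 2.0  # mmol ATP/gCDW/h


@dataclass
class ToyModelSpec:
    seed: int = 0
    chain_length: int = 3
    parallel_routes: int = 2
    include_redox: bool = False
    include_cycle: bool = False
    biomass_atp: float = DEFAULT_GAM  # plays GAM
    atp_per_substrate: float = 4.0  # chain topology only


@dataclass
class SyntheticOmicsSpec:
    seed: int = 0
    deleted_genes: Tuple[str, ...] = ("hydG", "ech")
    up_reactions: Optional[Tuple[str, ...]] = None  # planted; None = auto-select
    down_reactions: Optional[Tuple[str, ...]] = None
    sign_flip_reactions: Tuple[str, ...] = ()
    fc_magnitude: float = 1.0
    exact_magnitudes: bool = True
    unmeasured_fraction: float = 0.0
    noise_sd: float = 0.0
    max_planted_per_sign: int = 4
    uptake: float = 10.0
    growth_fraction: float = 0.95  # of max growth, pinned as "measured"


# ------------------------------------------------------------ toy models

def _met(model: Model, mid: str, compartment: str) -> None:
    model.add_metabolite(Metabolite(id=mid, compartment=compartment))


def _rxn(
    model: Model,
    rid: str,
    stoich: Dict[str, float],
    lb: float = 0.0,
    ub: float = DEFAULT_BOUND,
    gpr: str = "",
    exchange: bool = False,
) -> None:
    model.add_reaction(
        Reaction(
            id=rid,
            stoichiometry=dict(stoich),
            lower_bound=lb,
            upper_bound=ub,
            gpr=parse_gpr(gpr),
            is_exchange=exchange,
        )
    )


def _add_biomass_variants(model: Model, precursors: Dict[str, float], gam: float):
    """Three variants differing in precursor demand (cellulose costs more)."""
    scale = {"CELLOBIOSE": 1.0, "CELLULOSE": 1.1, "NO_CELLULOSOME": 0.9}
    for suffix, factor in scale.items():
        stoich = {m: c * factor for m, c in precursors.items()}
        stoich["atp_c"] = stoich.get("atp_c", 0.0) - gam
        stoich["adp_c"] = stoich.get("adp_c", 0.0) + gam
        stoich["pi_c"] = stoich.get("pi_c", 0.0) + gam
        _rxn(model, f"BIOMASS_{suffix}", stoich, 0.0, DEFAULT_BOUND)


def _add_cycle(model: Model) -> None:
    _met(model, "cyc1_c", "c")
    _met(model, "cyc2_c", "c")
    _rxn(model, "CYCA", {"cyc1_c": -1, "cyc2_c": 1})
    _rxn(model, "CYCB", {"cyc2_c": -1, "cyc1_c": 1})


def _chain_model(spec: ToyModelSpec) -> Model:
    if spec.parallel_routes < 1:
        raise FluxkitError("parallel_routes must be >= 1")
    if spec.chain_length < 1:
        raise FluxkitError("chain_length must be >= 1")
    model = Model(id=f"toy_chain_L{spec.chain_length}_R{spec.parallel_routes}")
    for mid in ("a_e", "q_e"):
        _met(model, mid, "e")
    for mid in ("atp_c", "adp_c", "pi_c", "q_c"):
        _met(model, mid, "c")
    k = spec.atp_per_substrate
    _rxn(model, "EX_a_e", {"a_e": -1}, -10.0, 0.0, exchange=True)
    _rxn(model, "EX_q_e", {"q_e": -1}, 0.0, DEFAULT_BOUND, exchange=True)
    chain_mets = [f"x{i}_c" for i in range(1, spec.chain_length + 1)]
    for mid in chain_mets:
        _met(model, mid, "c")
    _rxn(
        model,
        "UPT",
        {"a_e": -1, "adp_c": -k, "pi_c": -k, chain_mets[0]: 1, "atp_c": k},
        gpr="g_upt",
    )
    for i in range(len(chain_mets) - 1):
        _rxn(
            model,
            f"CHAIN{i + 1}",
            {chain_mets[i]: -1, chain_mets[i + 1]: 1},
            gpr=f"g_chain{i + 1}",
        )
    last = chain_mets[-1]
    for r in range(1, spec.parallel_routes + 1):
        _rxn(model, f"ROUTE{r}", {last: -1, "q_c": 1}, gpr=f"g_route{r}")
    _rxn(model, "SEC", {"q_c": -1, "q_e": 1}, gpr="g_sec")
    _rxn(model, "ATPM", {"atp_c": -1, "adp_c": 1, "pi_c": 1})
    _add_biomass_variants(model, {"q_c": -1.0}, spec.biomass_atp)
    return model


def _redox_model(spec: ToyModelSpec) -> Model:
    model = Model(id="toy_redox_core")
    for mid in ("cellb_e", "co2_e", "for_e", "eth_e", "ac_e", "h2_e",
                "kiv_e", "ibuoh_e"):
        _met(model, mid, "e")
    for mid in ("cellb_c", "pyr_c", "accoa_c", "fdxo_c", "fdxr_c", "nad_c",
                "nadh_c", "nadp_c", "nadph_c", "atp_c", "adp_c", "pi_c"):
        _met(model, mid, "c")
    _rxn(model, "EX_cellb_e", {"cellb_e": -1}, -10.0, 0.0, exchange=True)
    for mid in ("co2", "for", "eth", "ac", "h2", "ibuoh"):
        _rxn(model, f"EX_{mid}_e", {f"{mid}_e": -1}, 0.0, DEFAULT_BOUND,
             exchange=True)
    _rxn(model, "EX_kiv_e", {"kiv_e": -1}, 0.0, 0.0, exchange=True)
    _rxn(model, "CBT", {"cellb_e": -1, "cellb_c": 1}, gpr="cbt")
    _rxn(model, "GLYC",
         {"cellb_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
          "pyr_c": 2, "atp_c": 2, "nadh_c": 2}, gpr="glyA")
    _rxn(model, "POR",
         {"pyr_c": -1, "fdxo_c": -1, "accoa_c": 1, "fdxr_c": 1, "co2_e": 1},
         gpr="por")
    _rxn(model, "PFL", {"pyr_c": -1, "accoa_c": 1, "for_e": 1}, gpr="pfl")
    _rxn(model, "ALCD",
         {"accoa_c": -1, "nadh_c": -2, "eth_e": 1, "nad_c": 2}, gpr="adhE")
    _rxn(model, "ACK",
         {"accoa_c": -1, "adp_c": -1, "pi_c": -1, "ac_e": 1, "atp_c": 1},
         gpr="ack")
    _rxn(model, "ECH", {"fdxr_c": -1, "fdxo_c": 1, "h2_e": 1}, gpr="ech")
    _rxn(model, "BIF",
         {"fdxr_c": -1, "nadh_c": -1, "fdxo_c": 1, "nad_c": 1, "h2_e": 2},
         gpr="bif and hydG")
    _rxn(model, "H2ASE", {"nadph_c": -1, "nadp_c": 1, "h2_e": 1},
         gpr="h2ase and hydG")
    _rxn(model, "RNF", {"fdxr_c": -1, "nad_c": -1, "fdxo_c": 1, "nadh_c": 1},
         gpr="rnf")
    _rxn(model, "NFN",
         {"fdxr_c": -1, "nadh_c": -1, "nadp_c": -2,
          "fdxo_c": 1, "nad_c": 1, "nadph_c": 2}, gpr="nfn")
    _rxn(model, "KIVR",
         {"kiv_e": -1, "nadph_c": -1, "ibuoh_e": 1, "nadp_c": 1}, gpr="kivd")
    _rxn(model, "ATPM", {"atp_c": -1, "adp_c": 1, "pi_c": 1})
    _add_biomass_variants(
        model, {"pyr_c": -1.0, "nadh_c": -1.0, "nad_c": 1.0,
                "nadph_c": -0.2, "nadp_c": 0.2},
        spec.biomass_atp,
    )
    return model


def make_toy_core_model(spec: Optional[ToyModelSpec] = None) -> Model:
    """Build the toy model described by ``spec`` (deterministic per spec)."""
    spec = spec or ToyModelSpec()
    model = _redox_model(spec) if spec.include_redox else _chain_model(spec)
    if spec.include_cycle:
        _add_cycle(model)
    detect_pseudo_reactions(model)
    model.validate()
    return model


# ------------------------------------------------------------ conditions

def toy_condition(
    model: Model,
    name: str = "batch_cellobiose",
    uptake: float = 10.0,
    gam: float = DEFAULT_GAM,
    ngam: float = DEFAULT_NGAM,
    reactor_mode: str = "batch",
    biomass_variant: str = "cellobiose",
) -> Condition:
    """Standard batch condition for either toy topology.

    Substrate uptake is capped at ``uptake``; every other exchange except
    the ketoisovalerate supplement may secrete freely.
    """
    substrate = "EX_cellb_e" if "EX_cellb_e" in model.reactions else "EX_a_e"
    secretion = {
        rid for rid in model.exchanges if rid not in (substrate, "EX_kiv_e")
    }
    return Condition(
        name=name,
        reactor_mode=reactor_mode,
        carbon_source="cellobiose",
        biomass_variant=biomass_variant,
        gam=gam,
        ngam=ngam,
        medium=Medium(uptake={substrate: uptake}, secretion=secretion),
    )


# ------------------------------------------------------------ maintenance

def make_maintenance_dataset(
    model: Model,
    gam: float,
    ngam: float,
    growth_rates: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> List[Condition]:
    """Synthetic training conditions with known maintenance parameters.

    For each growth rate μ the ATP demand gam·μ + ngam is perturbed with
    seeded Gaussian noise (sd ``noise_sd``, mmol ATP/gCDW/h) and the
    substrate uptake consistent with that demand is derived from the chain
    model's ATP yield per substrate.  Measured tables carry the substrate
    exchange (mean ± the induced sd) and the growth rate.
    """
    if gam < 0 or ngam < 0:
        raise ValueError("gam and ngam must be >= 0")
    if not growth_rates:
        raise ValueError("growth rate list is empty")
    if "UPT" not in model.reactions:
        raise FluxkitError("maintenance dataset needs the chain toy model")
    k = model.reactions["UPT"].stoichiometry["atp_c"]
    rng = np.random.default_rng(seed)
    conditions = []
    for i, mu in enumerate(growth_rates):
        if mu < 0:
            raise ValueError("growth rates must be >= 0")
        u = (gam * mu + ngam) / k
        if u < mu:  # substrate also supplies the biomass precursor
            raise FluxkitError(
                f"growth rate {mu} infeasible: uptake {u:.3g} cannot cover "
                "both ATP demand and precursor demand"
            )
        demand_noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        u_noisy = u + demand_noise / k
        cond = toy_condition(
            model,
            name=f"train_{i}",
            uptake=max(u_noisy + 1.0, 2 * u),
            gam=gam,
            ngam=ngam,
        )
        cond.measured = {
            "EX_a_e": (-u_noisy, noise_sd / k if noise_sd > 0 else 0.0),
            "growth": (mu, 0.0),
        }
        conditions.append(cond)
    return conditions


# ------------------------------------------------------------ omics

def make_omics_dataset(
    model: Model, spec: Optional[SyntheticOmicsSpec] = None
) -> Tuple[GeneFCTable, Condition, Condition, Set[str]]:
    """Gene-FC table, wt/mutant conditions, and the planted consistent set.

    The wild-type and mutant states are pinned by "measured" uptake and
    growth (a fixed fraction of each strain's maximum); gene fold changes
    are planted on branches whose simulated flux genuinely shifts between
    the states, with signs matching (or deliberately flipped for
    ``sign_flip_reactions``).  The returned set is the ground truth the
    integration protocol should recover at zero noise.
    """
    spec = spec or SyntheticOmicsSpec()
    rng = np.random.default_rng(spec.seed)

    def pinned_condition(name: str, deletions: Sequence[str]) -> Condition:
        cond = toy_condition(model, name=name, uptake=spec.uptake)
        configured = set_condition(model, cond)
        if deletions:
            configured = apply_gene_deletions(configured, deletions)
        bid = configured.biomass_variants[cond.biomass_variant]
        growth = fba(configured, ObjectiveSpec.single(bid)).objective_value
        if growth <= 0:
            raise FluxkitError(
                f"state {name!r} cannot grow; omics fixture needs growth"
            )
        substrate = next(iter(cond.medium.uptake))
        cond.measured = {
            substrate: (-spec.uptake, 0.0),
            "growth": (spec.growth_fraction * growth, 0.0),
        }
        return cond

    cond_wt = pinned_condition("wt", ())
    cond_mut = pinned_condition("mut", spec.deleted_genes)

    def pinned_fluxes(cond: Condition, deletions: Sequence[str]):
        configured = set_condition(model, cond)
        if deletions:
            configured = apply_gene_deletions(configured, deletions)
        overrides = build_measured_bounds(configured, cond)
        return pfba_quadratic(apply_bound_overrides(configured, overrides))

    v_wt = pinned_fluxes(cond_wt, ())
    v_mut = pinned_fluxes(cond_mut, spec.deleted_genes)
    substrate = next(iter(cond_wt.medium.uptake))
    true_fc: Dict[str, float] = {}
    for rid in model.reactions:
        fc, flags = simulated_fc(
            v_mut[rid], v_wt[rid], v_mut[substrate], v_wt[substrate]
        )
        true_fc[rid] = 0.0 if "sign_reversal" in flags else fc

    # choose planted branches among gene-associated reactions with a real
    # shift; genes must be exclusive to their reaction so the planted fold
    # change maps back onto exactly that reaction
    gene_use: Dict[str, int] = {}
    for rxn in model.reactions.values():
        for g in rxn.gpr.genes():
            gene_use[g] = gene_use.get(g, 0) + 1
    if spec.up_reactions is None or spec.down_reactions is None:
        ups: List[str] = []
        downs: List[str] = []
        for rid, rxn in model.reactions.items():
            genes = rxn.gpr.genes()
            if not genes or abs(true_fc[rid]) < 0.2:
                continue
            if any(gene_use[g] > 1 for g in genes):
                continue
            target = ups if true_fc[rid] > 0 else downs
            if len(target) >= spec.max_planted_per_sign:
                continue
            target.append(rid)
        up_reactions = tuple(ups) if spec.up_reactions is None else spec.up_reactions
        down_reactions = (
            tuple(downs) if spec.down_reactions is None else spec.down_reactions
        )
    else:
        up_reactions, down_reactions = spec.up_reactions, spec.down_reactions
    if set(up_reactions) & set(down_reactions):
        raise FluxkitError("planted up/down sets must be disjoint")

    gene_values: Dict[str, float] = {}
    for rid in tuple(up_reactions) + tuple(down_reactions):
        rxn = model.reactions.get(rid)
        if rxn is None or rxn.gpr.is_empty:
            raise FluxkitError(
                f"planted reaction {rid!r} missing or has no gene association"
            )
        base = (
            true_fc[rid]
            if spec.exact_magnitudes
            else math.copysign(spec.fc_magnitude, true_fc[rid])
        )
        if rid in spec.sign_flip_reactions:
            base = -base
        for g in sorted(rxn.gpr.genes()):
            value = base + (rng.normal(0, spec.noise_sd) if spec.noise_sd else 0.0)
            gene_values.setdefault(g, value)

    for g in sorted(model.genes - set(gene_values)):
        if rng.random() >= spec.unmeasured_fraction:
            gene_values[g] = 0.0  # measured but unchanged

    # ground truth: planted, mapped, measured sign equal to the true shift sign
    expected: Set[str] = set()
    for rid in tuple(up_reactions) + tuple(down_reactions):
        genes = [
            g
            for g in model.reactions[rid].gpr.genes()
            if gene_values.get(g, 0.0) != 0.0
        ]
        if not genes:
            continue
        meas = float(np.mean([gene_values[g] for g in genes]))
        if meas != 0 and true_fc[rid] != 0 and (meas > 0) == (true_fc[rid] > 0):
            expected.add(rid)

    return GeneFCTable(gene_values), cond_wt, cond_mut, expected
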