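"""Contracts of FBA, quadratic flux minimisation, and (loopless) FVA.

Hand-derived optima on the fixtures serve as oracles: on the chain toy
with uptake capped at 10 and 4 ATP per substrate, maximum secretion is 10
and maximum growth is (4·10 − NGAM)/GAM; on the redox toy the wild-type
optimum is 38/13 (see the fixture module docs).
"""

import numpy as np
import pytest

from fluxkit.conditions import apply_bound_overrides, set_condition
from fluxkit.core import Metabolite, Model, Reaction
from fluxkit.errors import InfeasibleError, UnboundedError
from fluxkit.fixtures import ToyModelSpec, make_toy_core_model, toy_condition
from fluxkit.simulate import (
    FEASIBILITY_TOL,
    ObjectiveSpec,
    fba,
    find_blocked_reactions,
    fva,
    mass_balance_residual,
    pfba_quadratic,
)


def _parallel_demand_model(routes=2, demand=10.0):
    """Parallel routes carrying a fixed demand — symmetric QP fixture."""
    spec = ToyModelSpec(parallel_routes=routes)
    model = make_toy_core_model(spec)
    configured = set_condition(model, toy_condition(model))
    return apply_bound_overrides(
        configured, {"EX_q_e": (demand, demand), "EX_a_e": (-demand, 0.0)}
    )


# ----------------------------------------------------------------- FBA

def test_fba_chain_uptake_limited(configured_chain):
    sol = fba(configured_chain, ObjectiveSpec.single("EX_q_e"))
    assert sol.objective_value == pytest.approx(10.0, abs=1e-7)
    assert mass_balance_residual(configured_chain, sol) < FEASIBILITY_TOL


def test_fba_growth_matches_hand_lp(configured_chain, configured_redox):
    growth = fba(configured_chain, ObjectiveSpec.single("BIOMASS_CELLOBIOSE"))
    assert growth.objective_value == pytest.approx((40.0 - 2.0) / 12.0, abs=1e-7)
    redox = fba(configured_redox, ObjectiveSpec.single("BIOMASS_CELLOBIOSE"))
    assert redox.objective_value == pytest.approx(38.0 / 13.0, abs=1e-7)


def test_fba_infeasible_bounds(configured_chain):
    broken = apply_bound_overrides(configured_chain, {"UPT": (5.0, 2.0)})
    with pytest.raises(InfeasibleError):
        fba(broken, ObjectiveSpec.single("EX_q_e"))


def test_fba_unbounded_names_direction():
    model = Model(id="unbounded")
    model.add_metabolite(Metabolite("a_e", compartment="e"))
    model.add_reaction(
        Reaction("EX_a_e", stoichiometry={"a_e": -1},
                 lower_bound=-np.inf, upper_bound=np.inf, is_exchange=True)
    )
    model.add_reaction(
        Reaction("SRC", stoichiometry={"a_e": 1},
                 lower_bound=-np.inf, upper_bound=np.inf)
    )
    with pytest.raises(UnboundedError) as err:
        fba(model, ObjectiveSpec.single("EX_a_e"))
    assert "EX_a_e" in err.value.reactions


# ----------------------------------------------------------------- pFBA

def test_pfba_splits_parallel_routes_evenly():
    configured = _parallel_demand_model(routes=2)
    sol = pfba_quadratic(configured)
    assert sol["ROUTE1"] == pytest.approx(5.0, abs=1e-6)
    assert sol["ROUTE2"] == pytest.approx(5.0, abs=1e-6)


def test_pfba_chain_carries_fixed_uptake(chain_model):
    # growth closed: the chain is then a single path with no alternative
    configured = set_condition(chain_model, toy_condition(chain_model))
    configured = apply_bound_overrides(
        configured,
        {"EX_a_e": (-10.0, -10.0), "BIOMASS_CELLOBIOSE": (0.0, 0.0)},
    )
    sol = pfba_quadratic(configured)
    for rid in ("UPT", "CHAIN1", "CHAIN2", "SEC", "EX_q_e"):
        assert sol[rid] == pytest.approx(10.0, abs=1e-6)


def test_pfba_repeat_solves_agree(pinned_redox):
    a = pfba_quadratic(pinned_redox)
    b = pfba_quadratic(pinned_redox)
    for rid in a.fluxes:
        assert a[rid] == pytest.approx(b[rid], abs=1e-6)


def test_pfba_mass_balance_and_norm_optimality(pinned_redox):
    sol = pfba_quadratic(pinned_redox)
    assert mass_balance_residual(pinned_redox, sol) < FEASIBILITY_TOL
    ref = fba(pinned_redox, ObjectiveSpec.single("EX_eth_e"))
    norm_fba = sum(v**2 for v in ref.fluxes.values())
    assert sol.objective_value <= norm_fba + 1e-6


def test_pfba_satisfies_kkt_certificate(pinned_redox):
    """Independent optimality proof: the problem is strictly convex, so a
    point satisfying the KKT conditions (stationarity 2v = Sᵀλ + μ with
    correctly-signed bound multipliers) is the global minimiser."""
    S, _, _ = pinned_redox.stoichiometric_matrix()
    lb, ub = pinned_redox.bound_arrays()
    v = np.array(list(pfba_quadratic(pinned_redox).fluxes.values()))
    tol = 1e-6
    slack = 1e-5
    free = (v > lb + tol) & (v < ub - tol)
    at_lower_only = np.isclose(v, lb, atol=tol) & ~np.isclose(v, ub, atol=tol)
    at_upper_only = np.isclose(v, ub, atol=tol) & ~np.isclose(v, lb, atol=tol)
    A = S.toarray().T  # rows: reactions, cols: metabolite multipliers λ
    g = 2 * v
    # existence of λ with (Sᵀλ)_j = g_j on free coords, ≤ g_j at lower-only
    # bounds (μ_lower ≥ 0) and ≥ g_j at upper-only bounds (μ_upper ≥ 0)
    from scipy.optimize import linprog

    A_ub = np.vstack(
        [
            A[free],
            -A[free],
            A[at_lower_only],
            -A[at_upper_only],
        ]
    )
    b_ub = np.concatenate(
        [
            g[free] + slack,
            -g[free] + slack,
            g[at_lower_only] + slack,
            -g[at_upper_only] + slack,
        ]
    )
    cert = linprog(
        c=np.zeros(A.shape[1]),
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=[(None, None)] * A.shape[1],
        method="highs",
    )
    assert cert.status == 0, "no valid KKT multipliers exist for the QP point"


def test_pfba_infeasible(configured_chain):
    broken = apply_bound_overrides(
        configured_chain, {"EX_a_e": (0.0, 0.0), "EX_q_e": (5.0, 10.0)}
    )
    with pytest.raises(InfeasibleError):
        pfba_quadratic(broken)


# ------------------------------------------------------------------ FVA

def test_fva_chain_point_ranges(chain_model):
    configured = set_condition(chain_model, toy_condition(chain_model))
    configured = apply_bound_overrides(
        configured,
        {"EX_a_e": (-10.0, -10.0), "BIOMASS_CELLOBIOSE": (0.0, 0.0)},
    )
    ranges = fva(configured, reactions=["UPT", "CHAIN1", "SEC"])
    for rid in ("UPT", "CHAIN1", "SEC"):
        assert ranges[rid] == pytest.approx((10.0, 10.0), abs=1e-7)


def test_fva_parallel_routes_full_range():
    configured = _parallel_demand_model(routes=2)
    ranges = fva(configured, reactions=["ROUTE1", "ROUTE2"])
    assert ranges["ROUTE1"] == pytest.approx((0.0, 10.0), abs=1e-7)
    assert ranges["ROUTE2"] == pytest.approx((0.0, 10.0), abs=1e-7)


def test_fva_nesting_contains_pfba(pinned_redox):
    sol = pfba_quadratic(pinned_redox)
    ranges = fva(pinned_redox)
    for rid, (lo, hi) in ranges.ranges.items():
        assert lo - 1e-6 <= sol[rid] <= hi + 1e-6


def test_loopless_zeroes_isolated_cycle(cycle_model):
    configured = set_condition(cycle_model, toy_condition(cycle_model))
    configured = apply_bound_overrides(configured, {"EX_a_e": (-10.0, -10.0)})
    plain = fva(configured, reactions=["CYCA", "CYCB", "UPT"])
    assert plain["CYCA"] == pytest.approx((0.0, 1000.0), abs=1e-6)
    assert plain["CYCB"] == pytest.approx((0.0, 1000.0), abs=1e-6)
    loopless = fva(configured, reactions=["CYCA", "CYCB", "UPT"], loopless=True)
    assert loopless["CYCA"] == pytest.approx((0.0, 0.0), abs=1e-6)
    assert loopless["CYCB"] == pytest.approx((0.0, 0.0), abs=1e-6)
    # chain flux untouched by the loop-law constraints
    assert loopless["UPT"] == pytest.approx(plain["UPT"], abs=1e-6)
    assert not loopless.relaxed


def test_loopless_ranges_nested_in_plain(pinned_redox):
    plain = fva(pinned_redox)
    loopless = fva(pinned_redox, loopless=True)
    for rid in plain.ranges:
        assert loopless[rid][0] >= plain[rid][0] - 1e-6
        assert loopless[rid][1] <= plain[rid][1] + 1e-6


# -------------------------------------------------------------- blocked

def _dead_end_model():
    model = make_toy_core_model(ToyModelSpec())
    model.add_metabolite(Metabolite("orphan_c", compartment="c"))
    model.add_reaction(
        Reaction("DEADEND", stoichiometry={"q_c": -1, "orphan_c": 1},
                 lower_bound=0.0, upper_bound=1000.0)
    )
    return model


def test_dead_end_reaction_is_blocked():
    report = find_blocked_reactions(_dead_end_model())
    assert report.blocked == {"DEADEND"}
    assert report.percent == pytest.approx(100.0 / len(_dead_end_model().reactions))


def test_open_chain_has_no_blocked_reactions(chain_model):
    assert find_blocked_reactions(chain_model).blocked == set()


def test_blocked_set_invariant_to_exchange_bound_magnitude():
    model = _dead_end_model()
    assert (
        find_blocked_reactions(model, exchange_bound=1000.0).blocked
        == find_blocked_reactions(model, exchange_bound=2000.0).blocked
    )


def test_cycle_reactions_not_blocked_but_loopless_silent(cycle_model):
    # the isolated 2-cycle can carry circulating flux, so plain blocked
    # detection keeps it; the rest of the network is unaffected
    report = find_blocked_reactions(cycle_model)
    assert "CYCA" not in report.blocked and "CYCB" not in report.blocked
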