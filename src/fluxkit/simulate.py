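"""Flux simulation over the feasible space Ω_k = {v : S·v = 0, l ≤ v ≤ u}.

Three ways of interrogating Ω_k are provided:

* :func:`fba` — maximise a linear objective c·v (LP, HiGHS via scipy).
  Only the objective value is contractual; the flux vector of a degenerate
  optimum is solver-dependent.
* :func:`pfba_quadratic` — minimise Σ_j v_j² over Ω_k (OSQP).  The norm is
  strictly convex, so the minimiser is unique; no growth-maximisation
  pre-step is performed — measured bounds are expected to pin the state.
* :func:`fva` — per-reaction minimum and maximum flux, optionally with
  loopless (thermodynamically cycle-free) constraints enforced through a
  mixed-integer formulation with binary flux-direction variables and
  sign-constrained potential variables on internal reactions (big-M 1000).

:func:`find_blocked_reactions` opens every exchange to ±1000 and reports
reactions whose FVA interval collapses to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.linalg import null_space
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .conditions import build_measured_bounds  # noqa: F401  (simulation surface)
from .core import DEFAULT_BOUND, Model
from .errors import InfeasibleError, UnboundedError, UnknownIdentifierError

FEASIBILITY_TOL = 1e-6  # reported-constraint checks
LP_TOL = 1e-9  # solver feasibility/optimality
QP_TOL = 1e-8  # QP convergence on the objective
BIG_M = 1000.0  # matches the global flux bound


@dataclass
class ObjectiveSpec:
    """Linear objective: reaction-id → coefficient, maximised."""

    coefficients: Dict[str, float]
    sense: str = "maximize"

    def __post_init__(self):
        if not any(c != 0 for c in self.coefficients.values()):
            raise ValueError("objective needs at least one nonzero coefficient")
        if self.sense not in ("maximize", "minimize"):
            raise ValueError(f"bad sense {self.sense!r}")

    @classmethod
    def single(cls, reaction_id: str, sense: str = "maximize") -> "ObjectiveSpec":
        return cls({reaction_id: 1.0}, sense)


@dataclass
class FluxDistribution:
    condition: str
    fluxes: Dict[str, float]
    objective_value: Optional[float]
    status: str = "optimal"

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]


@dataclass
class FluxRange:
    ranges: Dict[str, Tuple[float, float]]
    loopless: bool = False
    #: reactions whose loopless MILP hit the time limit (LP bounds reported)
    relaxed: set = field(default_factory=set)

    def __getitem__(self, rid: str) -> Tuple[float, float]:
        return self.ranges[rid]


# ---------------------------------------------------------------- helpers

def _problem_arrays(model: Model):
    S, met_index, rxn_index = model.stoichiometric_matrix()
    lb, ub = model.bound_arrays()
    bad = np.flatnonzero(lb > ub)
    if bad.size:
        rids = list(model.reactions)
        raise InfeasibleError(
            "inconsistent bounds (lower > upper) on "
            f"{[rids[j] for j in bad[:5]]}"
        )
    return S, rxn_index, lb, ub


def _objective_vector(rxn_index, objective: ObjectiveSpec) -> np.ndarray:
    c = np.zeros(len(rxn_index))
    for rid, coef in objective.coefficients.items():
        if rid not in rxn_index:
            raise UnknownIdentifierError(f"objective references unknown {rid!r}")
        c[rxn_index[rid]] = coef
    if objective.sense == "minimize":
        c = -c
    return c  # maximised


def _solve_lp(S, lb, ub, c_max) -> Tuple[np.ndarray, float, int]:
    """Maximise c·v over Ω; returns (v, objective, scipy status code)."""
    res = linprog(
        c=-c_max,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options={"primal_feasibility_tolerance": LP_TOL,
                 "dual_feasibility_tolerance": LP_TOL},
    )
    x = res.x if res.x is not None else np.full(len(lb), np.nan)
    obj = -res.fun if res.fun is not None else np.nan
    return x, obj, res.status


def _unbounded_directions(S, lb, ub, c_max, rxn_ids) -> Tuple[str, ...]:
    """Heuristically name reactions driving an unbounded objective."""
    cap = 1e7
    x, _, status = _solve_lp(
        S, np.maximum(lb, -cap), np.minimum(ub, cap), c_max
    )
    if status != 0:
        return ()
    at_cap = np.flatnonzero(
        ((np.abs(x) > cap * 0.99) & ~np.isfinite(np.abs(lb) + np.abs(ub)))
        | ((x > cap * 0.99) & ~np.isfinite(ub))
        | ((x < -cap * 0.99) & ~np.isfinite(lb))
    )
    return tuple(rxn_ids[j] for j in at_cap)


# ---------------------------------------------------------------- FBA

def fba(model: Model, objective: ObjectiveSpec) -> FluxDistribution:
    """Maximise ``objective`` over the feasible flux space.

    Raises :class:`InfeasibleError` if Ω is empty and
    :class:`UnboundedError` (naming candidate unbounded reactions) if the
    optimum is +∞.
    """
    S, rxn_index, lb, ub = _problem_arrays(model)
    c = _objective_vector(rxn_index, objective)
    x, obj, status = _solve_lp(S, lb, ub, c)
    rids = list(rxn_index)
    if status == 2:
        raise InfeasibleError(
            f"model {model.id!r} infeasible under current bounds"
        )
    if status == 3:
        raise UnboundedError(
            f"objective unbounded for model {model.id!r}",
            _unbounded_directions(S, lb, ub, c, rids),
        )
    if status != 0:
        raise InfeasibleError(f"LP solver failure (status {status})")
    if objective.sense == "minimize":
        obj = -obj
    return FluxDistribution(
        condition=model.id, fluxes=dict(zip(rids, x)), objective_value=obj
    )


# ---------------------------------------------------------------- pFBA (QP)

def pfba_quadratic(model: Model) -> FluxDistribution:
    """The unique minimiser of Σ_j v_j² over the feasible flux space."""
    import osqp

    S, rxn_index, lb, ub = _problem_arrays(model)
    n = S.shape[1]
    P = sp.identity(n, format="csc") * 2.0
    A = sp.vstack([S, sp.identity(n)]).tocsc()
    l = np.concatenate([np.zeros(S.shape[0]), lb])
    u = np.concatenate([np.zeros(S.shape[0]), ub])
    prob = osqp.OSQP()
    prob.setup(
        P=P,
        q=np.zeros(n),
        A=A,
        l=l,
        u=u,
        eps_abs=QP_TOL * 1e-2,
        eps_rel=QP_TOL * 1e-2,
        eps_prim_inf=1e-10,
        max_iter=200000,
        polish=True,
        verbose=False,
    )
    res = prob.solve(raise_error=False)
    status = res.info.status
    if "infeasible" in status:
        raise InfeasibleError(f"quadratic flux minimisation infeasible: {status}")
    if "solved" not in status:
        raise InfeasibleError(f"QP solver failure: {status}")
    x = np.asarray(res.x, dtype=float)
    # clip roundoff outside finite bounds
    x = np.clip(x, np.where(np.isfinite(lb), lb, x), np.where(np.isfinite(ub), ub, x))
    return FluxDistribution(
        condition=model.id,
        fluxes=dict(zip(rxn_index, x)),
        objective_value=float(np.sum(x**2)),
        status=status,
    )


# ---------------------------------------------------------------- FVA

def _internal_reaction_mask(model: Model) -> np.ndarray:
    biomass = set(model.biomass_variants.values())
    return np.array(
        [
            (not r.is_exchange) and (r.id not in biomass)
            for r in model.reactions.values()
        ]
    )


def _loopless_extremum(
    S, lb, ub, internal: np.ndarray, K: np.ndarray, j: int, maximize: bool,
    time_limit: float,
):
    """Min/max v_j subject to Ω and loop-law constraints (MILP).

    Variables: v (n fluxes), a (binary direction per internal reaction),
    G (potential per internal reaction).  a_j = 1 forces v_j ≥ 0 and
    G_j ≤ −1; a_j = 0 forces v_j ≤ 0 and G_j ≥ 1; Kᵀ does not appear —
    instead each internal null-space basis vector k of S must satisfy
    k·G = 0, which excludes net flux around any closed internal cycle.
    """
    n = S.shape[1]
    int_idx = np.flatnonzero(internal)
    m_int = len(int_idx)
    n_tot = n + 2 * m_int  # v, a, G
    M = BIG_M

    cons = []
    # mass balance on v
    A_mb = sp.hstack([S, sp.csc_matrix((S.shape[0], 2 * m_int))])
    cons.append(LinearConstraint(A_mb, 0.0, 0.0))
    rows_v, rows_a, rows_G = [], [], []
    # v_j - M a_j <= 0   and   v_j + M(1-a_j) >= 0  <=>  v_j - M a_j >= -M
    D = sp.csc_matrix(
        (np.ones(m_int), (np.arange(m_int), int_idx)), shape=(m_int, n)
    )
    A_dir = sp.hstack(
        [D, -M * sp.identity(m_int), sp.csc_matrix((m_int, m_int))]
    )
    cons.append(LinearConstraint(A_dir, -M, 0.0))
    # G_j + (M+1) a_j in [1, M]
    A_pot = sp.hstack(
        [sp.csc_matrix((m_int, n)), (M + 1) * sp.identity(m_int),
         sp.identity(m_int)]
    )
    cons.append(LinearConstraint(A_pot, 1.0, M))
    # loop law: k·G = 0 for each internal null-space basis vector
    if K.size:
        A_loop = sp.hstack(
            [sp.csc_matrix((K.shape[1], n + m_int)), sp.csc_matrix(K.T)]
        )
        cons.append(LinearConstraint(A_loop, 0.0, 0.0))

    lo = np.concatenate([lb, np.zeros(m_int), -M * np.ones(m_int)])
    hi = np.concatenate([ub, np.ones(m_int), M * np.ones(m_int)])
    integrality = np.concatenate(
        [np.zeros(n), np.ones(m_int), np.zeros(m_int)]
    )
    c = np.zeros(n_tot)
    c[j] = -1.0 if maximize else 1.0
    res = milp(
        c=c,
        constraints=cons,
        bounds=Bounds(lo, hi),
        integrality=integrality,
        options={"time_limit": time_limit, "presolve": True},
    )
    if res.status == 0:
        val = res.x[j]
        return float(val), True
    if res.status == 2:
        raise InfeasibleError("loopless FVA subproblem infeasible")
    return None, False  # time limit / numerical trouble -> relaxed


def fva(
    model: Model,
    reactions: Optional[Iterable[str]] = None,
    loopless: bool = False,
    time_limit: float = 30.0,
) -> FluxRange:
    """Flux variability analysis: per-reaction [v_min, v_max] over Ω.

    With ``loopless=True`` internal thermodynamically infeasible cycles are
    excluded; exchanges and biomass reactions are exempt from the direction
    constraints.  A loopless subproblem that exceeds ``time_limit`` seconds
    falls back to its LP bound and is listed in ``FluxRange.relaxed``.
    """
    S, rxn_index, lb, ub = _problem_arrays(model)
    rids = list(rxn_index)
    targets = rids if reactions is None else list(reactions)
    for rid in targets:
        if rid not in rxn_index:
            raise UnknownIdentifierError(f"unknown reaction {rid!r} in FVA")

    internal = _internal_reaction_mask(model)
    K = np.empty((0, 0))
    if loopless and internal.any():
        S_int = S[:, np.flatnonzero(internal)].toarray()
        K = null_space(S_int)  # columns span internal cycles
        if K.shape[1] == 0:
            loopless_active = False
        else:
            loopless_active = True
    else:
        loopless_active = False

    ranges: Dict[str, Tuple[float, float]] = {}
    relaxed = set()
    for rid in targets:
        j = rxn_index[rid]
        vals = []
        for maximize in (False, True):
            lp_val = None
            if loopless_active:
                v, ok = _loopless_extremum(
                    S, lb, ub, internal, K, j, maximize, time_limit
                )
                if ok:
                    vals.append(v)
                    continue
                relaxed.add(rid)
            c = np.zeros(len(rids))
            c[j] = 1.0 if maximize else -1.0
            x, obj, status = _solve_lp(S, lb, ub, c)
            if status == 2:
                raise InfeasibleError("FVA: feasible space is empty")
            if status == 3:
                lp_val = np.inf if maximize else -np.inf
            elif status == 0:
                lp_val = obj if maximize else -obj
            else:
                raise InfeasibleError(f"FVA LP failure (status {status})")
            vals.append(lp_val)
        vmin, vmax = vals
        if vmin > vmax:  # solver roundoff on a point interval
            vmin = vmax = 0.5 * (vmin + vmax)
        ranges[rid] = (vmin, vmax)
    return FluxRange(ranges=ranges, loopless=loopless, relaxed=relaxed)


# ---------------------------------------------------------------- blocked

@dataclass
class BlockedReport:
    blocked: set
    fraction: float  # of all reactions

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


def find_blocked_reactions(
    model: Model,
    tol: float = FEASIBILITY_TOL,
    exchange_bound: float = DEFAULT_BOUND,
) -> BlockedReport:
    """Reactions unable to carry flux with every exchange open to ±1000.

    A reaction is blocked iff its FVA minimum and maximum are both zero
    (|v| < ``tol``).  This open-exchange scenario yields the smallest
    possible blocked set for the network; the set is insensitive to the
    exact ``exchange_bound`` magnitude.
    """
    probe = model.copy()
    for rid in probe.exchanges:
        probe.reactions[rid].bounds = (-exchange_bound, exchange_bound)
    ranges = fva(probe, loopless=False)
    blocked = {
        rid
        for rid, (vmin, vmax) in ranges.ranges.items()
        if abs(vmin) < tol and abs(vmax) < tol
    }
    return BlockedReport(
        blocked=blocked, fraction=len(blocked) / max(len(model.reactions), 1)
    )


def mass_balance_residual(model: Model, distribution: FluxDistribution) -> float:
    """max_i |Σ_j S_ij v_j| for a reported flux distribution."""
    S, _, rxn_index = model.stoichiometric_matrix()
    v = np.array([distribution.fluxes[rid] for rid in rxn_index])
    return float(np.max(np.abs(S @ v))) if len(v) else 0.0
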