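"""GAM/NGAM training from measured-flux datasets and growth validation.

The growth-associated maintenance (GAM, mmol ATP/gCDW) and non-growth-
associated maintenance (NGAM, mmol ATP/gCDW/h) are obtained by regressing
the model's maximum ATP-hydrolysis flux — computed with measured exchange
fluxes and growth rate as constraints, and with both maintenance terms
zeroed so every spare ATP is routed through the hydrolysis pseudo-reaction —
against the measured growth rate.  The slope of the ordinary least-squares
line is GAM and its intercept is NGAM.  Outliers are caller-designated
flags; no automatic detection is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import Condition, apply_bound_overrides, build_measured_bounds, set_condition
from .core import Model
from .errors import FluxkitError, InfeasibleError
from .simulate import ObjectiveSpec, fba


@dataclass
class MaintenancePoint:
    condition: str
    growth_rate: float  # measured, 1/h
    atp_flux: float  # maximum ATP-hydrolysis flux, mmol ATP/gCDW/h
    outlier: bool = False


@dataclass
class MaintenanceParameters:
    gam: float  # slope, mmol ATP/gCDW
    ngam: float  # intercept, mmol ATP/gCDW/h
    r_squared: float
    n_points: int
    excluded: Tuple[str, ...] = ()
    status: str = "ok"  # "ok" | "negative_ngam"


def max_atp_yield(
    model: Model, condition: Condition, zero_gam: bool = True
) -> MaintenancePoint:
    """Maximum ATP-hydrolysis flux under the condition's measured bounds.

    With ``zero_gam`` (default) the biomass GAM term and the NGAM lower
    bound are set to zero so that growth-proportional ATP consumption is
    absorbed by the regression slope rather than by the shipped
    coefficients.  Returns the (measured growth, max ATP) training point.
    """
    if model.atp_hydrolysis_reaction is None:
        raise FluxkitError("model has no ATP-hydrolysis reaction")
    cond = condition.replace(gam=0.0, ngam=0.0) if zero_gam else condition
    configured = set_condition(model, cond)
    overrides = build_measured_bounds(configured, cond)
    constrained = apply_bound_overrides(configured, overrides)
    try:
        sol = fba(constrained, ObjectiveSpec.single(model.atp_hydrolysis_reaction))
    except InfeasibleError as exc:
        raise InfeasibleError(
            f"condition {condition.name!r}: measured bounds are mutually "
            f"infeasible ({exc})"
        ) from exc
    growth = condition.measured.get("growth", condition.measured.get("biomass"))
    if growth is None:
        bid = configured.biomass_variants[condition.biomass_variant]
        growth = condition.measured.get(bid, (0.0, 0.0))
    return MaintenancePoint(
        condition=condition.name,
        growth_rate=float(growth[0]),
        atp_flux=float(sol.objective_value),
    )


def fit_gam_ngam(points: Sequence[MaintenancePoint]) -> MaintenanceParameters:
    """OLS of max ATP flux (y) on measured growth rate (x), non-outliers only.

    Measurement uncertainties enter through the flux bounds upstream, not as
    regression weights.  A negative fitted NGAM is physically suspect and
    reported with status ``"negative_ngam"`` (plus a warning) but still
    returned.
    """
    used = [p for p in points if not p.outlier]
    if len(used) < 2:
        raise ValueError(
            f"need at least 2 non-outlier points, got {len(used)}"
        )
    x = np.array([p.growth_rate for p in used])
    y = np.array([p.atp_flux for p in used])
    if np.ptp(x) == 0:
        raise ValueError("all growth rates identical; slope is undefined")
    res = stats.linregress(x, y)
    status = "ok"
    if res.intercept < 0:
        status = "negative_ngam"
        warnings.warn(
            f"fitted NGAM is negative ({res.intercept:.4g}); physically suspect",
            stacklevel=2,
        )
    return MaintenanceParameters(
        gam=float(res.slope),
        ngam=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(used),
        excluded=tuple(p.condition for p in points if p.outlier),
        status=status,
    )


@dataclass
class GrowthValidation:
    table: pd.DataFrame  # columns: condition, measured, predicted, status
    r_squared: Optional[float]  # Pearson r² over successful rows; None if n < 2


def validate_growth(
    model: Model,
    conditions: Iterable[Condition],
    parameters: Dict[str, MaintenanceParameters],
) -> GrowthValidation:
    """Predict max growth per condition with fitted class parameters.

    ``parameters`` maps a condition-class label ("batch",
    "chemostat-cellobiose", "chemostat-cellulose") to fitted values; the
    class of a condition is derived from its reactor mode and carbon
    source.  Exchanges are bounded to μ±σ, growth is left free and
    maximised.  Infeasible conditions are recorded as failed rows.
    """
    rows = []
    for cond in conditions:
        klass = (
            "batch"
            if cond.reactor_mode == "batch"
            else f"chemostat-{cond.carbon_source}"
        )
        params = parameters.get(klass)
        fitted = cond.replace(
            gam=params.gam if params else cond.gam,
            ngam=params.ngam if params else cond.ngam,
        )
        configured = set_condition(model, fitted)
        bid = configured.biomass_variants[cond.biomass_variant]
        overrides = build_measured_bounds(configured, fitted)
        overrides.pop(bid, None)  # growth stays free
        measured = cond.measured.get("growth", cond.measured.get("biomass"))
        measured_rate = float(measured[0]) if measured else np.nan
        try:
            sol = fba(
                apply_bound_overrides(configured, overrides),
                ObjectiveSpec.single(bid),
            )
            rows.append((cond.name, measured_rate, sol.objective_value, "ok"))
        except InfeasibleError:
            rows.append((cond.name, measured_rate, np.nan, "infeasible"))
    table = pd.DataFrame(
        rows, columns=["condition", "measured", "predicted", "status"]
    )
    ok = table.dropna(subset=["measured", "predicted"])
    r2 = None
    if len(ok) >= 2 and ok["measured"].nunique() > 1:
        r, _ = stats.pearsonr(ok["measured"], ok["predicted"])
        r2 = float(r**2)
    return GrowthValidation(table=table, r_squared=r2)
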