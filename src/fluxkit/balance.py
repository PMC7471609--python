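"""Elemental and charge balance checks with proton/water correction.

Imbalances are reported as products-minus-reactants deltas, weighted by the
stoichiometric coefficients.  Reactions whose residual is confined to H, O
and charge can be repaired by adding protons (H, charge +1) and water (H2O)
to the appropriate side, which is how biochemical reconstructions are
typically balanced after importing database stoichiometries.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

from .core import Metabolite, Reaction
from .errors import BalanceError

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> Dict[str, int]:
    """Parse ``"C10H12N5O13P3"`` into an element→count map."""
    if text is None:
        raise ValueError("formula is None")
    text = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
        elem, num = m.group(1), m.group(2)
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at offset {pos}")
    return counts


def format_formula(counts: Mapping[str, int]) -> str:
    """Hill-ordered formula string (C, H, then alphabetical)."""
    order = sorted(counts, key=lambda e: (e != "C", e != "H", e))
    return "".join(
        f"{e}{counts[e]}" if counts[e] != 1 else e for e in order if counts[e]
    )


@dataclass
class BalanceReport:
    reaction_id: str
    #: "balanced" | "imbalanced" | "unscorable" | "exchange"
    status: str
    element_deltas: Dict[str, float] = field(default_factory=dict)
    charge_delta: Optional[float] = None
    missing: list = field(default_factory=list)

    @property
    def balanced(self) -> bool:
        return self.status == "balanced"


def check_balance(
    reaction: Reaction, metabolite_table: Mapping[str, Metabolite], tol: float = 1e-9
) -> BalanceReport:
    """Per-element and charge deltas (products minus reactants) for a reaction.

    Exchange reactions are skipped by convention (status ``"exchange"``);
    participants lacking a formula or charge make the reaction
    ``"unscorable"`` rather than failing.
    """
    if reaction.is_exchange:
        return BalanceReport(reaction.id, "exchange")
    missing = [
        mid
        for mid in reaction.stoichiometry
        if mid not in metabolite_table
        or metabolite_table[mid].formula is None
        or metabolite_table[mid].charge is None
    ]
    if missing:
        return BalanceReport(reaction.id, "unscorable", missing=missing)
    deltas: Dict[str, float] = {}
    charge = 0.0
    for mid, coef in reaction.stoichiometry.items():
        met = metabolite_table[mid]
        for elem, cnt in met.formula.items():
            deltas[elem] = deltas.get(elem, 0.0) + coef * cnt
        charge += coef * met.charge
    deltas = {e: d for e, d in deltas.items() if abs(d) > tol}
    if abs(charge) <= tol:
        charge = 0.0
    status = "balanced" if not deltas and charge == 0.0 else "imbalanced"
    return BalanceReport(reaction.id, status, deltas, charge)


def _find_species(
    metabolite_table: Mapping[str, Metabolite], formula: Dict[str, int], charge: int
) -> Optional[str]:
    for mid, met in metabolite_table.items():
        if met.formula == formula and met.charge == charge:
            return mid
    return None


def balance_with_water_protons(
    reaction: Reaction,
    metabolite_table: Mapping[str, Metabolite],
    proton_id: Optional[str] = None,
    water_id: Optional[str] = None,
) -> Reaction:
    """Zero H/O/charge imbalance by adding integer amounts of H+ and H2O.

    With ``x`` protons and ``y`` waters added to the product side (negative
    values land on the reactant side), the residuals require x = −Δcharge,
    y = −ΔO and ΔH + x + 2y = 0; if the last identity fails, or any other
    element is imbalanced, the reaction is uncorrectable and a
    :class:`BalanceError` carrying the residual deltas is raised.
    Already-balanced reactions are returned unchanged.
    """
    report = check_balance(reaction, metabolite_table)
    if report.status == "unscorable":
        raise BalanceError(
            f"reaction {reaction.id!r} unscorable: missing formula/charge for "
            f"{report.missing}",
        )
    if report.status in ("balanced", "exchange"):
        return reaction
    other = {e: d for e, d in report.element_deltas.items() if e not in ("H", "O")}
    if other:
        raise BalanceError(
            f"reaction {reaction.id!r} imbalanced beyond H/O/charge", other
        )
    dH = report.element_deltas.get("H", 0.0)
    dO = report.element_deltas.get("O", 0.0)
    dq = report.charge_delta or 0.0
    x = -dq
    y = -dO
    if abs(dH + x + 2 * y) > 1e-9 or not (
        math.isclose(x, round(x), abs_tol=1e-9) and math.isclose(y, round(y), abs_tol=1e-9)
    ):
        raise BalanceError(
            f"reaction {reaction.id!r} has no integer proton/water correction",
            {"H": dH + x + 2 * y, "proton": x, "water": y},
        )
    x, y = int(round(x)), int(round(y))
    proton_id = proton_id or _find_species(metabolite_table, {"H": 1}, 1)
    water_id = water_id or _find_species(metabolite_table, {"H": 2, "O": 1}, 0)
    if x and proton_id is None:
        raise BalanceError("no proton species (formula H, charge +1) in table")
    if y and water_id is None:
        raise BalanceError("no water species (formula H2O, charge 0) in table")
    stoich = dict(reaction.stoichiometry)
    for mid, amount in ((proton_id, x), (water_id, y)):
        if amount:
            stoich[mid] = stoich.get(mid, 0.0) + amount
            if stoich[mid] == 0:
                del stoich[mid]
    corrected = Reaction(
        id=reaction.id,
        name=reaction.name,
        stoichiometry=stoich,
        lower_bound=reaction.lower_bound,
        upper_bound=reaction.upper_bound,
        gpr=reaction.gpr,
        is_exchange=reaction.is_exchange,
        subsystem=reaction.subsystem,
    )
    final = check_balance(corrected, metabolite_table)
    if not final.balanced:
        raise BalanceError(
            f"correction of {reaction.id!r} left residual imbalance",
            dict(final.element_deltas, charge=final.charge_delta),
        )
    return corrected
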