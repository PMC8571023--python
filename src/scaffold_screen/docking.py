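"""Docking-summary post-processing: inhibition constants, ligand efficiency
and lead selection.

The docking engine reports a predicted binding free energy dG_bind
(kcal/mol) per compound. Two derived quantities make compounds comparable:

* inhibition constant  Ki = exp(dG_bind / RT), in mol/L, with
  R = 1.98e-3 kcal/(mol K) and T = 298.15 K;
* ligand efficiency    LE = dG_bind / N_atm, kcal/mol per heavy atom.

Leads are the compounds binding strictly more strongly than a designated
reference compound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import pandas as pd

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.98e-3
#: Room temperature, K.
ROOM_TEMPERATURE_K = 298.15
#: RT at room temperature, kcal/mol.
RT_KCAL = GAS_CONSTANT_KCAL * ROOM_TEMPERATURE_K


@dataclass(frozen=True)
class DockResult:
    """Per-compound docking summary row.

    cl_rms is the RMS difference between the top two conformations in the
    lowest-energy cluster; cl_rms_a the mean RMS of all conformations
    against the lowest-energy one. Either may be missing (None).
    """

    compound_id: str
    dg_bind: float
    n_atm: int
    n_tor: int
    cl_rms: float | None = None
    cl_rms_a: float | None = None

    def __post_init__(self):
        if self.n_atm < 1:
            raise ValueError(f"{self.compound_id}: n_atm must be >= 1")
        if self.n_tor < 0:
            raise ValueError(f"{self.compound_id}: n_tor must be >= 0")
        for label, v in (("cl_rms", self.cl_rms), ("cl_rms_a", self.cl_rms_a)):
            if v is not None and v < 0:
                raise ValueError(f"{self.compound_id}: {label} must be >= 0")


@dataclass(frozen=True)
class KiDisplay:
    value: float
    unit: str  # "M", "mM" or "uM"


@dataclass(frozen=True)
class BindingMetrics:
    ki_molar: float
    ki_display: KiDisplay
    le: float


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (0.005 -> 0.01; -0.005 -> -0.01)."""
    exponent = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(exponent, rounding=ROUND_HALF_UP))


def ki_from_dg(dg_bind: float) -> float:
    """Inhibition constant Ki = exp(dG_bind / RT) in mol/L.

    A negative dG_bind (favourable binding) gives Ki < 1 M; dG_bind = 0
    gives exactly 1 M; a positive value exceeds 1 M.
    """
    if not math.isfinite(dg_bind):
        raise ValueError(f"dG_bind must be finite, got {dg_bind!r}")
    return math.exp(dg_bind / RT_KCAL)


def format_ki(ki_molar: float) -> KiDisplay:
    """Auto-scale a molar Ki for display: M above 0.1 M, mM above 1e-4 M,
    else uM; the value is rounded half-up to 2 decimals."""
    if not (ki_molar > 0):
        raise ValueError(f"Ki must be positive, got {ki_molar!r}")
    if ki_molar >= 0.1:
        scale, unit = 1.0, "M"
    elif ki_molar >= 1e-4:
        scale, unit = 1e-3, "mM"
    else:
        scale, unit = 1e-6, "uM"
    return KiDisplay(value=round_half_up(ki_molar / scale), unit=unit)


def ligand_efficiency(dg_bind: float, n_atm: int) -> float:
    """LE = dG_bind / N_atm, kcal/mol per heavy atom (sign preserved)."""
    if n_atm < 1:
        raise ValueError(f"n_atm must be >= 1, got {n_atm}")
    if not math.isfinite(dg_bind):
        raise ValueError(f"dG_bind must be finite, got {dg_bind!r}")
    return dg_bind / n_atm


def binding_metrics(result: DockResult) -> BindingMetrics:
    ki = ki_from_dg(result.dg_bind)
    return BindingMetrics(ki_molar=ki, ki_display=format_ki(ki),
                          le=ligand_efficiency(result.dg_bind, result.n_atm))


def select_leads(results: Sequence[DockResult], reference_id: str) -> list[str]:
    """Compound ids binding strictly more strongly than the reference.

    Returned sorted by ascending dG_bind (strongest binder first); the
    reference itself is excluded. Strict inequality: ties with the
    reference are not leads.
    """
    by_id = {r.compound_id: r for r in results}
    if reference_id not in by_id:
        raise KeyError(f"reference compound {reference_id!r} not in results")
    ref_dg = by_id[reference_id].dg_bind
    leads = [r for r in results
             if r.compound_id != reference_id and r.dg_bind < ref_dg]
    return [r.compound_id for r in sorted(leads, key=lambda r: r.dg_bind)]


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_docking_table(path: str | Path) -> list[DockResult]:
    """Read a docking summary CSV with columns
    compound_id,dg_bind,n_atm,n_tor,cl_rms,cl_rms_a (empty cell = missing)."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    required = {"compound_id", "dg_bind", "n_atm", "n_tor"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"docking CSV missing columns: {sorted(missing)}")
    results = []
    for row in df.itertuples(index=False):
        results.append(DockResult(
            compound_id=str(row.compound_id),
            dg_bind=float(row.dg_bind),
            n_atm=int(row.n_atm),
            n_tor=int(row.n_tor),
            cl_rms=None if pd.isna(getattr(row, "cl_rms", float("nan"))) else float(row.cl_rms),
            cl_rms_a=None if pd.isna(getattr(row, "cl_rms_a", float("nan"))) else float(row.cl_rms_a),
        ))
    return results


def metrics_table(results: Sequence[DockResult]) -> pd.DataFrame:
    """Docking summary with derived ki_value, ki_unit, ki_molar and le columns."""
    rows = []
    for r in results:
        m = binding_metrics(r)
        rows.append({
            "compound_id": r.compound_id, "dg_bind": r.dg_bind,
            "n_atm": r.n_atm, "n_tor": r.n_tor,
            "cl_rms": r.cl_rms, "cl_rms_a": r.cl_rms_a,
            "ki_molar": m.ki_molar, "ki_value": m.ki_display.value,
            "ki_unit": m.ki_display.unit, "le": m.le,
        })
    return pd.DataFrame(rows)
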