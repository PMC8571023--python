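"""MM-PBSA/GBSA post-analysis: entropy-enthalpy compensation, hot-residue
calls from energy decomposition, and buried surface area.

The end-state free energies obey the compensation identity

    dG = dH - TdS

separately for the Poisson-Boltzmann (PB) and generalized-Born (GB)
solvation models. Per-residue (and pairwise) decomposition assigns each
receptor residue an energetic contribution; residues at or below a negative
threshold (-3.0 kcal/mol per-residue, -6.0 pairwise, by convention here)
are the binding "hot spots". The buried surface area of a complex is half
the total solvent-accessible surface lost on binding:

    BSA = (ASA_pep + ASA_lig - ASA_comp) / 2
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

#: Default per-residue hot-spot threshold, kcal/mol.
PER_RESIDUE_THRESHOLD = -3.0
#: Default pairwise hot-spot threshold, kcal/mol.
PAIRWISE_THRESHOLD = -6.0
#: Compensation audit tolerance, kcal/mol (matches 2-decimal reporting).
COMPENSATION_TOL = 0.01


@dataclass(frozen=True)
class ThermoRecord:
    """One compound's MM-PBSA/GBSA summary (all energies kcal/mol).

    Fields may be None when the corresponding protocol was not run.
    """

    compound_id: str
    dg_pb: float | None = None
    dg_gb: float | None = None
    dg_pr: float | None = None
    gscore: float | None = None
    tds: float | None = None
    dh_pb: float | None = None
    dh_gb: float | None = None
    bsa: float | None = None


@dataclass(frozen=True)
class ResidueEnergy:
    """Decomposed energetic contribution of one receptor residue.

    residue is a name+number label (e.g. "Lys16"); chain identifies the
    receptor chain. Contributions under either solvation model may be
    missing. pairwise marks rows from pairwise (residue-ligand)
    decomposition rather than plain per-residue decomposition.
    """

    residue: str
    chain: str
    dg_pb_contrib: float | None = None
    dg_gb_contrib: float | None = None
    pairwise: bool = False

    @property
    def label(self) -> str:
        return f"{self.residue}({self.chain})"


@dataclass(frozen=True)
class ASARecord:
    """Accessible surface areas (A^2) of peptide, ligand and complex."""

    asa_pep: float
    asa_lig: float
    asa_comp: float

    def __post_init__(self):
        if min(self.asa_pep, self.asa_lig, self.asa_comp) < 0:
            raise ValueError("ASA values must be >= 0")


def gibbs_from_compensation(dh: float, tds: float) -> float:
    """dG = dH - TdS (all kcal/mol)."""
    if not (math.isfinite(dh) and math.isfinite(tds)):
        raise ValueError("dH and TdS must be finite")
    return dh - tds


def check_compensation(record: ThermoRecord,
                       tol: float = COMPENSATION_TOL) -> list[str]:
    """Audit dG_PB = dH_PB - TdS and dG_GB = dH_GB - TdS within tol.

    Returns one message per violated identity; identities whose inputs are
    missing are skipped. An empty list means the record is consistent.
    """
    violations = []
    for model, dg, dh in (("PB", record.dg_pb, record.dh_pb),
                          ("GB", record.dg_gb, record.dh_gb)):
        if dg is None or dh is None or record.tds is None:
            continue
        expected = gibbs_from_compensation(dh, record.tds)
        if abs(dg - expected) > tol:
            violations.append(
                f"{record.compound_id}: dG_{model} = {dg:.2f} but "
                f"dH_{model} - TdS = {expected:.2f} (tol {tol})")
    return violations


def hot_residues(entries: Sequence[ResidueEnergy],
                 threshold: float | None = None,
                 pairwise: bool = False) -> list[ResidueEnergy]:
    """Residues whose contribution is <= threshold in either solvation model.

    The default threshold is -3.0 kcal/mol for per-residue rows and -6.0
    kcal/mol for pairwise rows. "Either model" semantics: a residue
    qualifies when its PB or its GB contribution reaches the threshold.
    """
    if threshold is None:
        threshold = PAIRWISE_THRESHOLD if pairwise else PER_RESIDUE_THRESHOLD
    if not threshold < 0:
        raise ValueError(f"threshold must be negative, got {threshold}")
    out = []
    for e in entries:
        contribs = [c for c in (e.dg_pb_contrib, e.dg_gb_contrib) if c is not None]
        if contribs and min(contribs) <= threshold:
            out.append(e)
    return out


def buried_surface_area(asa: ASARecord, tol: float = 1e-6) -> float:
    """BSA = (ASA_pep + ASA_lig - ASA_comp) / 2, A^2.

    A complex cannot expose more surface than its free components; a
    negative difference beyond tol marks an invalid ASA triple. Small
    negative round-off is clamped to 0.
    """
    bsa = (asa.asa_pep + asa.asa_lig - asa.asa_comp) / 2.0
    if bsa < -tol:
        raise ValueError(f"invalid ASA triple: buried area {bsa:.4f} < 0")
    return max(bsa, 0.0)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def read_thermo_table(path: str | Path) -> list[ThermoRecord]:
    """Read an MM-PBSA/GBSA summary CSV (columns compound_id,dg_pb,dg_gb,
    dg_pr,gscore,tds,dh_pb,dh_gb,bsa; empty cell = missing)."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    return [ThermoRecord(compound_id=str(r.compound_id),
                         dg_pb=_opt(getattr(r, "dg_pb", None)),
                         dg_gb=_opt(getattr(r, "dg_gb", None)),
                         dg_pr=_opt(getattr(r, "dg_pr", None)),
                         gscore=_opt(getattr(r, "gscore", None)),
                         tds=_opt(getattr(r, "tds", None)),
                         dh_pb=_opt(getattr(r, "dh_pb", None)),
                         dh_gb=_opt(getattr(r, "dh_gb", None)),
                         bsa=_opt(getattr(r, "bsa", None)))
            for r in df.itertuples(index=False)]


def read_decomposition_table(path: str | Path) -> dict[str, list[ResidueEnergy]]:
    """Read a long-format decomposition CSV with columns
    compound_id,residue,chain,model,energy (model in {pb, gb}) and an
    optional pairwise column (0/1). Returns entries grouped per compound."""
    df = pd.read_csv(path, dtype={"compound_id": str})
    required = {"compound_id", "residue", "chain", "model", "energy"}
    if not required <= set(df.columns):
        raise ValueError(f"decomposition CSV missing columns: "
                         f"{sorted(required - set(df.columns))}")
    grouped: dict[str, list[ResidueEnergy]] = {}
    key_cols = ["residue", "chain"] + (["pairwise"] if "pairwise" in df.columns else [])
    for cid, sub in df.groupby("compound_id", sort=False):
        entries = []
        for key, rows in sub.groupby(key_cols, sort=False):
            contribs = {m: float(e) for m, e in zip(rows["model"], rows["energy"])}
            unknown = set(contribs) - {"pb", "gb"}
            if unknown:
                raise ValueError(f"unknown solvation model(s): {sorted(unknown)}")
            key = key if isinstance(key, tuple) else (key,)
            entries.append(ResidueEnergy(
                residue=str(key[0]), chain=str(key[1]),
                dg_pb_contrib=contribs.get("pb"),
                dg_gb_contrib=contribs.get("gb"),
                pairwise=bool(key[2]) if len(key) > 2 else False))
        grouped[str(cid)] = entries
    return grouped
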