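"""Blood-brain-barrier partitioning models.

logBB = log10(C_brain / C_blood) is estimated from two published linear
regressions on AlogP and topological PSA:

    Clark:    logBB = 0.152 * AlogP - 0.0148 * PSA + 0.139
    Rishton:  logBB = 0.155 * AlogP - 0.0100 * PSA + 0.164

logBB > 0 marks favourable CNS penetration. A second, independent rule of
thumb flags compounds whose PSA is below the 60-70 A^2 window usually
required of CNS drugs; the permissive upper bound (70 A^2) is the default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

#: Upper bound of the CNS polar-surface-area window, A^2.
PSA_CNS_THRESHOLD = 70.0


def _check_inputs(alogp: float, psa: float) -> None:
    if not (math.isfinite(alogp) and math.isfinite(psa)):
        raise ValueError("AlogP and PSA must be finite")
    if psa < 0:
        raise ValueError(f"PSA must be >= 0, got {psa}")


def logbb_clark(alogp: float, psa: float) -> float:
    """Clark model: 0.152*AlogP - 0.0148*PSA + 0.139."""
    _check_inputs(alogp, psa)
    return 0.152 * alogp - 0.0148 * psa + 0.139


def logbb_rishton(alogp: float, psa: float) -> float:
    """Rishton model: 0.155*AlogP - 0.01*PSA + 0.164."""
    _check_inputs(alogp, psa)
    return 0.155 * alogp - 0.01 * psa + 0.164


@dataclass(frozen=True)
class BBBProfile:
    """logBB under both models plus CNS-permeation flags.

    optimal      True iff both model estimates are strictly positive
    psa_cns_ok   True iff PSA is strictly below the CNS window bound
    logbb_exp    optional experimental logBB annotation (never computed)
    """

    alogp: float
    psa: float
    logbb_cl: float
    logbb_ri: float
    optimal: bool
    psa_cns_ok: bool
    logbb_exp: float | None = None


def bbb_profile(alogp: float, psa: float,
                psa_threshold: float = PSA_CNS_THRESHOLD,
                logbb_exp: float | None = None) -> BBBProfile:
    """Evaluate both logBB models and the CNS flags for one compound."""
    cl = logbb_clark(alogp, psa)
    ri = logbb_rishton(alogp, psa)
    return BBBProfile(alogp=alogp, psa=psa, logbb_cl=cl, logbb_ri=ri,
                      optimal=(cl > 0 and ri > 0),
                      psa_cns_ok=psa < psa_threshold,
                      logbb_exp=logbb_exp)


def annotate_bbb(descriptors: pd.DataFrame,
                 psa_threshold: float = PSA_CNS_THRESHOLD) -> pd.DataFrame:
    """Add logbb_cl, logbb_ri, optimal and psa_cns_ok columns to a
    descriptor table with (at least) columns id-like, alogp, psa."""
    required = {"alogp", "psa"}
    if not required <= set(descriptors.columns):
        raise ValueError(f"descriptor table missing columns: "
                         f"{sorted(required - set(descriptors.columns))}")
    out = descriptors.copy()
    profiles = [bbb_profile(a, p, psa_threshold)
                for a, p in zip(out["alogp"], out["psa"])]
    out["logbb_cl"] = [pr.logbb_cl for pr in profiles]
    out["logbb_ri"] = [pr.logbb_ri for pr in profiles]
    out["optimal"] = [pr.optimal for pr in profiles]
    out["psa_cns_ok"] = [pr.psa_cns_ok for pr in profiles]
    return out


def read_descriptor_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"compound_id": str})
    return df
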