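"""Rumen fermentation statistics: VFA molar percentages, A/P ratio, and ECH4.

Volatile fatty acid (VFA) concentrations are in mM; total VFA (TVFA) is the
sum of the six measured acids (acetate, propionate, butyrate, isobutyrate,
valerate, isovalerate — the iso-acids are included in the denominator of the
molar percentages).  The estimated methane statistic

    ECH4 = 2*Acetate% - Propionate% + 2*Butyrate% - Valerate%

is the stoichiometric molar amount of methane generated per mole of TVFA
produced, computed from molar percentages of TVFA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError

__all__ = [
    "VFA_FIELDS",
    "FermentationRecord",
    "molar_percentages",
    "ech4",
    "acetate_propionate_ratio",
    "fermentation_stats",
]

VFA_FIELDS = ("acetate", "propionate", "butyrate", "isobutyrate", "valerate", "isovalerate")


@dataclass
class FermentationRecord:
    """One sample's fermentation profile (VFAs in mM, NH3-N in mg/dL)."""

    acetate: float
    propionate: float
    butyrate: float
    isobutyrate: float
    valerate: float
    isovalerate: float
    ph: float
    nh3n: float
    tvfa: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        concs = [getattr(self, f) for f in VFA_FIELDS]
        if min(concs) < 0:
            raise UndefinedStatisticError("VFA concentrations must be nonnegative")
        total = float(sum(concs))
        if self.tvfa is None:
            self.tvfa = total
        elif abs(self.tvfa - total) > 1e-6 * max(1.0, total):
            raise UndefinedStatisticError(
                f"tvfa {self.tvfa} does not equal the sum of VFAs {total}"
            )


def molar_percentages(rec: FermentationRecord) -> dict[str, float]:
    """Each VFA's share of TVFA in percent; shares sum to 100."""
    if rec.tvfa <= 0:
        raise UndefinedStatisticError("molar percentages undefined at TVFA = 0")
    return {f: 100.0 * getattr(rec, f) / rec.tvfa for f in VFA_FIELDS}


def ech4(acetate_pct: float, propionate_pct: float, butyrate_pct: float, valerate_pct: float) -> float:
    """Estimated methane: 2*Acetate% - Propionate% + 2*Butyrate% - Valerate%."""
    return 2.0 * acetate_pct - propionate_pct + 2.0 * butyrate_pct - valerate_pct


def acetate_propionate_ratio(rec: FermentationRecord) -> float:
    """Acetate-to-propionate molar ratio."""
    if rec.propionate <= 0:
        raise UndefinedStatisticError("A/P ratio undefined at zero propionate")
    return rec.acetate / rec.propionate


def fermentation_stats(table: pd.DataFrame) -> pd.DataFrame:
    """Add TVFA, molar percentages, A/P ratio and ECH4 columns to a VFA table.

    ``table`` must carry the six VFA columns (mM); other columns (sample ids,
    pH, NH3-N) pass through unchanged.
    """
    out = table.copy()
    vfa = out[list(VFA_FIELDS)].to_numpy(dtype=float)
    if np.any(vfa < 0):
        raise UndefinedStatisticError("VFA concentrations must be nonnegative")
    tvfa = vfa.sum(axis=1)
    if np.any(tvfa <= 0):
        raise UndefinedStatisticError("molar percentages undefined at TVFA = 0")
    out["tvfa"] = tvfa
    for i, f in enumerate(VFA_FIELDS):
        out[f"{f}_pct"] = 100.0 * vfa[:, i] / tvfa
    if np.any(out["propionate"].to_numpy() <= 0):
        raise UndefinedStatisticError("A/P ratio undefined at zero propionate")
    out["ap_ratio"] = out["acetate"] / out["propionate"]
    out["ech4"] = ech4(
        out["acetate_pct"], out["propionate_pct"], out["butyrate_pct"], out["valerate_pct"]
    )
    return out
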