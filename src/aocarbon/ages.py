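"""Radiocarbon mean ages, dilution correction, depth-bin summaries, stocks.

The conventional mean age of a soil layer is Age = -(5730/ln 2) * ln F14C.
Because the ancient radiocarbon-free pool (aOC) dilutes the signal, the
fraction modern of the carbon actually cycling is recovered by

    F14C_active = F14C_SOC / (1 - aOC_ratio)

and its (younger, possibly negative for bomb-influenced layers) age follows
from the same age equation.  Layers are summarized in three depth bins
assigned by layer midpoint - topsoil [0, 30) cm, subsoil [30, 100) cm,
deepsoil [100, inf) cm - optionally grouped by WRB soil group or parent
material, and bin-mean aOC ratios scale published global carbon stocks to
aOC stocks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MEAN_LIFE",
    "DEPTH_BINS",
    "age_from_f14c",
    "corrected_f14c",
    "corrected_age",
    "assign_bin",
    "summarize_bins",
    "first_meter_summary",
    "upscale_stock",
]

#: Mean life of radiocarbon for age calculation, 5730 / ln 2 years.
MEAN_LIFE = 5730.0 / math.log(2.0)

#: Half-open depth bins by layer midpoint, cm below surface.
DEPTH_BINS = (
    ("topsoil", 0.0, 30.0),
    ("subsoil", 30.0, 100.0),
    ("deepsoil", 100.0, math.inf),
)


class AgeError(ValueError):
    pass


def age_from_f14c(f14c: float) -> float:
    """Mean age (years) of carbon with the given fraction modern.

    Negative for super-modern (F14C > 1, bomb-influenced) carbon; dead
    carbon (F14C <= 0) has no finite age and raises.
    """
    if f14c <= 0:
        raise AgeError("F14C must be > 0 (dead carbon has no finite age)")
    return -MEAN_LIFE * math.log(f14c)


def corrected_f14c(f14c: float, aoc_ratio: float) -> float:
    """Fraction modern of the active (non-aOC) carbon: F / (1 - ratio)."""
    if f14c <= 0:
        raise AgeError("F14C must be > 0")
    if not 0.0 <= aoc_ratio < 1.0:
        raise AgeError(f"aOC ratio {aoc_ratio} outside [0, 1)")
    return f14c / (1.0 - aoc_ratio)


def corrected_age(f14c: float, aoc_ratio: float) -> float:
    """Mean age of the active carbon after removing the aOC dilution."""
    return age_from_f14c(corrected_f14c(f14c, aoc_ratio))


def assign_bin(midpoint_cm: float) -> str:
    """Depth bin of a layer midpoint (half-open boundaries)."""
    for name, lo, hi in DEPTH_BINS:
        if lo <= midpoint_cm < hi:
            return name
    raise AgeError(f"midpoint {midpoint_cm} cm cannot be binned")


@dataclass(frozen=True)
class DepthBinSummary:
    bin: str
    group_key: str
    n_layers: int
    mean_ratio: float | None = None
    sd_ratio: float | None = None
    mean_age_raw: float | None = None
    sd_age_raw: float | None = None
    mean_age_corr: float | None = None
    sd_age_corr: float | None = None


def _layer_table(profiles, fits, grouping: str) -> pd.DataFrame:
    """One row per layer of every accepted profile, with ratio and ages."""
    by_id = {f.profile_id: f for f in fits}
    rows = []
    for p in profiles:
        fit = by_id.get(p.profile_id)
        if fit is None or not fit.accepted:
            continue
        if grouping == "overall":
            key = "overall"
        elif grouping == "wrb":
            key = p.wrb_group
        elif grouping == "parent_material":
            key = p.parent_material
        else:
            raise AgeError(f"unknown grouping {grouping!r}")
        for l in p.layers:
            ratio = fit.aoc_mg_g / l.soc_mg_g
            f = l.f14c
            rows.append(
                {
                    "profile_id": p.profile_id,
                    "group_key": key,
                    "bin": assign_bin(l.midpoint_cm),
                    "midpoint_cm": l.midpoint_cm,
                    "ratio": ratio,
                    "age_raw": age_from_f14c(f),
                    "age_corr": corrected_age(f, ratio) if ratio < 1 else np.nan,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "profile_id", "group_key", "bin", "midpoint_cm", "ratio", "age_raw", "age_corr",
        ],
    )


def summarize_bins(profiles, fits, grouping: str = "overall") -> pd.DataFrame:
    """Depth-bin summary table across the layers of accepted profiles.

    Means and SDs are unweighted across layers; bins with a single layer
    report no SD and empty bins report ``n_layers = 0``.
    """
    table = _layer_table(profiles, fits, grouping)
    groups = sorted(table["group_key"].unique()) if len(table) else ["overall"]
    records = []
    for g in groups:
        for name, _, _ in DEPTH_BINS:
            sub = table[(table["group_key"] == g) & (table["bin"] == name)]
            rec = {"group_key": g, "bin": name, "n_layers": len(sub)}
            if len(sub):
                for col, label in (
                    ("ratio", "ratio"), ("age_raw", "age_raw"), ("age_corr", "age_corr"),
                ):
                    rec[f"mean_{label}"] = sub[col].mean()
                    rec[f"sd_{label}"] = sub[col].std(ddof=1) if len(sub) > 1 else np.nan
            records.append(rec)
    cols = [
        "group_key", "bin", "n_layers",
        "mean_ratio", "sd_ratio", "mean_age_raw", "sd_age_raw",
        "mean_age_corr", "sd_age_corr",
    ]
    return pd.DataFrame(records).reindex(columns=cols)


def first_meter_summary(profiles, fits) -> dict:
    """Pooled topsoil + subsoil (midpoint < 100 cm) means for the first meter."""
    table = _layer_table(profiles, fits, "overall")
    sub = table[table["midpoint_cm"] < 100.0]
    if not len(sub):
        return {"n_layers": 0}
    return {
        "n_layers": int(len(sub)),
        "mean_ratio": float(sub["ratio"].mean()),
        "mean_age_raw": float(sub["age_raw"].mean()),
        "sd_age_raw": float(sub["age_raw"].std(ddof=1)),
        "mean_age_corr": float(sub["age_corr"].mean()),
        "sd_age_corr": float(sub["age_corr"].std(ddof=1)),
    }


def upscale_stock(global_stock_gt: float, mean_ratio: float) -> int:
    """Scale a global SOC stock (Gt) by a mean aOC ratio; integer Gt for reporting."""
    if global_stock_gt <= 0:
        raise AgeError("stock must be > 0")
    if not 0.0 <= mean_ratio < 1.0:
        raise AgeError("mean ratio must be in [0, 1)")
    return int(round(global_stock_gt * mean_ratio))
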