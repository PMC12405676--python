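"""Soil profile and layer containers plus ISRaD-like table readers.

Profiles arrive as two delimited tables: one row per profile (location,
sampling year, WRB soil group, parent material, loess flag) and one row per
layer (depths in cm, SOC mass concentration in mg C per g dry soil, and a
radiocarbon measurement as either fraction modern F14C or Delta14C per
mil).  Column names can be remapped to accommodate database exports.

Selection follows the meta-analysis rules: layers with SOC >= 120 mg/g are
considered organic and dropped; a profile is retained only if at least 4
layers survive and they span at least 50 cm of depth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "read_profiles",
    "delta14c_to_f14c",
    "f14c_to_delta14c",
    "select_profiles",
]

#: Mean life of radiocarbon (Libby, 8267 yr) used by the Delta14C reporting
#: convention; distinct from the 5730-yr half-life used for ages.
MEAN_LIFE_LIBBY = 8267.0

SOC_ORGANIC_LIMIT = 120.0  # mg/g; layers at or above are not mineral soil
MIN_LAYERS = 4
MIN_SPAN_CM = 50.0

PROFILE_COLUMNS = (
    "profile_id latitude longitude sampling_year wrb_group parent_material is_loess"
).split()
LAYER_COLUMNS = "profile_id top_cm bottom_cm soc_mg_g".split()


class ProfileError(ValueError):
    """Raised for malformed profile/layer tables."""


@dataclass
class SoilLayer:
    top_cm: float
    bottom_cm: float
    soc_mg_g: float
    f14c_raw: float | None = None
    delta14c: float | None = None
    f14c_2000: float | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not 0 <= self.top_cm < self.bottom_cm:
            raise ProfileError(
                f"invalid depths top={self.top_cm}, bottom={self.bottom_cm} "
                "(need 0 <= top < bottom)"
            )
        if self.soc_mg_g <= 0:
            raise ProfileError(f"SOC must be > 0 mg/g, got {self.soc_mg_g}")
        if (self.f14c_raw is None) == (self.delta14c is None):
            raise ProfileError("exactly one of f14c_raw / delta14c must be given")

    @property
    def midpoint_cm(self) -> float:
        return 0.5 * (self.top_cm + self.bottom_cm)

    @property
    def f14c(self) -> float:
        """Best available fraction modern: normalized if filled, else raw."""
        return self.f14c_2000 if self.f14c_2000 is not None else self.f14c_raw


@dataclass
class SoilProfile:
    profile_id: str
    latitude: float
    longitude: float
    sampling_year: int
    wrb_group: str = "unknown"
    parent_material: str = "unknown"
    is_loess: bool = False
    layers: list[SoilLayer] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.layers = sorted(self.layers, key=lambda l: l.top_cm)

    @property
    def depth_span_cm(self) -> float:
        if not self.layers:
            return 0.0
        return max(l.bottom_cm for l in self.layers) - min(l.top_cm for l in self.layers)


def delta14c_to_f14c(delta14c: float, measurement_year: float) -> float:
    """Convert a Delta14C (per mil) to fraction modern.

    F = (Delta/1000 + 1) * exp((year - 1950) / 8267).
    """
    if delta14c < -1000.0:
        raise ProfileError(f"Delta14C {delta14c} < -1000 per mil implies negative F14C")
    return (delta14c / 1000.0 + 1.0) * math.exp((measurement_year - 1950.0) / MEAN_LIFE_LIBBY)


def f14c_to_delta14c(f14c: float, measurement_year: float) -> float:
    """Inverse of :func:`delta14c_to_f14c`."""
    if f14c < 0:
        raise ProfileError("F14C must be >= 0")
    return (f14c * math.exp(-(measurement_year - 1950.0) / MEAN_LIFE_LIBBY) - 1.0) * 1000.0


def _read_table(source, column_map: dict[str, str] | None) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    df.columns = [str(c).strip() for c in df.columns]
    if column_map:
        df = df.rename(columns=column_map)
    return df


def read_profiles(
    profile_table,
    layer_table,
    profile_column_map: dict[str, str] | None = None,
    layer_column_map: dict[str, str] | None = None,
) -> list[SoilProfile]:
    """Join profile and layer tables into :class:`SoilProfile` objects.

    Layers referencing unknown profile ids and duplicate (profile, top,
    bottom) records are hard errors; unknown metadata is preserved as
    ``unknown``, never dropped.  Layers missing a bottom depth are skipped
    (depth binning and span checks need both bounds).
    """
    pdf = _read_table(profile_table, profile_column_map)
    ldf = _read_table(layer_table, layer_column_map)
    missing = [c for c in PROFILE_COLUMNS[:4] if c not in pdf.columns]
    if missing:
        raise ProfileError(f"profile table missing columns: {missing}")
    missing = [c for c in LAYER_COLUMNS if c not in ldf.columns]
    if missing:
        raise ProfileError(f"layer table missing columns: {missing}")
    if "f14c" not in ldf.columns and "delta14c" not in ldf.columns:
        raise ProfileError("layer table needs an 'f14c' or 'delta14c' column")

    known = set(pdf["profile_id"].astype(str))
    orphans = sorted(set(ldf["profile_id"].astype(str)) - known)
    if orphans:
        raise ProfileError(f"layers reference unknown profile ids: {orphans}")
    dup = ldf.duplicated(subset=["profile_id", "top_cm", "bottom_cm"], keep=False)
    if dup.any():
        bad = ldf.loc[dup, ["profile_id", "top_cm", "bottom_cm"]].drop_duplicates()
        raise ProfileError(f"duplicate layer records:\n{bad}")

    profiles = []
    grouped = dict(tuple(ldf.groupby(ldf["profile_id"].astype(str).rename("_pid"))))
    for _, row in pdf.iterrows():
        pid = str(row["profile_id"])
        year = int(row["sampling_year"])
        layers = []
        if pid in grouped:
            for _, lr in grouped[pid].iterrows():
                if pd.isna(lr["bottom_cm"]):
                    continue
                f14c = lr.get("f14c")
                delta = lr.get("delta14c")
                has_f = f14c is not None and not pd.isna(f14c)
                has_d = delta is not None and not pd.isna(delta)
                if has_f:
                    kw = {"f14c_raw": float(f14c)}
                elif has_d:
                    kw = {"f14c_raw": delta14c_to_f14c(float(delta), year)}
                else:
                    continue
                layers.append(
                    SoilLayer(
                        top_cm=float(lr["top_cm"]),
                        bottom_cm=float(lr["bottom_cm"]),
                        soc_mg_g=float(lr["soc_mg_g"]),
                        **kw,
                    )
                )
        profiles.append(
            SoilProfile(
                profile_id=pid,
                latitude=float(row["latitude"]),
                longitude=float(row["longitude"]),
                sampling_year=year,
                wrb_group=str(row.get("wrb_group", "unknown") or "unknown"),
                parent_material=str(row.get("parent_material", "unknown") or "unknown"),
                is_loess=bool(row.get("is_loess", False)),
                layers=layers,
            )
        )
    return profiles


def select_profiles(
    profiles: list[SoilProfile],
    soc_limit: float = SOC_ORGANIC_LIMIT,
    min_layers: int = MIN_LAYERS,
    min_span_cm: float = MIN_SPAN_CM,
) -> tuple[list[SoilProfile], list[tuple[SoilProfile, str]]]:
    """Apply the mineral-layer and profile-coverage filters.

    Per profile: drop layers with SOC >= ``soc_limit`` (120 mg/g, strict
    "below" reading), then retain the profile only if at least
    ``min_layers`` layers survive and they span at least ``min_span_cm``.
    Returns (retained, rejected-with-reason); the two lists partition the
    input.
    """
    retained: list[SoilProfile] = []
    rejected: list[tuple[SoilProfile, str]] = []
    for p in profiles:
        surviving = [l for l in p.layers if l.soc_mg_g < soc_limit]
        if len(surviving) < min_layers:
            rejected.append((p, f"fewer than {min_layers} mineral layers"))
            continue
        span = max(l.bottom_cm for l in surviving) - min(l.top_cm for l in surviving)
        if span < min_span_cm:
            rejected.append((p, f"depth span {span:g} cm < {min_span_cm:g} cm"))
            continue
        kept = SoilProfile(
            profile_id=p.profile_id,
            latitude=p.latitude,
            longitude=p.longitude,
            sampling_year=p.sampling_year,
            wrb_group=p.wrb_group,
            parent_material=p.parent_material,
            is_loess=p.is_loess,
            layers=surviving,
        )
        retained.append(kept)
    return retained, rejected
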