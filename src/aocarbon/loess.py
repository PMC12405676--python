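"""Three-source correction for loess-derived soil profiles.

Soils developed in loess carry, besides the ancient radiocarbon-free pool
and the biologically active pool, a glacial-age biospheric pool: organic
matter of the vegetation that stabilized the dust at deposition (typically
15-25 kyr old).  Where its concentration and age are known from nearby
paleoclimatic records, that pool is removed by mass balance before the
binary mixing regression:

    SOC' = SOC - C_g
    F'   = (SOC * F - C_g * F_g) / SOC'

with F_g = exp(-age * ln2 / 5730).  The corrected layers then follow the
standard two-component analysis.  The glacial pool is taken constant with
depth within a profile, mirroring the constancy assumption made for aOC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import warnings

from .profiles import SoilLayer, SoilProfile

__all__ = ["LoessPool", "glacial_pool_f14c", "correct_loess_layer", "correct_loess_profile"]

HALF_LIFE = 5730.0


class LoessError(ValueError):
    """Raised for inconsistent glacial-pool specifications."""


def glacial_pool_f14c(age_glacial_yr: float) -> float:
    """Fraction modern implied by a radiocarbon age: F = exp(-age * ln2 / 5730)."""
    if age_glacial_yr < 0:
        raise LoessError("glacial pool age must be >= 0")
    return math.exp(-age_glacial_yr * math.log(2.0) / HALF_LIFE)


@dataclass(frozen=True)
class LoessPool:
    """Glacial-age biospheric pool of a loess profile (site-literature input)."""

    c_glacial_mg_g: float
    age_glacial_yr: float
    f14c_glacial: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.c_glacial_mg_g < 0:
            raise LoessError("glacial pool concentration must be >= 0")
        if not 10_000 <= self.age_glacial_yr <= 60_000:
            warnings.warn(
                f"glacial pool age {self.age_glacial_yr} yr outside the typical "
                "10-60 kyr window",
                stacklevel=2,
            )
        if self.f14c_glacial is None:
            object.__setattr__(
                self, "f14c_glacial", glacial_pool_f14c(self.age_glacial_yr)
            )


def correct_loess_layer(layer: SoilLayer, pool: LoessPool) -> tuple[float, float]:
    """Remove the glacial pool from one layer by mass balance.

    Returns the corrected ``(soc_mg_g, f14c)``.  Uses the layer's best
    available fraction modern (normalized where filled, raw otherwise).
    """
    soc = layer.soc_mg_g
    f = layer.f14c
    cg = pool.c_glacial_mg_g
    if cg == 0.0:
        return soc, f
    if soc <= cg:
        raise LoessError(
            f"glacial pool ({cg} mg/g) meets or exceeds layer SOC ({soc} mg/g)"
        )
    soc_c = soc - cg
    f_c = (soc * f - cg * pool.f14c_glacial) / soc_c
    if f_c < 0:
        raise LoessError(
            "corrected F14C < 0: glacial pool specification inconsistent with "
            f"layer (SOC={soc}, F={f}, C_g={cg}, F_g={pool.f14c_glacial:.4f})"
        )
    return soc_c, f_c


def correct_loess_profile(profile: SoilProfile, pool: LoessPool) -> SoilProfile:
    """Profile with the glacial pool removed from every layer.

    The corrected fraction modern is stored in ``f14c_2000`` (the slot the
    mixing fit reads) and layers are flagged ``loess_corrected``.
    """
    layers = []
    for l in profile.layers:
        soc_c, f_c = correct_loess_layer(l, pool)
        new = SoilLayer(
            top_cm=l.top_cm,
            bottom_cm=l.bottom_cm,
            soc_mg_g=soc_c,
            f14c_raw=l.f14c_raw,
            f14c_2000=f_c,
            flags=set(l.flags) | {"loess_corrected"},
        )
        layers.append(new)
    return SoilProfile(
        profile_id=profile.profile_id,
        latitude=profile.latitude,
        longitude=profile.longitude,
        sampling_year=profile.sampling_year,
        wrb_group=profile.wrb_group,
        parent_material=profile.parent_material,
        is_loess=True,
        layers=layers,
    )
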