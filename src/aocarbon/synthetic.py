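"""Synthetic soil-profile generator with known ground truth.

Generates datasets with the exact statistical structure the aOC analysis
assumes: each profile carries a constant ancient radiocarbon-free pool
(F14C = 0) drawn from a configurable range, an active pool whose fraction
modern follows the one-pool model under a synthetic atmosphere (pre-1955
plateau, linear rise to a bomb peak, exponential relaxation), SOC declining
exponentially with depth toward a deep asymptote, and optional Gaussian
measurement noise on the composite F14C.  Ground truth (per-profile aOC,
per-layer turnover and active-pool F14C) is recorded for parameter-recovery
tests.

Default parameter choices emulate the source meta-analysis population:
aOC uniform on 0-5 mg/g (population mean ~2.5 mg/g), mineral-soil SOC
(surface 20-80 mg/g decaying to ~6 mg/g at depth, all below the 120 mg/g
organic limit), active-pool turnover from 50 yr at the surface to 5 kyr at
2 m, sampling years 1990-2015, and 0.02 fraction-modern measurement noise.
Setting ``turnover_deep_yr == turnover_surface_yr`` yields a single active
end-member per dataset, the regime in which the binary mixing model is
exactly specified (used by recovery tests); the depth-increasing default
deliberately violates it the way real profiles do.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .forcing import AtmosphereCurve
from .loess import LoessPool, glacial_pool_f14c
from .onepool import TURNOVER_MAX, TURNOVER_MIN, build_lookup
from .profiles import SoilLayer, SoilProfile

__all__ = ["SyntheticSpec", "make_atmosphere", "simulate_profile", "generate_dataset", "write_dataset"]

_WRB_TAGS = ("Cambisols", "Luvisols", "Podzols", "Andosols", "Cryosols", "Ferralsols")
_PARENT_TAGS = (
    "surficial deposits", "sedimentary deposits", "sedimentary rocks",
    "volcanic rocks", "plutonic rocks", "metamorphic rocks",
)


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic dataset (seed + spec => identical files)."""

    seed: int = 0
    n_profiles: int = 200
    aoc_range: tuple[float, float] = (0.0, 5.0)
    soc_surface_range: tuple[float, float] = (20.0, 80.0)
    soc_deep_mg_g: float = 6.0
    soc_decay_depth_cm: float = 40.0
    turnover_surface_yr: float = 50.0
    turnover_deep_yr: float = 5000.0
    noise_sd_f14c: float = 0.02
    noise_sd_soc_rel: float = 0.0
    layer_grid: tuple[float, ...] = (0.0, 10.0, 25.0, 45.0, 70.0, 100.0, 150.0, 200.0)
    sampling_year_range: tuple[int, int] = (1990, 2015)
    loess_fraction: float = 0.0
    glacial_c_mg_g: float = 2.0
    glacial_age_yr: float = 18000.0
    atm_plateau: float = 1.0
    atm_peak_year: int = 1964
    atm_peak_f14c: float = 1.8
    atm_efold_yr: float = 16.0
    end_year: int = 2020

    def __post_init__(self) -> None:
        if self.atm_plateau <= 0:
            raise SyntheticError("atmosphere plateau must be > 0")
        if self.atm_peak_f14c < self.atm_plateau:
            raise SyntheticError("bomb peak height must be >= plateau")
        if self.atm_peak_year < 1955:
            raise SyntheticError("bomb peak year must be >= 1955")
        if len(self.layer_grid) < 2 or np.any(np.diff(self.layer_grid) <= 0):
            raise SyntheticError("layer_grid must be increasing depth boundaries")
        if not 0.0 <= self.loess_fraction <= 1.0:
            raise SyntheticError("loess_fraction must be in [0, 1]")


def make_atmosphere(spec: SyntheticSpec) -> AtmosphereCurve:
    """Annual synthetic forcing: plateau, linear bomb rise, exponential relaxation."""
    years = np.arange(-53000, spec.end_year + 1, dtype=np.int64)
    f = np.full(years.shape, spec.atm_plateau, dtype=np.float64)
    rise = (years > 1955) & (years <= spec.atm_peak_year)
    f[rise] = spec.atm_plateau + (spec.atm_peak_f14c - spec.atm_plateau) * (
        (years[rise] - 1955) / (spec.atm_peak_year - 1955)
    )
    tail = years > spec.atm_peak_year
    f[tail] = spec.atm_plateau + (spec.atm_peak_f14c - spec.atm_plateau) * np.exp(
        -(years[tail] - spec.atm_peak_year) / spec.atm_efold_yr
    )
    return AtmosphereCurve("synthetic", years, f)


def _turnover_at(spec: SyntheticSpec, depth_cm: float) -> float:
    """Active-pool turnover, log-linear in depth between surface and 2 m."""
    lo = np.log(spec.turnover_surface_yr)
    hi = np.log(spec.turnover_deep_yr)
    t = float(np.exp(lo + (hi - lo) * depth_cm / 200.0))
    return float(np.clip(t, TURNOVER_MIN, TURNOVER_MAX))


def simulate_profile(
    spec: SyntheticSpec, index: int, curve: AtmosphereCurve | None = None
) -> tuple[SoilProfile, dict]:
    """Draw one profile and its ground-truth record (deterministic in seed+index)."""
    if curve is None:
        curve = make_atmosphere(spec)
    rng = np.random.default_rng([spec.seed, index])
    pid = f"syn{index:04d}"
    year = int(rng.integers(spec.sampling_year_range[0], spec.sampling_year_range[1] + 1))
    lookup = build_lookup(curve, year)

    is_loess = index < spec.loess_fraction * spec.n_profiles
    c_g = spec.glacial_c_mg_g if is_loess else 0.0
    f_g = glacial_pool_f14c(spec.glacial_age_yr) if is_loess else 0.0

    tops = np.asarray(spec.layer_grid[:-1])
    bottoms = np.asarray(spec.layer_grid[1:])
    mids = 0.5 * (tops + bottoms)
    surf = rng.uniform(*spec.soc_surface_range)
    soc = spec.soc_deep_mg_g + (surf - spec.soc_deep_mg_g) * np.exp(
        -mids / spec.soc_decay_depth_cm
    )
    if spec.noise_sd_soc_rel > 0:
        soc = soc * (1.0 + spec.noise_sd_soc_rel * rng.standard_normal(soc.size))
        soc = np.maximum(soc, 0.5)

    # keep the active pool positive in every layer, glacial pool included
    aoc_hi = min(spec.aoc_range[1], 0.9 * (soc.min() - c_g))
    aoc_lo = min(spec.aoc_range[0], aoc_hi)
    aoc = float(rng.uniform(aoc_lo, aoc_hi))

    layers, truth_layers = [], []
    for top, bottom, mid, s in zip(tops, bottoms, mids, soc):
        tau = _turnover_at(spec, mid)
        f_active = lookup.value_at(tau)
        f_true = ((s - aoc - c_g) * f_active + c_g * f_g) / s
        f_meas = f_true
        if spec.noise_sd_f14c > 0:
            for _ in range(100):
                f_meas = f_true + spec.noise_sd_f14c * rng.standard_normal()
                if f_meas > 0:
                    break
            else:
                raise SyntheticError(
                    f"profile {pid}: could not draw positive F14C at {mid} cm"
                )
        layers.append(
            SoilLayer(top_cm=float(top), bottom_cm=float(bottom),
                      soc_mg_g=float(s), f14c_raw=float(f_meas))
        )
        truth_layers.append(
            {"top_cm": float(top), "bottom_cm": float(bottom),
             "turnover_yr": tau, "f14c_active": f_active, "f14c_noise_free": f_true}
        )

    profile = SoilProfile(
        profile_id=pid,
        latitude=float(np.round(rng.uniform(-60.0, 70.0), 4)),
        longitude=float(np.round(rng.uniform(-180.0, 180.0), 4)),
        sampling_year=year,
        wrb_group=_WRB_TAGS[index % len(_WRB_TAGS)],
        parent_material="loess" if is_loess else _PARENT_TAGS[index % len(_PARENT_TAGS)],
        is_loess=is_loess,
        layers=layers,
    )
    truth = {
        "profile_id": pid,
        "aoc_mg_g": aoc,
        "sampling_year": year,
        "is_loess": is_loess,
        "c_glacial_mg_g": c_g,
        "age_glacial_yr": spec.glacial_age_yr if is_loess else 0.0,
        "layers": truth_layers,
    }
    return profile, truth


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[SoilProfile], list[dict], AtmosphereCurve]:
    """All profiles of a spec plus their truth records and the forcing curve."""
    curve = make_atmosphere(spec)
    profiles, truths = [], []
    for i in range(spec.n_profiles):
        p, t = simulate_profile(spec, i, curve)
        profiles.append(p)
        truths.append(t)
    return profiles, truths, curve


def write_dataset(profiles, truths, out_dir, spec: SyntheticSpec | None = None) -> dict:
    """Write profiles.csv / layers.csv / truth.csv (+ atmosphere.csv, manifest).

    The tables round-trip through :func:`aocarbon.profiles.read_profiles`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prof_rows = [
        {
            "profile_id": p.profile_id, "latitude": p.latitude, "longitude": p.longitude,
            "sampling_year": p.sampling_year, "wrb_group": p.wrb_group,
            "parent_material": p.parent_material, "is_loess": p.is_loess,
        }
        for p in profiles
    ]
    layer_rows = [
        {
            "profile_id": p.profile_id, "top_cm": l.top_cm, "bottom_cm": l.bottom_cm,
            "soc_mg_g": l.soc_mg_g, "f14c": l.f14c_raw,
        }
        for p in profiles
        for l in p.layers
    ]
    truth_rows = [
        {
            "profile_id": t["profile_id"], "aoc_mg_g": t["aoc_mg_g"],
            "sampling_year": t["sampling_year"], "is_loess": t["is_loess"],
            "c_glacial_mg_g": t["c_glacial_mg_g"], "age_glacial_yr": t["age_glacial_yr"],
            **tl,
        }
        for t in truths
        for tl in t["layers"]
    ]
    paths = {
        "profiles": out / "profiles.csv",
        "layers": out / "layers.csv",
        "truth": out / "truth.csv",
    }
    pd.DataFrame(prof_rows, columns=list(prof_rows[0]) if prof_rows else [
        "profile_id", "latitude", "longitude", "sampling_year", "wrb_group",
        "parent_material", "is_loess"]).to_csv(paths["profiles"], index=False)
    pd.DataFrame(layer_rows, columns=list(layer_rows[0]) if layer_rows else [
        "profile_id", "top_cm", "bottom_cm", "soc_mg_g", "f14c"]).to_csv(
        paths["layers"], index=False)
    pd.DataFrame(truth_rows, columns=list(truth_rows[0]) if truth_rows else [
        "profile_id", "aoc_mg_g", "sampling_year", "is_loess", "c_glacial_mg_g",
        "age_glacial_yr", "top_cm", "bottom_cm", "turnover_yr", "f14c_active",
        "f14c_noise_free"]).to_csv(paths["truth"], index=False)
    if spec is not None:
        curve = make_atmosphere(spec)
        atm = pd.DataFrame({"year": curve.years, "f14c": curve.f14c})
        atm.to_csv(out / "atmosphere.csv", index=False)
        paths["atmosphere"] = out / "atmosphere.csv"
        manifest = {"generator": "aocarbon.synthetic", "spec": dataclasses.asdict(spec)}
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        paths["manifest"] = out / "manifest.yaml"
    return {k: str(v) for k, v in paths.items()}
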