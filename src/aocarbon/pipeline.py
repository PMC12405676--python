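"""End-to-end orchestration: load, select, normalize, correct, fit, summarize.

Stages mirror the analysis chain: atmospheric forcing -> profile selection
-> normalization of layer F14C to year 2000 via the one-pool model ->
loess three-source correction where configured -> per-profile binary
mixing fits with quality screening and LOQ -> per-layer aOC ratios ->
depth-bin age summaries -> global stock upscaling.  Every stage writes its
table to the output directory and a manifest records the configuration
hash, seed, package version and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ages import DEPTH_BINS, first_meter_summary, summarize_bins, upscale_stock
from .forcing import AtmosphereCurve, load_curve, splice_and_annualize, zone_for_latitude
from .loess import LoessPool, correct_loess_profile
from .mixing import DegenerateFitError, compute_loq, fit_mixing
from .onepool import default_grid, normalize_to_2000
from .profiles import read_profiles, select_profiles

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger("aocarbon")

DEFAULT_STOCKS = {"topsoil_gt": 704.0, "subsoil_gt": 801.0, "deepsoil_gt": 910.0}
_STOCK_BIN = {"topsoil_gt": "topsoil", "subsoil_gt": "subsoil", "deepsoil_gt": "deepsoil"}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending profiles."""


def normalize_profiles(
    profiles,
    curve,
    cutoff: float = 0.16,
    reference_year: int = 2000,
    grid=None,
) -> None:
    """Fill ``f14c_2000`` (and flags) on every layer using one forcing curve."""
    for p in profiles:
        for l in p.layers:
            value, flags = normalize_to_2000(
                l.f14c_raw, p.sampling_year, curve,
                cutoff=cutoff, reference_year=reference_year, grid=grid,
            )
            if "unnormalized" in flags:
                l.flags |= flags
            else:
                l.f14c_2000 = value
                l.flags |= flags


@dataclass
class RunConfig:
    profiles_csv: str = ""
    layers_csv: str = ""
    out_dir: str = "aocarbon_out"
    seed: int = 0
    curve_csv: str | None = None
    prebomb_csv: str | None = None
    postbomb_csv: dict[str, str] = field(default_factory=dict)
    nh_lat_min: float = 15.0
    sh_lat_max: float = -15.0
    extension: str = "hold"
    start_year: int = -53000
    grid_points: int = 600
    f14c_cutoff: float = 0.16
    reference_year: int = 2000
    loess: dict[str, dict] = field(default_factory=dict)
    stocks: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STOCKS))
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        for key, value in raw.items():
            if key == "forcing":
                for k, v in value.items():
                    flat[k] = v
            elif key == "onepool":
                for k, v in value.items():
                    flat[k] = v
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Hash of the analysis-defining fields (output location excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k not in ("out_dir", "log_level")}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _load_curves(config: RunConfig, end_year: int) -> dict[str, AtmosphereCurve]:
    """Forcing per zone: one spliced curve, or prebomb + zonal postbomb records."""
    if config.curve_csv:
        curve = load_curve(config.curve_csv)
        curve = splice_and_annualize(
            curve, None, end_year, start_year=config.start_year, extension=config.extension
        )
        return {z: curve for z in ("NH", "Tropics", "SH", "synthetic")}
    if not config.prebomb_csv or not config.postbomb_csv:
        raise PipelineError(
            "forcing: provide either curve_csv or prebomb_csv + postbomb_csv"
        )
    prebomb = load_curve(config.prebomb_csv)
    curves = {}
    for zone, path in config.postbomb_csv.items():
        post = load_curve(path, zone=zone)
        curves[zone] = splice_and_annualize(
            prebomb, post, end_year, start_year=config.start_year,
            extension=config.extension,
        )
    return curves


def run_pipeline(config: RunConfig, write: bool = True) -> dict:
    """Execute all stages; returns tables, fits and the manifest."""
    logging.basicConfig(level=config.log_level)
    for name in ("profiles_csv", "layers_csv"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            raise PipelineError(f"pre-flight: {name} path missing or not found: {path!r}")

    profiles = read_profiles(config.profiles_csv, config.layers_csv)
    n_layers_in = sum(len(p.layers) for p in profiles)
    retained, rejected = select_profiles(profiles)
    log.info("selected %d/%d profiles", len(retained), len(profiles))

    end_year = max(
        [p.sampling_year for p in profiles] + [config.reference_year]
    )
    curves = _load_curves(config, end_year)
    grid = default_grid(config.grid_points)

    # normalization of each layer's F14C to the reference year
    for p in retained:
        zone = zone_for_latitude(p.latitude, config.nh_lat_min, config.sh_lat_max)
        curve = curves.get(zone) or next(iter(curves.values()))
        for l in p.layers:
            try:
                value, flags = normalize_to_2000(
                    l.f14c_raw, p.sampling_year, curve,
                    cutoff=config.f14c_cutoff,
                    reference_year=config.reference_year, grid=grid,
                )
            except Exception as exc:
                raise PipelineError(
                    f"normalize: profile {p.profile_id} layer "
                    f"{l.top_cm}-{l.bottom_cm} cm: {exc}"
                ) from exc
            if "unnormalized" in flags:
                l.flags |= flags
            else:
                l.f14c_2000 = value
                l.flags |= flags

    # loess three-source correction for configured profiles
    corrected = []
    for p in retained:
        block = config.loess.get(p.profile_id)
        if block:
            pool = LoessPool(
                c_glacial_mg_g=float(block["c_glacial_mg_g"]),
                age_glacial_yr=float(block["age_glacial_yr"]),
            )
            try:
                p = correct_loess_profile(p, pool)
            except Exception as exc:
                raise PipelineError(f"loess: profile {p.profile_id}: {exc}") from exc
        corrected.append(p)

    fits, fit_errors = [], []
    for p in corrected:
        try:
            fits.append(fit_mixing(p))
        except DegenerateFitError as exc:
            fit_errors.append((p.profile_id, str(exc)))
    if fit_errors:
        log.warning("degenerate fits skipped: %s", [pid for pid, _ in fit_errors])
    loq = compute_loq(fits)
    accepted = [f for f in fits if f.accepted]
    log.info("accepted %d/%d fits; LOQ = %.3f mg/g", len(accepted), len(fits), loq)

    fits_table = pd.DataFrame([f.to_record() for f in fits])
    by_id = {f.profile_id: f for f in fits}
    ratio_rows = [
        {
            "profile_id": p.profile_id, "top_cm": l.top_cm, "bottom_cm": l.bottom_cm,
            "soc_mg_g": l.soc_mg_g,
            "f14c": l.f14c,
            "aoc_ratio": by_id[p.profile_id].aoc_mg_g / l.soc_mg_g
            if p.profile_id in by_id and by_id[p.profile_id].valid
            else np.nan,
            "flags": ";".join(sorted(l.flags)),
        }
        for p in corrected
        for l in p.layers
        if p.profile_id in by_id
    ]
    ratios_table = pd.DataFrame(ratio_rows)

    summaries = {
        grouping: summarize_bins(corrected, fits, grouping=grouping)
        for grouping in ("overall", "wrb", "parent_material")
    }
    first_meter = first_meter_summary(corrected, fits)

    overall = summaries["overall"]
    stock_rows = []
    for key, stock in config.stocks.items():
        bin_name = _STOCK_BIN.get(key)
        if bin_name is None:
            raise PipelineError(f"stocks: unknown key {key!r}")
        row = overall[overall["bin"] == bin_name]
        ratio = float(row["mean_ratio"].iloc[0]) if len(row) and row["n_layers"].iloc[0] else np.nan
        stock_rows.append(
            {
                "bin": bin_name, "stock_gt": stock, "mean_ratio": ratio,
                "aoc_stock_gt": upscale_stock(stock, ratio) if np.isfinite(ratio) else np.nan,
            }
        )
    stocks_table = pd.DataFrame(stock_rows)

    manifest = {
        "package_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "counts": {
            "profiles_in": len(profiles),
            "profiles_selected": len(retained),
            "profiles_rejected": len(rejected),
            "layers_in": n_layers_in,
            "layers_analyzed": int(sum(len(p.layers) for p in retained)),
            "layers_dropped": int(
                n_layers_in - sum(len(p.layers) for p in retained)
            ),
            "fits": len(fits),
            "fits_accepted": len(accepted),
            "fit_errors": len(fit_errors),
        },
        "loq_mg_g": loq,
        "first_meter": first_meter,
        "rejections": [
            {"profile_id": p.profile_id, "reason": reason} for p, reason in rejected
        ],
        "fit_errors": [{"profile_id": pid, "error": msg} for pid, msg in fit_errors],
    }

    result = {
        "profiles": corrected,
        "fits": fits,
        "loq": loq,
        "fits_table": fits_table,
        "ratios_table": ratios_table,
        "summaries": summaries,
        "stocks_table": stocks_table,
        "manifest": manifest,
    }

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        fits_table.to_csv(out / "fits.csv", index=False)
        ratios_table.to_csv(out / "layer_ratios.csv", index=False)
        for grouping, table in summaries.items():
            table.to_csv(out / f"summary_{grouping}.csv", index=False)
        stocks_table.to_csv(out / "stocks.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        result["out_dir"] = str(out)
    return result
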