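"""Atmospheric radiocarbon forcing curves.

The one-pool soil model is driven by an annual time series of atmospheric
F14C (fraction modern).  Real analyses splice a pre-bomb calibration record
(IntCal-style, extending back beyond 50 kyr BP) with a zonal post-bomb
record (Hua-style, Northern Hemisphere / Tropics / Southern Hemisphere).
This module loads such records from delimited text, splices them, resamples
to annual resolution and assigns hemispheric zones by latitude.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AtmosphereCurve",
    "ZONES",
    "load_curve",
    "splice_and_annualize",
    "zone_for_latitude",
]

ZONES = ("NH", "Tropics", "SH", "synthetic")

#: Earliest calendar year the spliced forcing must reach (53 kyr before present,
#: the limit of the radiocarbon method).
DEFAULT_START_YEAR = -53000


class ForcingError(ValueError):
    """Raised for invalid or inconsistent atmospheric forcing data."""


@dataclass(frozen=True)
class AtmosphereCurve:
    """An atmospheric F14C time series for one zone.

    Parameters
    ----------
    zone : str
        One of ``NH``, ``Tropics``, ``SH`` or ``synthetic``.
    years : ndarray of int
        Calendar years, strictly increasing.  After annualization consecutive
        years differ by exactly 1.
    f14c : ndarray of float
        Atmospheric fraction modern per year; strictly positive.
    """

    zone: str
    years: np.ndarray
    f14c: np.ndarray
    _digest: str = field(default="", compare=False, repr=False)

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=np.int64)
        f14c = np.asarray(self.f14c, dtype=np.float64)
        if self.zone not in ZONES:
            raise ForcingError(f"unknown zone {self.zone!r}; expected one of {ZONES}")
        if years.ndim != 1 or years.shape != f14c.shape:
            raise ForcingError("years and f14c must be 1-D arrays of equal length")
        if years.size < 2:
            raise ForcingError("a curve needs at least 2 points")
        if np.any(np.diff(years) <= 0):
            raise ForcingError("years must be strictly increasing")
        if not np.all(np.isfinite(f14c)) or np.any(f14c <= 0):
            raise ForcingError("all F14C values must be finite and > 0")
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "f14c", f14c)
        h = hashlib.sha1()
        h.update(years.tobytes())
        h.update(f14c.tobytes())
        h.update(self.zone.encode())
        object.__setattr__(self, "_digest", h.hexdigest())

    @property
    def is_annual(self) -> bool:
        return bool(np.all(np.diff(self.years) == 1))

    def value_at(self, years):
        """F14C_atm at the given integer year(s); errors outside coverage."""
        years = np.asarray(years)
        if np.any(years < self.years[0]) or np.any(years > self.years[-1]):
            raise ForcingError(
                f"year(s) outside curve coverage [{self.years[0]}, {self.years[-1]}]"
            )
        return np.interp(years, self.years, self.f14c)


def load_curve(source, zone: str = "synthetic") -> AtmosphereCurve:
    """Read a year/F14C table (CSV/TSV or DataFrame) into an :class:`AtmosphereCurve`.

    Duplicate years are collapsed by their mean; rows are sorted by year.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    if "year" not in df.columns or "f14c" not in df.columns:
        raise ForcingError("input must have 'year' and 'f14c' columns")
    if "zone" in df.columns and df["zone"].nunique() == 1:
        zone = str(df["zone"].iloc[0])
    try:
        years = pd.to_numeric(df["year"], errors="raise")
        f14c = pd.to_numeric(df["f14c"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise ForcingError(f"non-numeric cell in forcing table: {exc}") from exc
    tidy = (
        pd.DataFrame({"year": years, "f14c": f14c})
        .groupby("year", as_index=False)["f14c"]
        .mean()
        .sort_values("year")
    )
    return AtmosphereCurve(zone, tidy["year"].to_numpy(), tidy["f14c"].to_numpy())


def splice_and_annualize(
    prebomb: AtmosphereCurve,
    postbomb: AtmosphereCurve | None,
    end_year: int,
    start_year: int = DEFAULT_START_YEAR,
    extension: str = "hold",
) -> AtmosphereCurve:
    """Combine pre-bomb and post-bomb records into one annual curve.

    Where the records overlap, the post-bomb record takes precedence from its
    first year onward (bomb-era points are direct atmospheric measurements).
    Sub-annual or irregular points are linearly interpolated to integer years.
    Years beyond the last datum are extended: ``hold`` repeats the last value,
    ``linear_trend`` extrapolates the mean slope of the final 10 years.
    """
    if prebomb.years[0] > start_year:
        raise ForcingError(
            f"pre-bomb curve starts at {prebomb.years[0]}, must cover {start_year}"
        )
    if extension not in ("hold", "linear_trend"):
        raise ForcingError(f"unknown extension rule {extension!r}")

    if postbomb is None:
        years = prebomb.years
        values = prebomb.f14c
        zone = prebomb.zone
    else:
        cut = postbomb.years[0]
        if prebomb.years[-1] < cut - 1:
            raise ForcingError(
                f"gap between pre-bomb record (ends {prebomb.years[-1]}) and "
                f"post-bomb record (starts {cut})"
            )
        keep = prebomb.years < cut
        years = np.concatenate([prebomb.years[keep], postbomb.years])
        values = np.concatenate([prebomb.f14c[keep], postbomb.f14c])
        zone = postbomb.zone

    grid = np.arange(start_year, end_year + 1, dtype=np.int64)
    annual = np.interp(grid, years, values)

    last = years[-1]
    if end_year > last:
        tail = grid > last
        if extension == "hold":
            annual[tail] = values[-1]
        else:
            recent = years >= last - 10
            slope = np.polyfit(years[recent], values[recent], 1)[0]
            annual[tail] = values[-1] + slope * (grid[tail] - last)
            annual[tail] = np.maximum(annual[tail], 1e-6)
    return AtmosphereCurve(zone, grid, annual)


def zone_for_latitude(
    latitude: float, nh_lat_min: float = 15.0, sh_lat_max: float = -15.0
) -> str:
    """Assign a hemispheric forcing zone from latitude.

    Boundaries default to +/-15 degrees, approximating the zonation of the
    published post-bomb compilations, and are configurable.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ForcingError(f"latitude {latitude} out of range [-90, 90]")
    if latitude >= nh_lat_min:
        return "NH"
    if latitude <= sh_lat_max:
        return "SH"
    return "Tropics"
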