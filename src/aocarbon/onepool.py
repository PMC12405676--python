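"""One-pool steady-state radiocarbon model of soil organic carbon.

The soil carbon pool receives constant inputs whose radiocarbon signature
tracks the atmosphere and loses carbon by decomposition (rate ``k``,
turnover time ``1/k``) and radioactive decay (``lambda = ln 2 / 5730``).
At annual time steps the fraction modern of the pool obeys

    F_SOC(j) = F_atm(j) * k + F_SOC(j-1) * (1 - k - lambda)

run from 53 kyr before present to the sampling year.  Evaluating the model
for a grid of turnover times yields, for a given sampling year, the
relationship F14C_SOC <-> turnover time used to (i) infer the turnover time
of a measured layer, and (ii) normalize the measurement to a common
reference year (2000) by reading the modeled value of the same turnover at
that year.

The post-bomb spike makes F14C_SOC non-monotone in turnover at the fast
end: a measured post-bomb value can correspond to two turnover times.  The
inversion returns the largest (oldest) solution and sets an ``ambiguous``
flag.  Measurements at or below 0.16 fraction modern (turnover beyond ~48
kyr for any sampling year) are left unnormalized, per the processing rule
of the source analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forcing import AtmosphereCurve

__all__ = [
    "LAMBDA_14C",
    "OnePoolParams",
    "TurnoverLookup",
    "simulate_f14c",
    "build_lookup",
    "invert_f14c",
    "normalize_to_2000",
]

#: Radiocarbon decay constant, year^-1 (5730-yr half-life convention).
LAMBDA_14C = math.log(2.0) / 5730.0

TURNOVER_MIN = 1.0
TURNOVER_MAX = 50_000.0

F14C_CUTOFF = 0.16
REFERENCE_YEAR = 2000


class OnePoolError(ValueError):
    """Raised for invalid one-pool model inputs."""


@dataclass(frozen=True)
class OnePoolParams:
    """Fixed parameters of the one-pool model.

    ``start_year`` is the spin-up start (default -53000); ``lam`` is the
    radiocarbon decay constant and should not normally be changed.
    """

    start_year: int = -53000
    lam: float = LAMBDA_14C


@dataclass(frozen=True)
class TurnoverLookup:
    """Modeled F14C_SOC at one sampling year over a turnover-time grid."""

    sampling_year: int
    turnover_grid: np.ndarray
    f14c_values: np.ndarray
    zone: str = "synthetic"

    def __post_init__(self) -> None:
        grid = np.asarray(self.turnover_grid, dtype=np.float64)
        vals = np.asarray(self.f14c_values, dtype=np.float64)
        if grid.size == 0:
            raise OnePoolError("empty turnover grid")
        if grid.shape != vals.shape:
            raise OnePoolError("grid and values must have equal length")
        if np.any(np.diff(grid) <= 0):
            raise OnePoolError("turnover grid must be strictly increasing")
        if np.any(grid < TURNOVER_MIN) or np.any(grid > TURNOVER_MAX):
            raise OnePoolError(
                f"turnover grid must lie within [{TURNOVER_MIN}, {TURNOVER_MAX}] years"
            )
        if np.any(vals <= 0):
            raise OnePoolError("modeled F14C values must be > 0")
        object.__setattr__(self, "turnover_grid", grid)
        object.__setattr__(self, "f14c_values", vals)

    def value_at(self, turnover: float) -> float:
        """Modeled F14C for a turnover time, piecewise-linear in log(turnover)."""
        if not TURNOVER_MIN <= turnover <= TURNOVER_MAX:
            raise OnePoolError(f"turnover {turnover} outside [{TURNOVER_MIN}, {TURNOVER_MAX}]")
        return float(
            np.interp(np.log(turnover), np.log(self.turnover_grid), self.f14c_values)
        )


def _simulate_grid(
    curve: AtmosphereCurve,
    turnovers: np.ndarray,
    target_year: int,
    params: OnePoolParams,
) -> np.ndarray:
    """Run the annual recursion for a vector of turnover times at once."""
    turnovers = np.asarray(turnovers, dtype=np.float64)
    if np.any(turnovers < TURNOVER_MIN):
        raise OnePoolError("turnover times below 1 year are not supported")
    k = 1.0 / turnovers
    lam = params.lam
    # spin-up-free initialization: equilibrium with the earliest atmosphere value
    years = np.arange(params.start_year, target_year + 1, dtype=np.int64)
    atm = curve.value_at(years)
    f = atm[0] * k / (k + lam)
    carry = 1.0 - k - lam
    for a in atm[1:]:
        f = a * k + f * carry
    return f


def simulate_f14c(
    curve: AtmosphereCurve,
    turnover: float,
    target_year: int,
    params: OnePoolParams | None = None,
) -> float:
    """F14C of the soil pool at ``target_year`` for a given turnover time.

    The recursion is initialized at the equilibrium value for the curve's
    earliest atmospheric level, removing spin-up bias for slow pools, and
    stepped annually from ``params.start_year`` to ``target_year``.
    """
    params = params or OnePoolParams()
    if turnover <= 0:
        raise OnePoolError("turnover must be positive")
    if turnover < TURNOVER_MIN:
        raise OnePoolError("turnover below 1 year: recursion step invalid (k + lambda >= 1 + lambda)")
    return float(_simulate_grid(curve, np.array([turnover]), target_year, params)[0])


def default_grid(n_points: int = 600) -> np.ndarray:
    """Log-spaced turnover grid on [1, 50000] years."""
    return np.geomspace(TURNOVER_MIN, TURNOVER_MAX, n_points)


_lookup_cache: dict[tuple, TurnoverLookup] = {}


def build_lookup(
    curve: AtmosphereCurve,
    sampling_year: int,
    grid: np.ndarray | None = None,
    params: OnePoolParams | None = None,
) -> TurnoverLookup:
    """Tabulate modeled F14C_SOC(sampling_year) over a turnover grid.

    Results are cached per (curve, year, grid), so repeated normalization of
    layers sampled in the same year costs one simulation pass.
    """
    params = params or OnePoolParams()
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=np.float64)
    key = (curve._digest, int(sampling_year), grid.tobytes(), params)
    if key not in _lookup_cache:
        values = _simulate_grid(curve, grid, int(sampling_year), params)
        _lookup_cache[key] = TurnoverLookup(
            int(sampling_year), grid, values, zone=curve.zone
        )
    return _lookup_cache[key]


def invert_f14c(lookup: TurnoverLookup, measured: float) -> tuple[float, set[str]]:
    """Turnover time whose modeled F14C matches a measurement.

    Piecewise-linear inversion (linear in log turnover) on the lookup.  When
    the bomb spike yields several solutions the largest turnover is returned
    with an ``ambiguous`` flag.  A measurement below the slowest modeled
    value saturates at 50 kyr (``saturated``); one above the global maximum
    returns the fast-end turnover of that maximum (``super_modern``).
    """
    if measured <= 0:
        raise OnePoolError("measured F14C must be > 0")
    v = lookup.f14c_values
    x = np.log(lookup.turnover_grid)
    flags: set[str] = set()

    if measured < v.min():
        flags.add("saturated")
        return float(lookup.turnover_grid[-1]), flags
    if measured > v.max():
        flags.add("super_modern")
        return float(lookup.turnover_grid[int(np.argmax(v))]), flags

    solutions = []
    dv = v - measured
    for i in range(len(v) - 1):
        lo, hi = dv[i], dv[i + 1]
        if lo == 0.0:
            solutions.append(x[i])
        elif lo * hi < 0.0:
            t = x[i] + (measured - v[i]) / (v[i + 1] - v[i]) * (x[i + 1] - x[i])
            solutions.append(t)
    if dv[-1] == 0.0:
        solutions.append(x[-1])
    if not solutions:  # pragma: no cover - bracketed by min/max checks above
        raise OnePoolError("inversion failed to bracket the measurement")
    if len(set(np.round(solutions, 12))) > 1:
        flags.add("ambiguous")
    return float(np.exp(max(solutions))), flags


def normalize_to_2000(
    measured: float,
    sampling_year: int,
    curve: AtmosphereCurve,
    cutoff: float = F14C_CUTOFF,
    reference_year: int = REFERENCE_YEAR,
    grid: np.ndarray | None = None,
    params: OnePoolParams | None = None,
) -> tuple[float, set[str]]:
    """Normalize a measured F14C_SOC to the reference year (default 2000).

    The measurement's turnover time is inferred at the sampling year, then
    the modeled value for that same turnover is read at the reference year.
    Values at or below ``cutoff`` (default 0.16, i.e. inferred turnover
    beyond ~48 kyr) are returned unchanged with an ``unnormalized`` flag.
    """
    if measured <= 0:
        raise OnePoolError("measured F14C must be > 0")
    if measured <= cutoff:
        return measured, {"unnormalized"}
    lookup = build_lookup(curve, sampling_year, grid=grid, params=params)
    turnover, flags = invert_f14c(lookup, measured)
    ref = build_lookup(curve, reference_year, grid=grid, params=params)
    return ref.value_at(turnover), flags
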