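"""Binary mixing model for ancient radiocarbon-free organic carbon (aOC).

Each soil layer's bulk radiocarbon signature is treated as a two-component
mixture of (i) an ancient, radiocarbon-free pool of constant mass
concentration aOC down the profile (F14C_aOC = 0) and (ii) an active pool
younger than 60 kyr with common fraction modern F14C_active:

    F14C_SOC = (aOC / SOC) * 0 + (SOC_active / SOC) * F14C_active

Multiplying through by SOC and substituting SOC_active = SOC - aOC gives a
straight line in the transformed variables Y = SOC * F14C_SOC, X = SOC:

    Y = F14C_active * X - F14C_active * aOC

so an ordinary least-squares fit across the layers of one profile yields
the active pool's fraction modern (slope) and the profile's aOC
concentration (minus intercept over slope).  Negative estimates have no
physical meaning and are clamped to zero; the median of the negative
estimates across a dataset serves as the limit of quantification (LOQ).
A fit is accepted when R^2 > 0.9 and every layer's aOC ratio (aOC / SOC)
is below 1.

The module is organised in the model/results style: build a
:class:`MixingModel` from a profile or raw arrays, call :meth:`fit`, and
inspect the returned :class:`MixingResults`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = [
    "MixingModel",
    "MixingResults",
    "fit_mixing",
    "layer_ratios",
    "apply_acceptance",
    "compute_loq",
    "propagate_aoc_sd",
    "DegenerateFitError",
]

R2_THRESHOLD = 0.9
RATIO_THRESHOLD = 1.0


class DegenerateFitError(ValueError):
    """All SOC values identical: the mixing line cannot be constrained."""


def propagate_aoc_sd(slope: float, intercept: float, cov: np.ndarray) -> float:
    """First-order SD of aOC = -intercept/slope given the 2x2 regression
    covariance ``cov`` ordered (intercept, slope)."""
    var = (
        cov[0, 0] / slope**2
        + intercept**2 * cov[1, 1] / slope**4
        - 2.0 * intercept * cov[0, 1] / slope**3
    )
    return math.sqrt(max(var, 0.0))


class MixingModel:
    """Per-profile binary mixing regression.

    Parameters
    ----------
    soc : array-like
        Layer SOC mass concentrations, mg C per g dry soil (the regressor X).
    f14c : array-like
        Layer fractions modern, normalized to the reference year where
        available (raw values are used for unnormalized layers).
    profile_id : str, optional
        Carried through to the results for bookkeeping.
    """

    def __init__(self, soc, f14c, profile_id: str = ""):
        soc = np.asarray(soc, dtype=np.float64)
        f14c = np.asarray(f14c, dtype=np.float64)
        if soc.shape != f14c.shape or soc.ndim != 1:
            raise ValueError("soc and f14c must be 1-D arrays of equal length")
        if soc.size < 3:
            raise ValueError("need at least 3 layers to fit slope, intercept and R^2")
        if np.any(soc <= 0):
            raise ValueError("SOC values must be > 0")
        self.soc = soc
        self.f14c = f14c
        self.profile_id = profile_id

    @classmethod
    def from_profile(cls, profile) -> "MixingModel":
        """Build from a :class:`~aocarbon.profiles.SoilProfile`.

        Uses each layer's normalized F14C where the pipeline has filled it
        and the raw measurement for layers flagged unnormalized.
        """
        soc = [l.soc_mg_g for l in profile.layers]
        f14c = [l.f14c for l in profile.layers]
        return cls(soc, f14c, profile_id=profile.profile_id)

    def fit(self) -> "MixingResults":
        """Ordinary least squares of Y = SOC * F14C on X = SOC."""
        x = self.soc
        y = self.soc * self.f14c
        if np.ptp(x) == 0:
            raise DegenerateFitError(
                f"profile {self.profile_id!r}: all SOC values equal; slope undefined"
            )
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        intercept, slope = ols.params
        cov = ols.cov_params()
        sd_intercept = math.sqrt(cov[0, 0])
        sd_slope = math.sqrt(cov[1, 1])
        cov_sl_in = cov[0, 1]

        valid = slope > 0
        if valid:
            aoc_raw = -intercept / slope
            aoc_sd = propagate_aoc_sd(slope, intercept, cov)
        else:
            aoc_raw = math.nan
            aoc_sd = math.nan
        clamped = valid and aoc_raw < 0
        return MixingResults(
            profile_id=self.profile_id,
            slope=float(slope),
            intercept=float(intercept),
            slope_sd=sd_slope,
            intercept_sd=sd_intercept,
            cov_slope_intercept=float(cov_sl_in),
            aoc_mg_g=(max(aoc_raw, 0.0) if valid else math.nan),
            aoc_raw_mg_g=float(aoc_raw),
            aoc_sd=float(aoc_sd),
            r2=float(ols.rsquared),
            n_layers=int(x.size),
            clamped=bool(clamped),
            valid=bool(valid),
            model=self,
        )


@dataclass
class MixingResults:
    """Result of a per-profile mixing fit.

    ``slope`` is the active pool's fraction modern (F14C of SOC younger
    than 60 kyr); ``aoc_mg_g`` the clamped aOC concentration;
    ``aoc_raw_mg_g`` the pre-clamp estimate (negative values feed the LOQ);
    ``aoc_sd`` its first-order propagated standard deviation.
    """

    profile_id: str
    slope: float
    intercept: float
    slope_sd: float
    intercept_sd: float
    cov_slope_intercept: float
    aoc_mg_g: float
    aoc_raw_mg_g: float
    aoc_sd: float
    r2: float
    n_layers: int
    clamped: bool
    valid: bool
    model: MixingModel | None = field(default=None, repr=False)
    max_layer_ratio: float | None = None
    accepted: bool | None = None
    rejection_reason: str | None = None
    below_loq: bool | None = None

    def layer_ratios(self, soc=None) -> np.ndarray:
        """Per-layer aOC ratio = aOC / SOC; records the maximum on the fit."""
        if soc is None:
            if self.model is None:
                raise ValueError("no SOC values available; pass soc explicitly")
            soc = self.model.soc
        soc = np.asarray(soc, dtype=np.float64)
        if np.any(soc <= 0):
            raise ValueError("SOC values must be > 0")
        ratios = (self.aoc_mg_g if self.valid else np.nan) / soc
        if self.valid:
            self.max_layer_ratio = float(ratios.max())
        return ratios

    def apply_acceptance(
        self, r2_threshold: float = R2_THRESHOLD, ratio_threshold: float = RATIO_THRESHOLD
    ) -> "MixingResults":
        """Set the acceptance flag: R^2 > 0.9 and every layer ratio < 1."""
        if self.max_layer_ratio is None:
            self.layer_ratios()
        reasons = []
        if not self.valid:
            reasons.append("non-positive slope (active pool F14C must be > 0)")
        else:
            if not self.r2 > r2_threshold:
                reasons.append(f"R^2 {self.r2:.3f} <= {r2_threshold}")
            if not self.max_layer_ratio < ratio_threshold:
                reasons.append(
                    f"max aOC ratio {self.max_layer_ratio:.3f} >= {ratio_threshold}"
                )
        self.accepted = not reasons
        self.rejection_reason = "; ".join(reasons) or None
        return self

    def to_record(self) -> dict:
        """Flat record of the fit for tabular output."""
        return {
            "profile_id": self.profile_id,
            "slope": self.slope,
            "intercept": self.intercept,
            "aoc_mg_g": self.aoc_mg_g,
            "aoc_raw_mg_g": self.aoc_raw_mg_g,
            "aoc_sd": self.aoc_sd,
            "r2": self.r2,
            "n_layers": self.n_layers,
            "clamped": self.clamped,
            "valid": self.valid,
            "max_layer_ratio": self.max_layer_ratio,
            "accepted": self.accepted,
            "rejection_reason": self.rejection_reason,
            "below_loq": self.below_loq,
        }

    def summary(self) -> str:
        lines = [
            f"Binary mixing fit: profile {self.profile_id or '<unnamed>'}",
            "=" * 54,
            f"layers                     {self.n_layers:>10d}",
            f"slope (F14C active pool)   {self.slope:>10.5f} +/- {self.slope_sd:.5f}",
            f"intercept (mg/g * F14C)    {self.intercept:>10.5f} +/- {self.intercept_sd:.5f}",
            f"aOC (mg/g)                 {self.aoc_mg_g:>10.5f} +/- {self.aoc_sd:.5f}",
            f"aOC pre-clamp (mg/g)       {self.aoc_raw_mg_g:>10.5f}",
            f"R^2                        {self.r2:>10.6f}",
        ]
        if self.max_layer_ratio is not None:
            lines.append(f"max layer aOC ratio        {self.max_layer_ratio:>10.5f}")
        if self.accepted is not None:
            status = "accepted" if self.accepted else f"rejected ({self.rejection_reason})"
            lines.append(f"quality screen             {status:>10s}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Scatter of (X, Y) = (SOC, SOC * F14C) with the fitted mixing line."""
        import matplotlib.pyplot as plt

        if self.model is None:
            raise ValueError("plotting needs the originating model data")
        if ax is None:
            _, ax = plt.subplots()
        x = self.model.soc
        ax.scatter(x, x * self.model.f14c, label="layers")
        xs = np.linspace(0, x.max() * 1.05, 50)
        ax.plot(xs, self.slope * xs + self.intercept, "k--",
                label=f"Y = {self.slope:.3f} X {self.intercept:+.3f}")
        ax.axvline(self.aoc_mg_g, color="0.6", lw=0.8)
        ax.set_xlabel("SOC (mg/g)")
        ax.set_ylabel("SOC x F14C (mg/g)")
        ax.legend()
        return ax


def fit_mixing(profile) -> MixingResults:
    """Fit, compute layer ratios and screen a profile in one call."""
    res = MixingModel.from_profile(profile).fit()
    res.layer_ratios()
    res.apply_acceptance()
    return res


def layer_ratios(profile, fit: MixingResults) -> np.ndarray:
    """Per-layer aOC ratios for a profile given its fit."""
    return fit.layer_ratios([l.soc_mg_g for l in profile.layers])


def apply_acceptance(fit: MixingResults) -> MixingResults:
    return fit.apply_acceptance()


def compute_loq(fits: list[MixingResults]) -> float:
    """Limit of quantification: |median of the negative pre-clamp estimates|.

    Returns 0 when no fit produced a negative estimate (the LOQ is then
    undefined and concentrations cannot be flagged).  The LOQ is a
    reporting flag (``below_loq``), never a filter.
    """
    negatives = [
        f.aoc_raw_mg_g for f in fits if f.valid and np.isfinite(f.aoc_raw_mg_g) and f.aoc_raw_mg_g < 0
    ]
    if not negatives:
        import warnings

        warnings.warn("no negative aOC estimates: LOQ undefined, using 0", stacklevel=2)
        loq = 0.0
    else:
        loq = abs(float(np.median(negatives)))
    for f in fits:
        f.below_loq = bool(f.valid and f.aoc_mg_g < loq)
    return loq
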