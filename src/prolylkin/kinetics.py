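"""Catalytic efficiency from exchange-rate titrations and Michaelis-Menten
limiting regimes.

Below K_M the apparent cis/trans exchange rate grows linearly with enzyme
concentration, k_app([E]) = k_0 + (kcat/KM) * [E]; the slope of a straight-
line fit across the titration is the catalytic efficiency.  The regime
helpers evaluate kcat/KM = kon*kcat/(koff + kcat) and its two limits:
binding-equilibrated ("EX2-like", koff >> kcat, efficiency -> kcat/K_D) and
association-limited ("EX1-like", kcat >> koff, efficiency -> kon).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "TitrationSeries",
    "ActivityEstimate",
    "MichaelisMentenParams",
    "RegimeResult",
    "fit_activity_slope",
    "efficiency_regimes",
    "koff_upper_bound",
    "per_uM_to_per_M",
]

#: label threshold: rate ratio at which a limiting expression holds to ~1%
REGIME_RATIO = 100.0


@dataclass(frozen=True)
class TitrationSeries:
    """Apparent exchange rates across an enzyme titration at fixed substrate.

    Concentrations in uM, rates in s^-1.  The substrate concentration must
    sit below K_M for the linear relation to hold; that is an experimental
    design constraint, not something this class can verify.
    """

    enzyme_conc_uM: np.ndarray
    k_app: np.ndarray
    k_app_sd: np.ndarray | None = None
    substrate_conc_uM: float = 100.0

    def __post_init__(self) -> None:
        e = np.asarray(self.enzyme_conc_uM, dtype=float)
        k = np.asarray(self.k_app, dtype=float)
        object.__setattr__(self, "enzyme_conc_uM", e)
        object.__setattr__(self, "k_app", k)
        if e.shape != k.shape or e.ndim != 1:
            raise ValueError("enzyme_conc_uM and k_app must be equal-length 1D arrays")
        if self.k_app_sd is not None:
            sd = np.asarray(self.k_app_sd, dtype=float)
            object.__setattr__(self, "k_app_sd", sd)
            if sd.shape != e.shape:
                raise ValueError("k_app_sd length mismatch")
            if np.any(sd <= 0):
                raise ValueError("k_app_sd must be positive where supplied")
        if np.any(e < 0):
            raise ValueError("enzyme concentrations must be >= 0")
        if len(np.unique(e)) < 3:
            raise ValueError("need at least 3 distinct enzyme concentrations")
        if self.substrate_conc_uM <= 0:
            raise ValueError("substrate_conc_uM must be > 0")


@dataclass(frozen=True)
class ActivityEstimate:
    """kcat/KM (uM^-1 s^-1) with standard error, plus the zero-enzyme rate."""

    kcat_over_km: float
    kcat_over_km_sd: float
    intercept_k0: float
    intercept_k0_sd: float
    negative_slope: bool = False

    @property
    def kcat_over_km_per_M(self) -> float:
        return per_uM_to_per_M(self.kcat_over_km)


def per_uM_to_per_M(value_per_uM_s: float) -> float:
    """Convert a second-order rate from uM^-1 s^-1 to M^-1 s^-1."""
    return value_per_uM_s * 1e6


def fit_activity_slope(series: TitrationSeries, weighted: bool = True) -> ActivityEstimate:
    """Straight-line fit of k_app versus enzyme concentration.

    Weighted by 1/sd^2 when uncertainties are supplied (and ``weighted``),
    ordinary least squares otherwise.  The slope, in s^-1 per uM of enzyme,
    is the catalytic efficiency kcat/KM in uM^-1 s^-1; the intercept is the
    uncatalysed exchange rate.  A negative fitted slope is returned with a
    warning flag rather than clipped.
    """
    X = sm.add_constant(series.enzyme_conc_uM)
    if weighted and series.k_app_sd is not None:
        model = sm.WLS(series.k_app, X, weights=1.0 / series.k_app_sd**2)
    else:
        model = sm.OLS(series.k_app, X)
    res = model.fit()
    slope = float(res.params[1])
    negative = slope < 0
    if negative:
        warnings.warn("fitted activity slope is negative", stacklevel=2)
    return ActivityEstimate(
        kcat_over_km=slope,
        kcat_over_km_sd=float(res.bse[1]),
        intercept_k0=float(res.params[0]),
        intercept_k0_sd=float(res.bse[0]),
        negative_slope=negative,
    )


@dataclass(frozen=True)
class MichaelisMentenParams:
    """Microscopic constants of E + S <-> ES -> E + P (all SI: M, s^-1)."""

    k_on: float   # M^-1 s^-1
    k_off: float  # s^-1
    k_cat: float  # s^-1

    def __post_init__(self) -> None:
        for name in ("k_on", "k_off", "k_cat"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def K_M(self) -> float:
        """Michaelis constant (koff + kcat)/kon, M."""
        if self.k_on == 0:
            raise ZeroDivisionError("k_on = 0: K_M undefined")
        return (self.k_off + self.k_cat) / self.k_on

    @property
    def K_D(self) -> float:
        """Equilibrium dissociation constant koff/kon, M."""
        if self.k_on == 0:
            raise ZeroDivisionError("k_on = 0: K_D undefined")
        return self.k_off / self.k_on


@dataclass(frozen=True)
class RegimeResult:
    kcat_over_km_per_M: float
    regime: str  # "EX2-like" | "EX1-like" | "intermediate"


def efficiency_regimes(params: MichaelisMentenParams) -> RegimeResult:
    """Catalytic efficiency kon*kcat/(koff + kcat) with a regime label.

    koff/kcat >= 100 -> "EX2-like" (binding equilibrated; value ~ kcat/K_D);
    kcat/koff >= 100 -> "EX1-like" (association limited; value ~ kon);
    otherwise "intermediate".  At the 100x threshold the limiting form holds
    to about 1%.
    """
    denom = params.k_off + params.k_cat
    if denom == 0:
        raise ZeroDivisionError("k_off + k_cat = 0: efficiency undefined")
    value = params.k_on * params.k_cat / denom
    if params.k_cat > 0 and params.k_off / params.k_cat >= REGIME_RATIO:
        regime = "EX2-like"
    elif params.k_off == 0 or params.k_cat / params.k_off >= REGIME_RATIO:
        regime = "EX1-like"
    else:
        regime = "intermediate"
    return RegimeResult(kcat_over_km_per_M=value, regime=regime)


def koff_upper_bound(k_on_assumed: float, K_D: float) -> float:
    """Upper bound on the dissociation rate, koff <= kon * K_D.

    With a diffusion-limited association rate assumed (1e8 M^-1 s^-1 for
    SlyD-peptide encounters) and a measured dissociation constant, the
    dissociation rate can be at most kon * K_D.  SI units: kon in
    M^-1 s^-1, K_D in M, result in s^-1.
    """
    if k_on_assumed < 0 or K_D < 0:
        raise ValueError("k_on and K_D must be >= 0")
    return k_on_assumed * K_D
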