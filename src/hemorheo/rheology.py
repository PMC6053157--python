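"""Shear-thinning constitutive models and their fits.

Two empirical viscosity laws are supported:

* **power law (Ostwald–de Waele)** — stress τ = K·γ̇ⁿ, i.e. apparent
  viscosity μ(γ̇) = K·γ̇^(n−1).  Fitted by ordinary least squares on
  log–log axes: log μ = log K + (n−1)·log γ̇.
* **Carreau** — μ(γ̇) = μ∞ + (μ0 − μ∞)·(1 + (λγ̇)^a)^((n−1)/a) with the
  Carreau-Yasuda shape parameter a fixed at 2.  Fitted by
  Levenberg–Marquardt with positivity of μ0, μ∞ and λ enforced by
  optimizing their logarithms.

Both fitters are scikit-learn estimators (``fit`` / ``predict`` /
``get_params``) so they compose with sklearn model selection; the
module-level functions are thin wrappers returning plain result records.

Goodness of fit follows the hemorheology convention: R² about the mean
of the data on the linear viscosity scale, and a degrees-of-freedom
corrected RMSE = sqrt(Σ(μ_exp − μ_fit)² / (m − p)) with p the number of
free parameters (2 for the power law, 4 for Carreau).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import DomainError, FitError

__all__ = [
    "ViscosityCurve", "PowerLawFit", "CarreauFit", "GoodnessOfFit",
    "PowerLawModel", "CarreauModel",
    "power_law_viscosity", "carreau_viscosity",
    "fit_power_law", "fit_carreau", "goodness_of_fit", "relative_viscosity",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ViscosityCurve:
    """Paired (shear rate, apparent viscosity) samples for one condition."""

    shear_rates_s1: np.ndarray
    viscosities_cp: np.ndarray
    plasma_viscosity_cp: Optional[float] = None
    hematocrit_pct: Optional[float] = None
    temperature_c: Optional[float] = None
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.shear_rates_s1 = np.asarray(self.shear_rates_s1, dtype=float)
        self.viscosities_cp = np.asarray(self.viscosities_cp, dtype=float)
        if self.shear_rates_s1.shape != self.viscosities_cp.shape:
            raise DomainError("shear rates and viscosities must have equal length")
        if np.any(self.shear_rates_s1 <= 0):
            raise DomainError("shear rates must be positive")
        if np.any(self.viscosities_cp <= 0):
            raise DomainError("viscosities must be positive")
        if self.plasma_viscosity_cp is not None and self.plasma_viscosity_cp <= 0:
            raise DomainError("plasma viscosity must be positive")

    @property
    def relative_viscosities(self) -> Optional[np.ndarray]:
        """Apparent viscosity normalized by the donor plasma viscosity."""
        if self.plasma_viscosity_cp is None:
            return None
        return self.viscosities_cp / self.plasma_viscosity_cp

    def to_csv(self, path) -> None:
        df = pd.DataFrame({"shear_rate_s1": self.shear_rates_s1,
                           "viscosity_cP": self.viscosities_cp})
        if self.plasma_viscosity_cp is not None:
            df["plasma_viscosity_cP"] = self.plasma_viscosity_cp
        if self.hematocrit_pct is not None:
            df["hematocrit_pct"] = self.hematocrit_pct
        if self.temperature_c is not None:
            df["temperature_C"] = self.temperature_c
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ViscosityCurve":
        df = pd.read_csv(path)
        def first(col):
            return float(df[col].iloc[0]) if col in df else None
        return cls(df["shear_rate_s1"].to_numpy(),
                   df["viscosity_cP"].to_numpy(),
                   plasma_viscosity_cp=first("plasma_viscosity_cP"),
                   hematocrit_pct=first("hematocrit_pct"),
                   temperature_c=first("temperature_C"))


@dataclass(frozen=True)
class GoodnessOfFit:
    m: int
    p: int
    rmse: float
    r_squared: float


@dataclass(frozen=True)
class PowerLawFit:
    consistency_K: float
    behaviour_index_n: float
    r_squared: float
    rmse: float
    m: int
    viscosity_unit: str = "cP"

    @property
    def k_unit(self) -> str:
        return f"{self.viscosity_unit}·s^(n-1)"


@dataclass(frozen=True)
class CarreauFit:
    mu_zero: float
    mu_inf: float
    relaxation_lambda: float
    index_n: float
    shape_a: float
    r_squared: float
    rmse: float
    m: int
    p: int
    converged: bool
    viscosity_unit: str = "cP"


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


def power_law_viscosity(shear_rate, K: float, n: float):
    """Apparent viscosity μ = K·γ̇^(n−1) of an Ostwald–de Waele fluid.

    The shear stress follows as τ = μ·γ̇ = K·γ̇ⁿ.  Undefined at γ̇ ≤ 0
    (the model diverges at the extremes).
    """
    g = np.asarray(shear_rate, dtype=float)
    if not K > 0:
        raise DomainError("consistency index K must be positive")
    if np.any(g <= 0) or not np.all(np.isfinite(g)):
        raise DomainError("power-law viscosity requires positive shear rates")
    out = K * g ** (n - 1.0)
    return float(out) if np.isscalar(shear_rate) else out


def carreau_viscosity(shear_rate, mu_zero: float, mu_inf: float, lam: float,
                      n: float, a: float = 2.0):
    """Carreau(-Yasuda) apparent viscosity; γ̇ = 0 returns μ0 exactly."""
    if not (mu_zero > 0 and mu_inf > 0):
        raise DomainError("plateau viscosities must be positive")
    if lam < 0:
        raise DomainError("relaxation time must be non-negative")
    g = np.asarray(shear_rate, dtype=float)
    out = mu_inf + (mu_zero - mu_inf) * (1.0 + (lam * g) ** a) ** ((n - 1.0) / a)
    return float(out) if np.isscalar(shear_rate) else out


def relative_viscosity(mu_apparent, mu_plasma: float):
    """Apparent viscosity normalized by the donor plasma viscosity."""
    if not mu_plasma > 0:
        raise DomainError("plasma viscosity must be positive")
    return np.asarray(mu_apparent, dtype=float) / mu_plasma if not np.isscalar(
        mu_apparent) else mu_apparent / mu_plasma


def goodness_of_fit(mu_exp: Sequence[float], mu_fit: Sequence[float],
                    p: int) -> GoodnessOfFit:
    """Degrees-of-freedom corrected RMSE and R² on the linear scale.

    RMSE = sqrt(Σ(μ_exp − μ_fit)² / (m − p)); R² = 1 − SS_res/SS_tot
    with SS_tot about the mean of μ_exp.
    """
    e = np.asarray(mu_exp, dtype=float)
    f = np.asarray(mu_fit, dtype=float)
    if e.shape != f.shape:
        raise DomainError("mu_exp and mu_fit must have equal length")
    m = e.size
    if m <= p:
        raise DomainError(f"need more data points ({m}) than parameters ({p})")
    ss_res = float(np.sum((e - f) ** 2))
    ss_tot = float(np.sum((e - e.mean()) ** 2))
    rmse = float(np.sqrt(ss_res / (m - p)))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    return GoodnessOfFit(m=m, p=p, rmse=rmse, r_squared=r2)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------


def _as_xy(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        if X.shape[1] != 1:
            raise DomainError("X must be a single column of shear rates")
        X = X[:, 0]
    y = np.asarray(y, dtype=float)
    if X.shape != y.shape:
        raise DomainError("X and y must have the same length")
    return X, y


class PowerLawModel(BaseEstimator, RegressorMixin):
    """Power-law viscosity model fitted by log–log linear least squares.

    ``fit(X, y)`` takes shear rates (1/s) and apparent viscosities; the
    slope of the regression gives n − 1 and the intercept log K.

    Attributes
    ----------
    K_ : fitted consistency index (input viscosity unit · s^(n−1))
    n_ : fitted behaviour index
    r_squared_, rmse_ : goodness of fit on the linear viscosity scale
        (RMSE with p = 2 degrees of freedom removed)
    """

    _p = 2

    def fit(self, X, y):
        g, mu = _as_xy(X, y)
        bad = np.flatnonzero((g <= 0) | (mu <= 0))
        if bad.size:
            raise DomainError(
                f"power-law fit requires positive data; offending indices "
                f"{bad.tolist()}")
        if g.size < 3:
            raise DomainError("need at least 3 points for a power-law fit")
        slope, intercept = np.polyfit(np.log(g), np.log(mu), 1)
        self.n_ = float(slope + 1.0)
        self.K_ = float(np.exp(intercept))
        gof = goodness_of_fit(mu, self.predict(g), p=self._p)
        self.r_squared_, self.rmse_ = gof.r_squared, gof.rmse
        self.m_ = gof.m
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        g = X[:, 0] if X.ndim == 2 else X
        return power_law_viscosity(g, self.K_, self.n_)


class CarreauModel(BaseEstimator, RegressorMixin):
    """Carreau viscosity model fitted by Levenberg–Marquardt.

    Parameters
    ----------
    a : Carreau-Yasuda shape parameter, fixed (2.0 gives the Carreau model).
    lam_fixed : if given, the relaxation time is held at this value and
        the degrees of freedom drop accordingly.
    init : optional dict overriding the data-driven initialization
        (keys among ``mu_zero``, ``mu_inf``, ``lam``, ``n``); defaults
        are μ0 ← max(y), μ∞ ← min(y), λ ← 1 s, n ← 0.5.
    max_iter : maximum number of residual evaluations for the solver.

    μ0, μ∞ and λ are optimized as logarithms so positivity is structural.
    """

    def __init__(self, a: float = 2.0, lam_fixed: Optional[float] = None,
                 init: Optional[dict] = None, max_iter: int = 2000):
        self.a = a
        self.lam_fixed = lam_fixed
        self.init = init
        self.max_iter = max_iter

    def fit(self, X, y):
        g, mu = _as_xy(X, y)
        fixed_lam = self.lam_fixed is not None
        p = 3 if fixed_lam else 4
        if g.size < p + 1:
            raise DomainError(
                f"need at least {p + 1} points to fit {p} Carreau parameters")
        if np.any(mu <= 0):
            raise DomainError("Carreau fit requires positive viscosities")

        init = {"mu_zero": float(mu.max()), "mu_inf": float(mu.min()),
                "lam": 1.0, "n": 0.5}
        if self.init:
            init.update(self.init)

        a = self.a

        if fixed_lam:
            theta0 = np.array([np.log(init["mu_zero"]), np.log(init["mu_inf"]),
                               init["n"]])
            unpack = lambda th: (np.exp(th[0]), np.exp(th[1]),
                                 float(self.lam_fixed), th[2])
        else:
            theta0 = np.array([np.log(init["mu_zero"]), np.log(init["mu_inf"]),
                               np.log(init["lam"]), init["n"]])
            unpack = lambda th: (np.exp(th[0]), np.exp(th[1]), np.exp(th[2]),
                                 th[3])

        def resid(th):
            mu0, mui, lam, n = unpack(th)
            return mu_model(g, mu0, mui, lam, n) - mu

        def mu_model(gg, mu0, mui, lam, n):
            return mui + (mu0 - mui) * (1.0 + (lam * gg) ** a) ** ((n - 1.0) / a)

        sol = least_squares(resid, theta0, method="lm", xtol=1e-14, ftol=1e-14,
                            gtol=1e-14, max_nfev=self.max_iter)
        mu0, mui, lam, n = unpack(sol.x)
        if not sol.success:
            raise FitError("Carreau fit did not converge",
                           best_params=dict(mu_zero=mu0, mu_inf=mui, lam=lam,
                                            n=n),
                           residual=float(np.sqrt(np.mean(sol.fun ** 2))))
        self.mu_zero_, self.mu_inf_, self.lam_, self.n_ = (
            float(mu0), float(mui), float(lam), float(n))
        if not self.mu_zero_ > self.mu_inf_:
            warnings.warn("fitted Carreau plateaus are not shear-thinning "
                          "(mu_zero <= mu_inf)", stacklevel=2)
        if self.n_ < 0:
            warnings.warn("fitted Carreau index n is negative", stacklevel=2)
        self.converged_ = bool(sol.success)
        self.p_ = p
        gof = goodness_of_fit(mu, self.predict(g), p=p)
        self.r_squared_, self.rmse_, self.m_ = gof.r_squared, gof.rmse, gof.m
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        g = X[:, 0] if X.ndim == 2 else X
        return carreau_viscosity(g, self.mu_zero_, self.mu_inf_, self.lam_,
                                 self.n_, self.a)


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def fit_power_law(curve: ViscosityCurve) -> PowerLawFit:
    """Fit the power-law model to a viscosity curve (log–log OLS)."""
    est = PowerLawModel().fit(curve.shear_rates_s1, curve.viscosities_cp)
    return PowerLawFit(consistency_K=est.K_, behaviour_index_n=est.n_,
                       r_squared=est.r_squared_, rmse=est.rmse_, m=est.m_)


def fit_carreau(curve: ViscosityCurve, init: Optional[dict] = None,
                lam_fixed: Optional[float] = None, a: float = 2.0) -> CarreauFit:
    """Fit the Carreau model (a = 2) by Levenberg–Marquardt."""
    est = CarreauModel(a=a, lam_fixed=lam_fixed, init=init)
    est.fit(curve.shear_rates_s1, curve.viscosities_cp)
    return CarreauFit(mu_zero=est.mu_zero_, mu_inf=est.mu_inf_,
                      relaxation_lambda=est.lam_, index_n=est.n_, shape_a=a,
                      r_squared=est.r_squared_, rmse=est.rmse_, m=est.m_,
                      p=est.p_, converged=est.converged_)
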