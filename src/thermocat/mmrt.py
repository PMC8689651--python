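"""Macromolecular rate theory (MMRT): curved ln k vs T with a heat capacity term.

Transition state theory gives ln k = ln(kappa k_B T / h) - dG^/(R T). MMRT
lets the activation enthalpy and entropy vary with temperature through a
constant difference in heat capacity between ground and transition state,
dCp^ (kJ mol^-1 K^-1):

    dH^(T) = dH^_T0 + dCp^ (T - T0)
    dS^(T) = dS^_T0 + dCp^ ln(T / T0)

    ln k(T) = ln(kappa k_B T / h)
              - [dH^_T0 + dCp^ (T - T0)] / (R T)
              + [dS^_T0 + dCp^ ln(T / T0)] / R

with T0 an arbitrary reference temperature. A negative dCp^ produces a rate
optimum below any unfolding transition; dCp^ = 0 recovers the ordinary
Eyring line in the {1, 1/T} basis.

Key numerical fact exploited here: with y = ln k - ln(k_B T / h), the model
is LINEAR in the basis {1, 1/T, ln T}, so the fit is a closed-form (weighted)
linear least squares, immune to the initialisation issues of generic
nonlinear optimisers. Parameters and their covariance are mapped back to
(dH^_T0, dS^_T0, dCp^) for any requested T0; predictions are invariant to
the choice of T0.

Per-second rates are used before applying the k_B T / h prefactor, so
dS^_T0 carries an absolute convention tied to that choice of rate unit.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .constants import H_PLANCK, K_B, KJ_TO_J, R_GAS
from .io import TemperatureRateSeries, ValidationError


@dataclass(frozen=True)
class MMRTParams:
    """MMRT parameter set at reference temperature T0.

    dH_T0 in kJ mol^-1; dS_T0 and dCp in kJ mol^-1 K^-1; T0 in K;
    transmission is the dimensionless prefactor scale kappa (default 1).
    """

    dH_T0: float
    dS_T0: float
    dCp: float
    T0: float = 348.0
    transmission: float = 1.0

    def __post_init__(self):
        vals = (self.dH_T0, self.dS_T0, self.dCp, self.T0, self.transmission)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("MMRT parameters must be finite")
        if self.T0 <= 0:
            raise ValueError("T0 must be positive kelvin")


@dataclass(frozen=True)
class MMRTFit:
    """MMRT fit result with covariance over (dH_T0, dS_T0, dCp)."""

    params: MMRTParams
    covariance: np.ndarray    # 3x3, kJ-based units
    se: dict                  # dH_T0, dS_T0, dCp -> standard error
    residual_rms: float       # in ln k
    n_points: int

    def ln_rate(self, T):
        return mmrt_ln_rate(self.params, T)

    def rate(self, T):
        return np.exp(self.ln_rate(T))


@dataclass(frozen=True)
class ThermoProfile:
    """Activation thermodynamics on a temperature grid (dG = dH - T dS exactly)."""

    temperature: np.ndarray   # K
    dH: np.ndarray            # kJ mol^-1
    dS: np.ndarray            # kJ mol^-1 K^-1
    dG: np.ndarray            # kJ mol^-1


@dataclass(frozen=True)
class KIEProfile:
    """Temperature profile of a kinetic isotope effect from paired MMRT fits."""

    temperature: np.ndarray
    kie: np.ndarray           # k_H / k_D on the grid
    ddCp: float               # dCp(deuterated) - dCp(protiated), kJ mol^-1 K^-1
    ddCp_se: float
    fit_H: MMRTFit
    fit_D: MMRTFit

    @property
    def minus_ddCp(self) -> float:
        """The same isotope effect with the opposite sign convention."""
        return -self.ddCp

    def kie_at(self, T) -> float:
        return float(np.exp(self.fit_H.ln_rate(T) - self.fit_D.ln_rate(T)))


def mmrt_ln_rate(params: MMRTParams, T):
    """ln k (k in s^-1) at temperature T (K) under the MMRT model."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive kelvin")
    dH = params.dH_T0 * KJ_TO_J
    dS = params.dS_T0 * KJ_TO_J
    dCp = params.dCp * KJ_TO_J
    T0 = params.T0
    pref = np.log(params.transmission * K_B * T / H_PLANCK)
    out = (pref
           - (dH + dCp * (T - T0)) / (R_GAS * T)
           + (dS + dCp * np.log(T / T0)) / R_GAS)
    return out if out.ndim else float(out)


def rate_optimum_temperature(params: MMRTParams) -> float:
    """Temperature of the interior rate maximum, where dH^(T) = -R T.

    Solves R T + dH_T0 + dCp (T - T0) = 0; meaningful for dCp < 0.
    """
    dH = params.dH_T0 * KJ_TO_J
    dCp = params.dCp * KJ_TO_J
    denom = R_GAS + dCp
    if denom == 0:
        raise ValueError("no interior optimum: dCp = -R")
    return float((dCp * params.T0 - dH) / denom)


def thermo_profile(params: MMRTParams, temperature) -> ThermoProfile:
    """dH^(T), dS^(T) and dG^(T) = dH^ - T dS^ on a temperature grid."""
    T = np.asarray(temperature, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature grid must be positive")
    dH = params.dH_T0 + params.dCp * (T - params.T0)
    dS = params.dS_T0 + params.dCp * np.log(T / params.T0)
    return ThermoProfile(temperature=T, dH=dH, dS=dS, dG=dH - T * dS)


def _abc_to_params(a, b, c, T0, transmission=1.0) -> MMRTParams:
    dCp = R_GAS * c
    dH = -R_GAS * b + dCp * T0
    dS = R_GAS * a + dCp * (1 + np.log(T0))
    return MMRTParams(dH_T0=dH / KJ_TO_J, dS_T0=dS / KJ_TO_J, dCp=dCp / KJ_TO_J,
                      T0=T0, transmission=transmission)


def _abc_jacobian(T0):
    """d(dH, dS, dCp)/d(a, b, c) in kJ-based units."""
    return np.array([
        [0.0, -R_GAS, R_GAS * T0],
        [R_GAS, 0.0, R_GAS * (1 + np.log(T0))],
        [0.0, 0.0, R_GAS],
    ]) / KJ_TO_J


def fit_mmrt(series: TemperatureRateSeries, T0: float = 348.0,
             weighting: str = "none") -> MMRTFit:
    """Fit the MMRT model to a (T, k) series by closed-form linear LS.

    The target is y = ln k - ln(k_B T / h), linear in {1, 1/T, ln T}.
    ``weighting='se'`` applies inverse-variance weights from the rate SEs
    (propagated to ln k as se/k); default is unweighted, appropriate for
    multiplicative rate noise.
    """
    if weighting not in ("none", "se"):
        raise ValueError("weighting must be 'none' or 'se'")
    T = series.temperature
    k = series.rate
    if np.unique(T).size < 3:
        raise ValidationError("MMRT fit needs at least 3 distinct temperatures")
    y = np.log(k) - np.log(K_B * T / H_PLANCK)
    X = np.column_stack([np.ones_like(T), 1.0 / T, np.log(T)])

    if weighting == "se":
        if series.rate_se is None:
            raise ValidationError("weighting='se' requires rate_se on the series")
        se_ln = series.rate_se / k
        if np.any(se_ln <= 0):
            raise ValidationError("weighting='se' requires strictly positive rate_se")
        w = 1.0 / se_ln**2
    else:
        w = np.ones_like(y)

    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ coef
    n = T.size
    dof = max(n - 3, 1)
    s2 = float(np.sum(w * resid**2) / dof)
    xtwx = X.T @ (X * w[:, None])
    try:
        cov_abc = np.linalg.inv(xtwx) * s2
    except np.linalg.LinAlgError as e:
        raise ValidationError(f"rank-deficient MMRT design matrix: {e}") from e

    params = _abc_to_params(*coef, T0=T0)
    J = _abc_jacobian(T0)
    cov = J @ cov_abc @ J.T
    cov = 0.5 * (cov + cov.T)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return MMRTFit(
        params=params, covariance=cov,
        se={"dH_T0": se[0], "dS_T0": se[1], "dCp": se[2]},
        residual_rms=float(np.sqrt(np.mean(resid**2))), n_points=n,
    )


def fit_kie_pair(series_H: TemperatureRateSeries, series_D: TemperatureRateSeries,
                 T0: float = 348.0, temperature_grid=None,
                 weighting: str = "none") -> KIEProfile:
    """Fit each isotopologue independently and form KIE(T) = k_H(T)/k_D(T).

    ddCp follows the convention dCp(deuterated) - dCp(protiated); its SE is
    the quadrature sum of the two fit SEs.
    """
    if series_H.substrate != series_D.substrate:
        raise ValidationError(
            f"substrate labels differ: {series_H.substrate!r} vs {series_D.substrate!r}"
        )
    fit_H = fit_mmrt(series_H, T0=T0, weighting=weighting)
    fit_D = fit_mmrt(series_D, T0=T0, weighting=weighting)
    if temperature_grid is None:
        lo = min(series_H.temperature[0], series_D.temperature[0])
        hi = max(series_H.temperature[-1], series_D.temperature[-1])
        temperature_grid = np.linspace(lo, hi, 101)
    grid = np.asarray(temperature_grid, dtype=float)
    kie = np.exp(fit_H.ln_rate(grid) - fit_D.ln_rate(grid))
    ddCp = fit_D.params.dCp - fit_H.params.dCp
    ddCp_se = float(np.hypot(fit_H.se["dCp"], fit_D.se["dCp"]))
    return KIEProfile(temperature=grid, kie=kie, ddCp=float(ddCp),
                      ddCp_se=ddCp_se, fit_H=fit_H, fit_D=fit_D)


def bootstrap_ci(series: TemperatureRateSeries, T0: float = 348.0,
                 n_boot: int = 1000, seed: int = 0, weighting: str = "none",
                 levels=(2.5, 97.5)):
    """Residual-resampling bootstrap CIs for (dH_T0, dS_T0, dCp).

    Residuals in ln k from the point fit are resampled with replacement and
    added back to the fitted curve; each replicate is refitted by the same
    closed-form solve. Deterministic given *seed*. Returns a dict of
    parameter -> (low, high) percentile bounds, plus the point fit under
    ``"fit"`` and a ``"degenerate"`` flag when all residuals are zero.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    fit = fit_mmrt(series, T0=T0, weighting=weighting)
    ln_hat = fit.ln_rate(series.temperature)
    resid = np.log(series.rate) - ln_hat
    degenerate = bool(np.allclose(resid, 0))
    draws = np.empty((n_boot, 3))
    for i in range(n_boot):
        r = resid[rng.integers(0, resid.size, size=resid.size)]
        boot = replace(series, rate=np.exp(ln_hat + r))
        f = fit_mmrt(boot, T0=T0, weighting="none")
        draws[i] = (f.params.dH_T0, f.params.dS_T0, f.params.dCp)
    lo, hi = np.percentile(draws, levels, axis=0)
    out = {name: (float(l), float(h))
           for name, l, h in zip(("dH_T0", "dS_T0", "dCp"), lo, hi)}
    out["fit"] = fit
    out["degenerate"] = degenerate
    return out
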