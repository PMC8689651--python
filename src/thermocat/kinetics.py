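"""Fitting of stopped-flow transients and steady-state rate-concentration data.

Transients are modelled as a sum of (optionally stretched) exponentials,

    A(t) = offset + sum_i A_i * exp(-(k_i * t)^b_i),

with ``b_i = 1`` the ordinary exponential; ``b`` close to 1 indicates the
trace is not convolved of unresolved extra phases. Steady-state data follow
Michaelis-Menten kinetics, optionally with uncompetitive substrate
inhibition,

    v(S) = Vmax * S / (K_M + S + S^2 / K_i),

the standard single-K_i form for rate loss at high substrate. Model
comparisons (1 vs 2 phases, inhibition on vs off) use the small-sample
corrected Akaike criterion (AICc) so nested and non-nested alternatives are
handled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import AbsorbanceTransient, RateConcentrationSeries, TemperatureRateSeries, ValidationError


class FitError(ValueError):
    """A nonlinear fit failed to converge from every starting point."""


def aicc(rss: float, n: int, n_params: int) -> float:
    """Small-sample corrected Akaike information criterion for an LS fit."""
    if n <= n_params + 1:
        return np.inf
    aic = n * np.log(max(rss, 1e-300) / n) + 2 * n_params
    return aic + 2 * n_params * (n_params + 1) / (n - n_params - 1)


# ---------------------------------------------------------------------------
# Transients
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransientFit:
    """Result of a multi-exponential transient fit.

    Phases are ordered by decreasing amplitude fraction (|A_i| / sum |A_j|);
    ties break toward the faster rate.
    """

    n_phases: int
    amplitudes: np.ndarray          # AU
    rates: np.ndarray               # s^-1
    stretches: np.ndarray           # dimensionless b_i
    offset: float                   # AU
    amplitude_fractions: np.ndarray
    se: dict                        # parameter name -> standard error
    residual_rms: float
    aicc: float
    warnings: tuple = ()

    def __call__(self, t):
        return eval_transient(self.amplitudes, self.rates, self.stretches, self.offset, t)


def eval_transient(amplitudes, rates, stretches, offset, t):
    """Evaluate offset + sum_i A_i exp(-(k_i t)^{b_i}) at times t >= 0."""
    A = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    k = np.atleast_1d(np.asarray(rates, dtype=float))
    b = np.atleast_1d(np.asarray(stretches, dtype=float))
    if not (np.isfinite(A).all() and np.isfinite(k).all() and np.isfinite(b).all()
            and np.isfinite(offset)):
        raise ValueError("transient parameters must be finite")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    kt = np.multiply.outer(t, k)          # (..., n_phases)
    return offset + (A * np.exp(-np.power(kt, b))).sum(axis=-1)


_B_MAX = 1.5   # upper bound on the stretch factor


def _order_phases(A, k, b):
    frac = np.abs(A) / max(np.abs(A).sum(), 1e-300)
    order = np.lexsort((-k, -frac))       # by fraction desc, tie -> rate desc
    return A[order], k[order], b[order], frac[order]


def fit_transient(transient: AbsorbanceTransient, n_phases: int = 1,
                  allow_stretch: bool = False, seed: int = 0) -> TransientFit:
    """Least-squares fit of a 1- or 2-phase (stretched) exponential decay.

    Multi-start initialisation: 8 log-spaced rate guesses per phase with
    seed-controlled jitter; the best converged start wins. ``allow_stretch``
    frees the per-phase stretch b in (0, 1.5]; otherwise b is fixed at 1.

    Rates are constrained to the identifiable window of the record,
    0.5/t_span <= k <= 5/dt: a slower phase is indistinguishable from the
    offset (it aliases the baseline) and a faster one decays between the
    first two samples. A fitted rate at either bound is flagged.
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t, y = transient.time, transient.absorbance
    n = t.size
    rng = np.random.default_rng(seed)

    span = t[-1] - t[0]
    dt = np.min(np.diff(t))
    k_grid = np.geomspace(0.5 / span, 0.5 / dt, 8)
    amp0 = y[0] - y[-1]
    if amp0 == 0:
        amp0 = np.ptp(y) if np.ptp(y) > 0 else 1.0
    off0 = y[-1]

    def pack(params):
        """param vector -> (A, k, b, offset)"""
        stride = 3 if allow_stretch else 2
        A = params[0:stride * n_phases:stride]
        k = params[1:stride * n_phases:stride]
        if allow_stretch:
            b = params[2:stride * n_phases:stride]
        else:
            b = np.ones(n_phases)
        return A, k, b, params[-1]

    def resid(params):
        A, k, b, off = pack(params)
        return eval_transient(A, k, b, off, t) - y

    starts = []
    for g in k_grid:
        jit = np.exp(rng.normal(0, 0.05, size=n_phases))
        if n_phases == 1:
            ks = [g * jit[0]]
            As = [amp0]
        else:
            ks = [g * jit[0], 10 * g * jit[1]]
            As = [0.7 * amp0, 0.3 * amp0]
        p0 = []
        for Ai, ki in zip(As, ks):
            p0 += [Ai, ki] + ([1.0] if allow_stretch else [])
        p0.append(off0)
        starts.append(np.array(p0))

    k_lo, k_hi = 0.5 / span, 5.0 / dt               # identifiable rate window
    stride = 3 if allow_stretch else 2
    lo = np.full(stride * n_phases + 1, -np.inf)
    hi = np.full(stride * n_phases + 1, np.inf)
    lo[1:stride * n_phases:stride] = k_lo
    hi[1:stride * n_phases:stride] = k_hi
    if allow_stretch:
        lo[2:stride * n_phases:stride] = 1e-3       # b > 0
        hi[2:stride * n_phases:stride] = _B_MAX

    best = None
    for p0 in starts:
        p0 = np.clip(p0, lo * (1 + 1e-9) + np.where(np.isfinite(lo), 1e-12, 0),
                     hi * (1 - 1e-9))
        try:
            res = least_squares(resid, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("transient fit failed from every start")

    A, k, b, off = pack(best.x)
    A, k, b, frac = _order_phases(np.asarray(A, float), np.asarray(k, float),
                                  np.asarray(b, float))
    rss = float(2 * best.cost)
    n_par = best.x.size
    warnings = []
    if np.any(k < k_lo * 1.01) or np.any(k > k_hi * 0.99) or (
            allow_stretch and np.any(b > _B_MAX - 1e-6)):
        warnings.append("rate or stretch at identifiability bound")

    se = _se_from_jacobian(best.jac, rss, n, n_par)
    se_map = {}
    names = []
    for i in range(n_phases):
        names += [f"A{i+1}", f"k{i+1}"] + ([f"b{i+1}"] if allow_stretch else [])
    names.append("offset")
    for nm, s in zip(names, se):
        se_map[nm] = s

    return TransientFit(
        n_phases=n_phases, amplitudes=A, rates=k, stretches=b, offset=float(off),
        amplitude_fractions=frac, se=se_map,
        residual_rms=float(np.sqrt(rss / n)),
        aicc=aicc(rss, n, n_par), warnings=tuple(warnings),
    )


def _se_from_jacobian(jac, rss, n, n_par):
    if n <= n_par:
        return np.full(n_par, np.nan)
    try:
        cov = np.linalg.pinv(jac.T @ jac) * rss / (n - n_par)
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(n_par, np.nan)


def select_phase_count(transient: AbsorbanceTransient, allow_stretch: bool = False,
                       seed: int = 0):
    """Choose 1 vs 2 exponential phases by AICc.

    The second phase is accepted only when it improves AICc by more than 2
    units; smaller differences (including exact ties) resolve to 1 phase.

    Returns ``(n_phases, {"fits": {...}, "aicc": {...}})``.
    """
    fits, crit = {}, {}
    errors = {}
    for n_ph in (1, 2):
        try:
            fits[n_ph] = fit_transient(transient, n_ph, allow_stretch, seed=seed)
            crit[n_ph] = fits[n_ph].aicc
        except FitError as e:
            errors[n_ph] = e
    if not fits:
        raise FitError(f"both phase-count fits failed: {errors}")
    if len(fits) == 1:
        choice = next(iter(fits))
    else:
        # the extra phase must earn substantial AICc support (conventional
        # threshold of 2); anything closer counts as a tie toward 1 phase
        choice = 2 if crit[2] < crit[1] - 2.0 else 1
    return choice, {"fits": fits, "aicc": crit}


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MichaelisFit:
    """Michaelis-Menten fit, optionally with uncompetitive substrate inhibition.

    ``k_cat = Vmax / enzyme_conc`` with the velocity and enzyme concentration
    expressed in consistent concentration units (e.g. uM/s and uM).
    """

    vmax: float                 # rate units of the input series
    K_M: float                  # mM
    K_i: float | None           # mM; None when no inhibition term fitted
    k_cat: float                # s^-1
    se: dict
    covariance: np.ndarray
    residual_rms: float
    aicc: float
    temperature: float = 298.15
    substrate: str = ""
    isotopologue: str = "protiated"

    @property
    def has_inhibition(self) -> bool:
        return self.K_i is not None

    def __call__(self, S):
        return eval_michaelis(self.vmax, self.K_M, S, K_i=self.K_i)


def eval_michaelis(vmax, K_M, S, K_i=None):
    """v = Vmax S/(K_M + S) or, with inhibition, Vmax S/(K_M + S + S^2/K_i)."""
    if vmax < 0 or K_M < 0 or (K_i is not None and K_i <= 0):
        raise ValueError("Michaelis-Menten parameters must be positive")
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise ValueError("substrate concentration must be non-negative")
    denom = K_M + S
    if K_i is not None:
        denom = denom + S**2 / K_i
    return vmax * S / denom


def substrate_inhibition_optimum(K_M: float, K_i: float) -> float:
    """Concentration maximising v under substrate inhibition: sqrt(K_M K_i)."""
    return float(np.sqrt(K_M * K_i))


def _fit_mm_once(S, v, with_ki, seed):
    rng = np.random.default_rng(seed)
    vmax0 = float(np.max(v)) * 1.2
    S_pos = S[S > 0]
    km_grid = np.geomspace(max(S_pos.min(), 1e-6), S_pos.max(), 5)

    def resid(p):
        if with_ki:
            return eval_michaelis(p[0], p[1], S, K_i=p[2]) - v
        return eval_michaelis(p[0], p[1], S) - v

    best = None
    for km0 in km_grid:
        jit = np.exp(rng.normal(0, 0.05, size=3))
        p0 = [vmax0 * jit[0], km0 * jit[1]]
        lo = [1e-12, 1e-12]
        hi = [np.inf, np.inf]
        if with_ki:
            p0.append(float(S_pos.max()) * 2 * jit[2])
            lo.append(1e-9)
            hi.append(np.inf)
        try:
            res = least_squares(resid, p0, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("Michaelis-Menten fit failed from every start")
    return best


def fit_michaelis(series: RateConcentrationSeries, inhibition: str = "auto",
                  seed: int = 0) -> MichaelisFit:
    """Nonlinear LS fit of v(S); ``inhibition`` is ``auto``, ``on`` or ``off``.

    In ``auto`` mode both forms are fitted and the inhibition form is kept
    only when it wins the AICc comparison and its K_i is identifiable (not
    driven to effectively infinite values).
    """
    if inhibition not in ("auto", "on", "off"):
        raise ValueError("inhibition must be auto|on|off")
    S, v = series.substrate_conc, series.rate
    n = S.size
    if inhibition in ("auto", "on") and np.unique(S).size < 6:
        if inhibition == "on":
            raise ValidationError("substrate-inhibition fit needs >=6 distinct concentrations")
        inhibition = "off"

    results = {}
    if inhibition in ("auto", "off"):
        results[False] = _fit_mm_once(S, v, False, seed)
    if inhibition in ("auto", "on"):
        results[True] = _fit_mm_once(S, v, True, seed)

    def crit(with_ki):
        res = results[with_ki]
        return aicc(float(2 * res.cost), n, res.x.size)

    if inhibition == "auto":
        use_ki = crit(True) < crit(False)
        if use_ki and results[True].x[2] > 1e4 * results[True].x[1]:
            use_ki = False      # K_i unbounded above: inhibition undetectable
    else:
        use_ki = inhibition == "on"

    res = results[use_ki]
    rss = float(2 * res.cost)
    se = _se_from_jacobian(res.jac, rss, n, res.x.size)
    try:
        cov = np.linalg.pinv(res.jac.T @ res.jac) * rss / max(n - res.x.size, 1)
    except np.linalg.LinAlgError:
        cov = np.full((res.x.size, res.x.size), np.nan)

    vmax, km = float(res.x[0]), float(res.x[1])
    ki = float(res.x[2]) if use_ki else None
    kcat = vmax / series.enzyme_conc
    names = ["vmax", "K_M"] + (["K_i"] if use_ki else [])
    se_map = dict(zip(names, se))
    se_map["k_cat"] = se_map["vmax"] / series.enzyme_conc
    return MichaelisFit(
        vmax=vmax, K_M=km, K_i=ki, k_cat=kcat, se=se_map, covariance=cov,
        residual_rms=float(np.sqrt(rss / n)), aicc=crit(use_ki),
        temperature=series.temperature, substrate=series.substrate,
        isotopologue=series.isotopologue,
    )


def build_temperature_series(fits) -> TemperatureRateSeries:
    """Assemble (T, k_cat) pairs from per-temperature fits into one series.

    *fits* is an iterable of ``(temperature_K, MichaelisFit)``; standard
    errors are the per-fit k_cat SEs passed through verbatim.
    """
    fits = list(fits)
    temps = np.array([t for t, _ in fits], dtype=float)
    if np.unique(temps).size != temps.size:
        raise ValidationError("duplicate temperatures in temperature series")
    order = np.argsort(temps)
    k = np.array([fits[i][1].k_cat for i in order])
    se = np.array([fits[i][1].se.get("k_cat", np.nan) for i in order])
    substrates = {fits[i][1].substrate for i in order}
    isos = {fits[i][1].isotopologue for i in order}
    return TemperatureRateSeries(
        temperature=temps[order], rate=k, rate_se=se,
        substrate=substrates.pop() if len(substrates) == 1 else "",
        isotopologue=isos.pop() if len(isos) == 1 else "protiated",
    )
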