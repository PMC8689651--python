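"""MMRT model, closed-form fitting, thermodynamic profiles, KIE, bootstrap."""

import numpy as np
import pytest
from scipy.optimize import least_squares

from thermocat.constants import H_PLANCK, K_B, R_GAS
from thermocat.mmrt import (
    MMRTParams, bootstrap_ci, fit_kie_pair, fit_mmrt, mmrt_ln_rate,
    rate_optimum_temperature, thermo_profile,
)
from thermocat.synthetic import NoiseSpec, gen_mmrt_series, scenario_mmrt_series


def test_ln_rate_constant_oracle():
    """dCp=0, T=T0=300 K, dH=50 kJ/mol, dS=0: ln k = ln(kB 300/h) - 50000/(300 R)."""
    p = MMRTParams(dH_T0=50.0, dS_T0=0.0, dCp=0.0, T0=300.0)
    expected = np.log(K_B * 300.0 / H_PLANCK) - 50000.0 / (R_GAS * 300.0)
    assert mmrt_ln_rate(p, 300.0) == pytest.approx(expected, rel=1e-12)
    assert mmrt_ln_rate(p, 300.0) == pytest.approx(9.4184, abs=1e-3)


def test_dCp_terms_vanish_at_T0():
    base = dict(dH_T0=60.0, dS_T0=0.1, T0=320.0)
    for dCp in (-5.0, 0.0, 3.0):
        p = MMRTParams(dCp=dCp, **base)
        assert mmrt_ln_rate(p, 320.0) == pytest.approx(
            mmrt_ln_rate(MMRTParams(dCp=0.0, **base), 320.0), rel=1e-14)


def test_interior_maximum_matches_grid_argmax():
    p = MMRTParams(dH_T0=55.0, dS_T0=0.0, dCp=-3.0, T0=348.0)
    T = np.linspace(250.0, 400.0, 300_001)
    grid_opt = T[np.argmax(mmrt_ln_rate(p, T))]
    assert rate_optimum_temperature(p) == pytest.approx(grid_opt, abs=1e-3)


def test_closed_form_equals_nonlinear_optimizer():
    """Linear-basis solution matches an independent iterative NLS fit to 1e-6."""
    series, _ = scenario_mmrt_series("d-glucose", np.linspace(293, 358, 14),
                                     noise=NoiseSpec(sigma=0.02, seed=3))
    fit = fit_mmrt(series, T0=348.0)

    T, lnk = series.temperature, np.log(series.rate)

    def resid(x):
        p = MMRTParams(dH_T0=x[0], dS_T0=x[1], dCp=x[2], T0=348.0)
        return mmrt_ln_rate(p, T) - lnk

    nls = least_squares(resid, [50.0, 0.0, -1.0], xtol=1e-15, ftol=1e-15)
    assert fit.params.dH_T0 == pytest.approx(nls.x[0], abs=1e-6)
    assert fit.params.dS_T0 == pytest.approx(nls.x[1], abs=1e-6)
    assert fit.params.dCp == pytest.approx(nls.x[2], abs=1e-6)


def test_noiseless_recovery_to_1e8():
    series, _ = gen_mmrt_series(dH_T0=54.7, dCp=-3.0, T0=348.0,
                                anchor=(348.0, 10.865), temperature=np.linspace(293, 358, 10))
    fit = fit_mmrt(series, T0=348.0)
    assert fit.params.dH_T0 == pytest.approx(54.7, rel=1e-8)
    assert fit.params.dCp == pytest.approx(-3.0, rel=1e-8)


def test_T0_reparameterization_invariance():
    """dCp and predicted ln k(T) are identical for T0=298 vs T0=348."""
    series, _ = scenario_mmrt_series("d-galactose", np.linspace(293, 358, 14),
                                     noise=NoiseSpec(sigma=0.02, seed=5))
    f298 = fit_mmrt(series, T0=298.0)
    f348 = fit_mmrt(series, T0=348.0)
    assert f298.params.dCp == pytest.approx(f348.params.dCp, rel=1e-10)
    grid = np.linspace(280, 370, 40)
    assert np.allclose(f298.ln_rate(grid), f348.ln_rate(grid), rtol=1e-10)
    # dH transforms consistently: dH(348) from the 298-fit equals the 348-fit value
    dH_348_from_298 = f298.params.dH_T0 + f298.params.dCp * (348.0 - 298.0)
    assert dH_348_from_298 == pytest.approx(f348.params.dH_T0, rel=1e-10)


def test_eyring_limit_dcp_within_3se():
    """Data generated with dCp=0 return |dCp| < 3 SE in >=95% of seeds."""
    T = np.linspace(293, 358, 14)
    hits = 0
    n_seeds = 100
    for seed in range(n_seeds):
        s, _ = gen_mmrt_series(dH_T0=60.0, dCp=0.0, T0=348.0, anchor=(348.0, 5.0),
                               temperature=T, noise=NoiseSpec(sigma=0.02, seed=seed))
        f = fit_mmrt(s, T0=348.0)
        if abs(f.params.dCp) < 3 * f.se["dCp"]:
            hits += 1
    assert hits >= 0.95 * n_seeds


@pytest.mark.parametrize("dCp_true", [-3.0, -1.0, 0.0, 1.4])
def test_parameter_recovery_unbiased(dCp_true):
    """Bias of recovered dCp is small relative to its SE (200 seeds, 2% noise)."""
    T = np.linspace(293, 358, 14)
    vals, ses = [], []
    for seed in range(200):
        s, _ = gen_mmrt_series(dH_T0=60.0, dCp=dCp_true, T0=348.0, anchor=(348.0, 5.0),
                               temperature=T, noise=NoiseSpec(sigma=0.02, seed=seed))
        f = fit_mmrt(s, T0=348.0)
        vals.append(f.params.dCp)
        ses.append(f.se["dCp"])
    bias = np.mean(vals) - dCp_true
    assert abs(bias) < 0.1 * np.mean(ses)


def test_weighted_fit_uses_se():
    series, _ = scenario_mmrt_series("d-glucose", np.linspace(293, 358, 14),
                                     noise=NoiseSpec(sigma=0.02, seed=9))
    import dataclasses
    with_se = dataclasses.replace(series, rate_se=0.02 * series.rate)
    fw = fit_mmrt(with_se, T0=348.0, weighting="se")
    fu = fit_mmrt(series, T0=348.0, weighting="none")
    # uniform relative errors -> weights constant -> same solution
    assert fw.params.dCp == pytest.approx(fu.params.dCp, rel=1e-9)


def test_thermo_profile_identities():
    p = MMRTParams(dH_T0=54.7, dS_T0=0.05, dCp=-3.0, T0=348.0)
    grid = np.linspace(290, 360, 141)
    prof = thermo_profile(p, grid)
    assert np.allclose(prof.dG, prof.dH - grid * prof.dS)           # exact identity
    i0 = np.argmin(np.abs(grid - 348.0))
    assert prof.dH[i0] == pytest.approx(54.7)
    assert prof.dS[i0] == pytest.approx(0.05)
    # finite-difference d(dH)/dT ~ dCp
    slope = np.gradient(prof.dH, grid)
    assert np.allclose(slope, -3.0, atol=1e-9)
    # dCp = 0 -> constant profiles
    flat = thermo_profile(MMRTParams(54.7, 0.05, 0.0, 348.0), grid)
    assert np.ptp(flat.dH) == 0 and np.ptp(flat.dS) == 0


# ---------------------------------------------------------------------------
# KIE
# ---------------------------------------------------------------------------

def test_kie_identical_series_is_unity():
    s, _ = scenario_mmrt_series("d-galactose", np.linspace(293, 358, 14))
    prof = fit_kie_pair(s, s, T0=348.0)
    assert np.allclose(prof.kie, 1.0, atol=1e-12)
    assert prof.ddCp == pytest.approx(0.0, abs=1e-12)


def test_kie_ddcp_zero_is_loglinear_in_inverse_T():
    """With identical curvature, ln KIE(T) = dd/(R) * (1/T) + const exactly."""
    T = np.linspace(293, 358, 14)
    h, _ = gen_mmrt_series(60.0, -2.0, 348.0, (348.0, 5.0), T, substrate="x")
    d, _ = gen_mmrt_series(65.0, -2.0, 348.0, (348.0, 3.0), T, substrate="x")
    prof = fit_kie_pair(h, d, T0=348.0, temperature_grid=T)
    lnkie = np.log(prof.kie)
    # closed form: ln KIE = -(dH_H - dH_D)/(R T) + (dS_H - dS_D)/R with dd terms constant
    coeffs = np.polyfit(1.0 / T, lnkie, 1)
    assert np.allclose(np.polyval(coeffs, 1.0 / T), lnkie, atol=1e-10)
    assert coeffs[0] == pytest.approx(5000.0 / R_GAS, rel=1e-6)   # (65-60) kJ/mol / R
    assert prof.ddCp == pytest.approx(0.0, abs=1e-9)


def test_kie_mismatched_substrates_error():
    a, _ = gen_mmrt_series(60.0, -2.0, 348.0, (348.0, 5.0),
                           np.linspace(293, 358, 10), substrate="glc")
    b, _ = gen_mmrt_series(60.0, -2.0, 348.0, (348.0, 5.0),
                           np.linspace(293, 358, 10), substrate="gal")
    from thermocat.io import ValidationError
    with pytest.raises(ValidationError):
        fit_kie_pair(a, b)


def test_kie_magnitude_recovery():
    """H/D pair differing by a constant factor 1.7 recovers KIE(348) ~ 1.7."""
    T = np.linspace(293, 358, 14)
    kies = []
    for seed in range(5):
        h, _ = scenario_mmrt_series("d-galactose", T, NoiseSpec(sigma=0.02, seed=seed))
        d, _ = scenario_mmrt_series("d-galactose", T, NoiseSpec(sigma=0.02, seed=seed + 1000),
                                    kie_divisor=1.7, isotopologue="deuterated")
        kies.append(fit_kie_pair(h, d, T0=348.0).kie_at(348.0))
    assert np.mean(kies) == pytest.approx(1.7, abs=0.05)


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def test_bootstrap_zero_noise_zero_width():
    s, _ = scenario_mmrt_series("d-glucose", np.linspace(293, 358, 14))
    ci = bootstrap_ci(s, n_boot=100, seed=0)
    assert ci["degenerate"]
    for k in ("dH_T0", "dS_T0", "dCp"):
        assert ci[k][1] - ci[k][0] == pytest.approx(0.0, abs=1e-9)


def test_bootstrap_deterministic_given_seed():
    s, _ = scenario_mmrt_series("d-glucose", np.linspace(293, 358, 14),
                                NoiseSpec(sigma=0.02, seed=2))
    a = bootstrap_ci(s, n_boot=150, seed=7)
    b = bootstrap_ci(s, n_boot=150, seed=7)
    assert a["dCp"] == b["dCp"] and a["dH_T0"] == b["dH_T0"]


def test_bootstrap_ci_shrinks_with_point_count():
    """CI width scales roughly like 1/sqrt(n) when the grid density doubles."""
    widths = {}
    for n in (14, 56):
        s, _ = scenario_mmrt_series("d-glucose", np.linspace(293, 358, n),
                                    NoiseSpec(sigma=0.02, seed=3))
        ci = bootstrap_ci(s, n_boot=300, seed=1)
        widths[n] = ci["dCp"][1] - ci["dCp"][0]
    ratio = widths[14] / widths[56]
    assert 1.3 < ratio < 3.2   # ideal 2.0, generous band for bootstrap noise
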