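"""Seed-deterministic generators for every input class the pipeline consumes.

Each generator returns ``(record, GeneratorManifest)``; the manifest captures
the generator name, all parameters and the seed, and suffices to regenerate
bit-identical output. Noise streams are split deterministically per data
point (one child seed per point), so extending a grid never reshuffles the
noise on earlier points.

``SUBSTRATE_SCENARIOS`` collects the steady-state and temperature-dependence
parameters of the glucose dehydrogenase study system (ssGDH with NADP+ and a
panel of pyranose sugars) that the generators emulate: turnover numbers,
Michaelis constants, a substrate-inhibition constant for 4-deoxy-d-glucose,
activation enthalpies and heat capacities of activation referenced to 348 K.
Entropies are never taken from tables: generators anchor the ln k intercept
through a (T, k) anchor point instead, which pins the absolute rate without
committing to any entropy convention.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .constants import H_PLANCK, K_B, KJ_TO_J, PER_MIN_TO_PER_S, R_GAS
from .io import (AbsorbanceTransient, CoordinateEnsemble, ExcitationEmissionMatrix,
                 RateConcentrationSeries, TemperatureRateSeries, ValidationError)
from .kinetics import eval_michaelis, eval_transient
from .mmrt import MMRTParams, mmrt_ln_rate

# Study-condition kinetic parameters for the ssGDH sugar panel.
# kcat in min^-1, K_M / K_i in mM, dH (348 K) in kJ mol^-1, dCp in kJ mol^-1 K^-1.
SUBSTRATE_SCENARIOS = {
    "d-glucose":        {"kcat_per_min": 651.9, "K_M": 1.0,   "K_i": None, "dH_348": 54.7, "dCp": -3.0},
    "2-deoxy":          {"kcat_per_min": 240.9, "K_M": 154.2, "K_i": None, "dH_348": 93.4, "dCp": -2.1},
    "3-deoxy":          {"kcat_per_min": 60.9,  "K_M": 129.2, "K_i": None, "dH_348": 65.1, "dCp": -2.4},
    "4-deoxy":          {"kcat_per_min": 761.4, "K_M": 15.04, "K_i": 29.5, "dH_348": 70.4, "dCp": 1.4},
    "d-xylose":         {"kcat_per_min": 700.0, "K_M": 0.5,   "K_i": None, "dH_348": 73.4, "dCp": -2.3},
    "d-galactose":      {"kcat_per_min": 613.4, "K_M": 1.0,   "K_i": None, "dH_348": 67.9, "dCp": -1.1},
    "d-mannose":        {"kcat_per_min": 141.1, "K_M": 711.3, "K_i": None, "dH_348": 58.5, "dCp": -2.9},
}

#: reference temperature (K) at which the scenario dH values apply
SCENARIO_T0 = 348.0

#: primary KIE magnitude (k_H/k_D) of the hydride transfer for d-galactose
GALACTOSE_KIE = 1.7

#: major-phase amplitude fraction of low-temperature biphasic transients
MAJOR_PHASE_FRACTION = 0.97

#: dominant substrate-orientation population for the glucose-like case
DOMINANT_ORIENTATION_FRACTION = 0.85


@dataclass(frozen=True)
class NoiseSpec:
    """Noise model applied point-wise to generated data.

    ``multiplicative-lognormal``: x -> x * exp(sigma * z), homoscedastic in
    ln x (the default for rates, matching the log-space fitting choice).
    ``additive-gaussian``: x -> x + sigma * z (absolute sigma).
    """

    kind: str = "multiplicative-lognormal"
    sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("multiplicative-lognormal", "additive-gaussian"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.sigma == 0:
            return values.copy()
        z = _per_point_normals(self.seed, values.size).reshape(values.shape)
        if self.kind == "multiplicative-lognormal":
            return values * np.exp(self.sigma * z)
        return values + self.sigma * z


def _per_point_normals(seed: int, n: int) -> np.ndarray:
    """One standard normal per point from per-point child streams."""
    children = np.random.SeedSequence(seed).spawn(n)
    return np.array([np.random.default_rng(c).standard_normal() for c in children])


@dataclass(frozen=True)
class GeneratorManifest:
    """Everything needed to regenerate a synthetic record bit-identically."""

    generator: str
    parameters: dict
    seed: int
    created: str = field(default_factory=lambda: _dt.datetime.now().isoformat())

    def as_dict(self) -> dict:
        return {"generator": self.generator, "parameters": _plain(self.parameters),
                "seed": self.seed, "created": self.created}


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


# ---------------------------------------------------------------------------
# Kinetic generators
# ---------------------------------------------------------------------------

def gen_transient(phases, offset, time, noise: NoiseSpec | None = None,
                  temperature: float = 298.15, label: str = "synthetic"):
    """Stopped-flow transient from phases [(A, k, b), ...] plus noise.

    Noise defaults to none; additive Gaussian is the physically sensible
    kind for absorbance.
    """
    noise = noise or NoiseSpec(kind="additive-gaussian", sigma=0.0)
    time = np.asarray(time, dtype=float)
    A = np.array([p[0] for p in phases], dtype=float)
    k = np.array([p[1] for p in phases], dtype=float)
    b = np.array([p[2] for p in phases], dtype=float)
    if np.any(k <= 0) or np.any((b <= 0) | (b > 1.5)):
        raise ValidationError("phase rates must be positive and stretches in (0, 1.5]")
    clean = eval_transient(A, k, b, offset, time)
    record = AbsorbanceTransient(time=time, absorbance=noise.apply(clean),
                                 temperature=temperature, label=label)
    manifest = GeneratorManifest(
        "gen_transient",
        {"phases": [list(p) for p in phases], "offset": offset, "time": time,
         "noise": {"kind": noise.kind, "sigma": noise.sigma},
         "temperature": temperature, "label": label},
        noise.seed)
    return record, manifest


def gen_mm_series(kcat: float, K_M: float, substrate_conc, K_i: float | None = None,
                  enzyme_conc: float = 1.0, temperature: float = 298.15,
                  noise: NoiseSpec | None = None, substrate: str = "",
                  isotopologue: str = "protiated"):
    """Rate-concentration series v(S) = E * kcat * S / (K_M + S [+ S^2/K_i]).

    *kcat* is in s^-1; the stored rates are velocities in concentration units
    of *enzyme_conc* per second, so fitting recovers kcat via Vmax / E.
    """
    noise = noise or NoiseSpec()
    if kcat <= 0 or K_M <= 0 or (K_i is not None and K_i <= 0) or enzyme_conc <= 0:
        raise ValidationError("kinetic parameters must be positive")
    S = np.asarray(substrate_conc, dtype=float)
    clean = enzyme_conc * eval_michaelis(kcat, K_M, S, K_i=K_i)
    record = RateConcentrationSeries(
        substrate_conc=S, rate=noise.apply(clean), temperature=temperature,
        enzyme_conc=enzyme_conc, substrate=substrate, isotopologue=isotopologue)
    manifest = GeneratorManifest(
        "gen_mm_series",
        {"kcat": kcat, "K_M": K_M, "K_i": K_i, "enzyme_conc": enzyme_conc,
         "substrate_conc": S, "temperature": temperature,
         "noise": {"kind": noise.kind, "sigma": noise.sigma},
         "substrate": substrate, "isotopologue": isotopologue},
        noise.seed)
    return record, manifest


def anchored_entropy(dH_T0: float, dCp: float, T0: float,
                     T_anchor: float, k_anchor: float) -> float:
    """dS_T0 (kJ mol^-1 K^-1) making ln k pass exactly through (T_anchor, k_anchor).

    Inverts the MMRT rate law for the entropy term, so generated series are
    pinned by an observable rate rather than by any tabulated entropy
    convention.
    """
    dH = dH_T0 * KJ_TO_J
    dCpJ = dCp * KJ_TO_J
    ln_pref = np.log(K_B * T_anchor / H_PLANCK)
    dS = (R_GAS * (np.log(k_anchor) - ln_pref)
          + (dH + dCpJ * (T_anchor - T0)) / T_anchor
          - dCpJ * np.log(T_anchor / T0))
    return float(dS / KJ_TO_J)


def gen_mmrt_series(dH_T0: float, dCp: float, T0: float, anchor, temperature,
                    noise: NoiseSpec | None = None, substrate: str = "",
                    isotopologue: str = "protiated"):
    """Temperature-rate series from the MMRT law, anchored at (T_anchor, k_anchor).

    ``anchor = (T_anchor_K, k_anchor_per_s)``; the entropy at T0 is chosen so
    the noiseless model passes exactly through the anchor.
    """
    noise = noise or NoiseSpec()
    T_anchor, k_anchor = anchor
    if k_anchor <= 0:
        raise ValidationError("anchor rate must be positive")
    T = np.asarray(temperature, dtype=float)
    if np.any(T <= 0):
        raise ValidationError("temperature grid must be positive kelvin")
    dS_T0 = anchored_entropy(dH_T0, dCp, T0, T_anchor, k_anchor)
    params = MMRTParams(dH_T0=dH_T0, dS_T0=dS_T0, dCp=dCp, T0=T0)
    clean = np.exp(mmrt_ln_rate(params, T))
    record = TemperatureRateSeries(temperature=T, rate=noise.apply(clean),
                                   substrate=substrate, isotopologue=isotopologue)
    manifest = GeneratorManifest(
        "gen_mmrt_series",
        {"dH_T0": dH_T0, "dCp": dCp, "T0": T0, "anchor": list(anchor),
         "dS_T0": dS_T0, "temperature": T,
         "noise": {"kind": noise.kind, "sigma": noise.sigma},
         "substrate": substrate, "isotopologue": isotopologue},
        noise.seed)
    return record, manifest


def scenario_mmrt_series(substrate: str, temperature, noise: NoiseSpec | None = None,
                         kie_divisor: float = 1.0, isotopologue: str = "protiated"):
    """MMRT series for a named scenario, anchored at its kcat(348 K).

    ``kie_divisor`` scales the anchor rate down (deuterated isotopologues).
    """
    sc = SUBSTRATE_SCENARIOS[substrate]
    k348 = sc["kcat_per_min"] * PER_MIN_TO_PER_S / kie_divisor
    return gen_mmrt_series(sc["dH_348"], sc["dCp"], SCENARIO_T0,
                           anchor=(SCENARIO_T0, k348), temperature=temperature,
                           noise=noise, substrate=substrate, isotopologue=isotopologue)


# ---------------------------------------------------------------------------
# Spectral generator
# ---------------------------------------------------------------------------

def gen_eem(csm0: float, amplitude: float, curvature: float, peak_width: float,
            excitation, emission, noise: NoiseSpec | None = None,
            label: str = "synthetic"):
    """Excitation-emission matrix whose CSM curve follows CSM0 + A exp(R dLam).

    Each excitation row is a Gaussian emission band (sd *peak_width* nm); the
    band centre is solved per row so that the DISCRETE center of spectral
    mass on the given emission grid equals the target exactly, which makes
    the zero-noise output an exact fixed point of the CSM/QUBES analysis
    despite grid truncation of the band tails.
    """
    noise = noise or NoiseSpec(kind="additive-gaussian", sigma=0.0)
    if peak_width <= 0 or curvature <= 0:
        raise ValidationError("peak width and curvature must be positive")
    ex = np.asarray(excitation, dtype=float)
    em = np.asarray(emission, dtype=float)
    dlam = ex - ex.min()
    targets = csm0 + amplitude * np.exp(curvature * dlam)
    if np.any(targets <= em.min()) or np.any(targets >= em.max()):
        raise ValidationError("target CSM values must lie inside the emission range")

    def discrete_csm(center):
        f = np.exp(-0.5 * ((em - center) / peak_width) ** 2)
        return float((f * em).sum() / f.sum())

    intensity = np.empty((ex.size, em.size))
    for i, target in enumerate(targets):
        # discrete_csm is monotone in the centre; bracket generously
        c = brentq(lambda c: discrete_csm(c) - target,
                   em.min() - 5 * peak_width, em.max() + 5 * peak_width)
        intensity[i] = np.exp(-0.5 * ((em - c) / peak_width) ** 2)
    record = ExcitationEmissionMatrix(
        excitation_wavelengths=ex, emission_wavelengths=em,
        intensity=np.clip(noise.apply(intensity), 0.0, None), label=label)
    manifest = GeneratorManifest(
        "gen_eem",
        {"csm0": csm0, "amplitude": amplitude, "curvature": curvature,
         "peak_width": peak_width, "excitation": ex, "emission": em,
         "noise": {"kind": noise.kind, "sigma": noise.sigma}, "label": label},
        noise.seed)
    return record, manifest


# ---------------------------------------------------------------------------
# Ensemble generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovarianceBlock:
    """One block of a factor-model displacement covariance.

    Atoms in the block fluctuate with sd *sigma* (Angstrom, isotropic); a
    fraction *internal_corr* of the displacement variance is carried by a
    shared latent factor with the given *sign*, so within-block correlation
    is internal_corr and the cross-block correlation of blocks b, c is
    sign_b * sign_c * sqrt(rho_b * rho_c) — positive semidefinite by
    construction.
    """

    atom_indices: np.ndarray
    sigma: float = 0.5
    internal_corr: float = 0.7
    sign: int = 1

    def __post_init__(self):
        object.__setattr__(self, "atom_indices", np.asarray(self.atom_indices, dtype=int))
        if not (0 <= self.internal_corr < 1):
            raise ValidationError("internal_corr must be in [0, 1)")
        if self.sign not in (-1, 1):
            raise ValidationError("sign must be +1 or -1")
        if self.sigma < 0:
            raise ValidationError("sigma must be non-negative")


def gen_ensemble(reference: CoordinateEnsemble, n_frames: int,
                 blocks=None, isotropic_sigma: float = 0.0,
                 rigid_body: tuple[float, float] | None = None,
                 orientation_mixture=None, seed: int = 0):
    """Gaussian coordinate ensemble around a reference structure.

    Parameters
    ----------
    reference : single-frame CoordinateEnsemble supplying geometry and labels
    blocks : optional list of CovarianceBlock for correlated motion
    isotropic_sigma : independent Gaussian jitter (Angstrom) on every atom
    rigid_body : optional (rotation_sd_degrees, translation_sd_A) applied per
        frame; removed again by alignment, so fluctuation statistics should
        be blind to it
    orientation_mixture : optional (fraction, substrate_indices, alt_pose)
        where a Bernoulli(fraction) draw per frame keeps the substrate atoms
        at the reference pose, else swaps in ``alt_pose`` (n_sub, 3)
    seed : master seed; every stochastic ingredient derives from it
    """
    if reference.n_frames != 1:
        raise ValidationError("reference must be a single-frame ensemble")
    if n_frames < 1:
        raise ValidationError("n_frames must be >= 1")
    ref = reference.coordinates[0]
    n_atoms = ref.shape[0]
    root = np.random.SeedSequence(seed)
    s_latent, s_iso, s_rigid, s_mix = root.spawn(4)
    rng_latent = np.random.default_rng(s_latent)
    rng_iso = np.random.default_rng(s_iso)
    rng_rigid = np.random.default_rng(s_rigid)
    rng_mix = np.random.default_rng(s_mix)

    frames = np.repeat(ref[None, :, :], n_frames, axis=0)

    if blocks:
        # blocks couple through a single shared factor so cross-block sign
        # structure is controlled
        shared = rng_latent.standard_normal((n_frames, 3))
        for bi, blk in enumerate(blocks):
            rho = blk.internal_corr
            eps = rng_latent.standard_normal((n_frames, blk.atom_indices.size, 3))
            disp = blk.sigma * (np.sqrt(rho) * blk.sign * shared[:, None, :]
                                + np.sqrt(1 - rho) * eps)
            frames[:, blk.atom_indices, :] += disp
    if isotropic_sigma > 0:
        frames += isotropic_sigma * rng_iso.standard_normal(frames.shape)

    mixture_flags = None
    if orientation_mixture is not None:
        fraction, sub_idx, alt_pose = orientation_mixture
        sub_idx = np.asarray(sub_idx, dtype=int)
        alt_pose = np.asarray(alt_pose, dtype=float)
        if alt_pose.shape != (sub_idx.size, 3):
            raise ValidationError("alt_pose must be (n_substrate_atoms, 3)")
        mixture_flags = rng_mix.random(n_frames) >= fraction  # True -> alt pose
        offset = alt_pose - ref[sub_idx]
        for f in np.flatnonzero(mixture_flags):
            frames[f, sub_idx, :] += offset

    if rigid_body is not None:
        rot_sd_deg, trans_sd = rigid_body
        for f in range(n_frames):
            axis = rng_rigid.standard_normal(3)
            axis /= np.linalg.norm(axis)
            angle = np.radians(rng_rigid.normal(0, rot_sd_deg))
            Rm = _rotation_matrix(axis, angle)
            center = frames[f].mean(axis=0)
            frames[f] = (frames[f] - center) @ Rm.T + center
            frames[f] += rng_rigid.normal(0, trans_sd, size=3)

    ens = CoordinateEnsemble(
        coordinates=frames, atom_names=reference.atom_names,
        residue_ids=reference.residue_ids, residue_names=reference.residue_names,
        chain_ids=reference.chain_ids)
    manifest = GeneratorManifest(
        "gen_ensemble",
        {"n_frames": n_frames, "isotropic_sigma": isotropic_sigma,
         "rigid_body": list(rigid_body) if rigid_body else None,
         "blocks": [{"atoms": b.atom_indices, "sigma": b.sigma,
                     "internal_corr": b.internal_corr, "sign": b.sign}
                    for b in (blocks or [])],
         "orientation_fraction": (orientation_mixture[0]
                                  if orientation_mixture else None)},
        seed)
    return ens, manifest


def _rotation_matrix(axis, angle):
    """Rodrigues rotation about a unit axis."""
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    C = 1 - c
    return np.array([
        [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
        [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
        [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
    ])
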