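"""Red edge excitation shift (REES) quantification.

Tryptophan emission spectra broaden and red-shift as the excitation moves to
the red edge, photo-selecting discrete solvent-relaxed conformational states.
Each emission spectrum is summarised by its center of spectral mass,

    CSM = sum_i f_i lambda_i / sum_i f_i,

the intensity-weighted mean emission wavelength. The CSM vs excitation curve
is then condensed into three numbers by fitting the exponential

    CSM(lam_Ex) = CSM0 + A exp(R * (lam_Ex - min lam_Ex)),

where CSM0 is the excitation-independent baseline (solvent exposure), A the
amplitude above it at the bluest excitation and R the curvature of the red
edge rise. The ratio A/R serves as a compact flexibility metric: with an
invariant CSM0, a larger A/R indicates a broader equilibrium of emissive
conformational substates ("less rigid").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .io import ExcitationEmissionMatrix, ValidationError


@dataclass(frozen=True)
class CSMCurve:
    """Center of spectral mass per excitation wavelength."""

    excitation_wavelengths: np.ndarray  # nm
    csm: np.ndarray                     # nm
    label: str = ""


@dataclass(frozen=True)
class QUBESFit:
    """Exponential quantification of a CSM curve: CSM0 + A exp(R dLam).

    ``unidentifiable_R`` flags a flat input curve, for which A = 0 and R is
    meaningless; A/R is reported as nan in that case.
    """

    csm0: float            # nm
    amplitude: float       # nm (A)
    curvature: float       # nm^-1 (R)
    se: dict
    residual_rms: float
    unidentifiable_R: bool = False

    @property
    def a_over_r(self) -> float:
        if self.unidentifiable_R or self.curvature == 0:
            return float("nan")
        return self.amplitude / self.curvature

    def __call__(self, excitation_wavelengths, reference=None):
        lam = np.asarray(excitation_wavelengths, dtype=float)
        ref = lam.min() if reference is None else reference
        return self.csm0 + self.amplitude * np.exp(self.curvature * (lam - ref))


def compute_csm(emission_wavelengths, intensities, baseline: float | None = None) -> float:
    """Intensity-weighted mean emission wavelength of one spectrum (nm).

    An optional constant *baseline* is subtracted first (negative values are
    clipped to zero). The total intensity after baseline handling must be
    positive; the result always lies inside the emission wavelength range.
    """
    lam = np.asarray(emission_wavelengths, dtype=float)
    f = np.asarray(intensities, dtype=float)
    if lam.shape != f.shape or lam.ndim != 1:
        raise ValidationError("wavelengths and intensities must be 1-D and matched")
    if baseline is not None:
        f = np.clip(f - baseline, 0.0, None)
    total = f.sum()
    if total <= 0:
        raise ValidationError("total intensity must be positive to form a CSM")
    csm = float((f * lam).sum() / total)
    assert lam.min() <= csm <= lam.max()
    return csm


def estimate_baseline(eem: ExcitationEmissionMatrix, n_red_points: int = 10) -> float:
    """Constant instrument baseline: mean intensity of the reddest emission points."""
    order = np.argsort(eem.emission_wavelengths)
    red = order[-n_red_points:]
    return float(eem.intensity[:, red].mean())


def csm_curve(eem: ExcitationEmissionMatrix, baseline: float | None = None) -> CSMCurve:
    """One CSM per excitation row, preserving excitation order."""
    csm = np.empty(eem.excitation_wavelengths.size)
    for i, lam_ex in enumerate(eem.excitation_wavelengths):
        try:
            csm[i] = compute_csm(eem.emission_wavelengths, eem.intensity[i], baseline)
        except ValidationError as e:
            raise ValidationError(f"excitation {lam_ex:g} nm: {e}") from e
    return CSMCurve(excitation_wavelengths=eem.excitation_wavelengths.copy(),
                    csm=csm, label=eem.label)


_FLAT_TOL = 1e-9   # nm^2 variance below which a CSM curve counts as flat


def fit_qubes(curve: CSMCurve, seed: int = 0) -> QUBESFit:
    """Nonlinear LS fit of CSM(lam_Ex) = CSM0 + A exp(R dLam), R > 0.

    dLam is measured from the bluest excitation in the curve, so A is the
    amplitude above CSM0 there. Multi-start over the curvature R guards
    against the usual exponential-fit initialisation trap. A flat curve
    returns A = 0, CSM0 = mean and an unidentifiable-R flag.
    """
    lam = np.asarray(curve.excitation_wavelengths, dtype=float)
    y = np.asarray(curve.csm, dtype=float)
    if lam.size < 6:
        raise ValidationError("QUBES fit needs at least 6 excitation points")
    dlam = lam - lam.min()

    if np.var(y) < _FLAT_TOL:
        return QUBESFit(csm0=float(np.mean(y)), amplitude=0.0, curvature=0.0,
                        se={"csm0": 0.0, "amplitude": 0.0, "curvature": np.nan},
                        residual_rms=float(np.std(y)), unidentifiable_R=True)

    rng = np.random.default_rng(seed)
    span = dlam.max()
    amp0 = max(y[-1] - y[0], 1e-3)

    def resid(p):
        csm0, A, R = p
        return csm0 + A * np.exp(R * dlam) - y

    best = None
    for r0 in np.geomspace(0.01, 1.0, 6):
        jit = np.exp(rng.normal(0, 0.05))
        # amplitude guess consistent with the total rise at this curvature
        a0 = amp0 / max(np.exp(r0 * span) - 1.0, 1e-6)
        p0 = [y[0] - a0, a0, r0 * jit]
        try:
            res = least_squares(resid, p0, bounds=([-np.inf, -np.inf, 1e-6],
                                                   [np.inf, np.inf, 10.0]))
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise ValidationError("QUBES fit failed from every start")

    rss = float(2 * best.cost)
    n = y.size
    dof = max(n - 3, 1)
    try:
        cov = np.linalg.pinv(best.jac.T @ best.jac) * rss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    return QUBESFit(csm0=float(best.x[0]), amplitude=float(best.x[1]),
                    curvature=float(best.x[2]),
                    se={"csm0": se[0], "amplitude": se[1], "curvature": se[2]},
                    residual_rms=float(np.sqrt(rss / n)))
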