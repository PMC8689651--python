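# Methods

## The MMRT rate law and what is estimated

Transition state theory writes the first-order rate constant as
k = κ (k_B T / h) exp(−ΔG‡ / RT). Macromolecular rate theory adds a constant
difference in heat capacity between the enzyme–substrate ground state and
the transition state, ΔC_P‡, which makes the activation enthalpy and entropy
temperature dependent:

    ΔH‡(T) = ΔH‡_T0 + ΔC_P‡ (T − T0)
    ΔS‡(T) = ΔS‡_T0 + ΔC_P‡ ln(T / T0)

T0 is an arbitrary reference temperature; predictions are invariant to its
choice and the fitter exposes it as a parameter (default 348 K, the
temperature at which the study system's activation parameters are quoted).
A negative ΔC_P‡ produces an interior rate optimum at the temperature where
ΔH‡(T) = −RT (`rate_optimum_temperature`), well below any unfolding
transition — the signature that distinguishes MMRT curvature from
denaturation. Alternative curvature sources (two-state or equilibrium
unfolding models) are deliberately out of scope.

**Fitting.** The fit target is y = ln k − ln(k_B T / h), which is exactly
linear in the basis {1, 1/T, ln T}. The solve is closed-form (weighted)
linear least squares; basis coefficients and their covariance map linearly
to (ΔH‡_T0, ΔS‡_T0, ΔC_P‡). This removes the initialisation sensitivity of
generic nonlinear fitting; a test cross-checks the closed form against an
independent iterative optimiser. Fits are performed on ln k, unweighted by
default: multiplicative rate noise is homoscedastic in log space. Optional
inverse-variance weighting uses se(ln k) = se(k)/k.

**Units and conventions.** Internal canonical units are K, s, s⁻¹, mM, nm,
Å, kJ mol⁻¹ and kJ mol⁻¹ K⁻¹. Rates are converted to s⁻¹ before the
k_B T / h prefactor is applied, so ΔS‡_T0 has an absolute meaning tied to
that rate unit. Published activation-entropy tables for this system use an
unexplained convention with values orders of magnitude above typical ones;
the generators therefore never consume a tabulated entropy — they anchor
the intercept by requiring the noiseless curve to pass exactly through a
(T_anchor, k_anchor) pair (`anchored_entropy`), with k_anchor the quoted
turnover number at 348 K. Physical constants are CODATA 2018 via scipy.

**KIE.** Protiated and deuterated series are fitted independently;
KIE(T) = exp(ln k_H − ln k_D). The isotope effect on the heat capacity is
ΔΔC_P‡ = ΔC_P‡(D) − ΔC_P‡(H) with the SE combined in quadrature; reports
also print −ΔΔC_P‡ since the opposite sign convention is common. When the
two isotopologues share ΔC_P‡, ln KIE is exactly linear in 1/T (tested in
closed form).

**Uncertainty.** Asymptotic SEs come from the scaled inverse normal matrix.
`bootstrap_ci` adds residual-resampling percentile intervals (resample ln-k
residuals, add back to the fitted curve, refit by the same closed form);
it is deterministic given its seed and returns zero-width intervals with a
flag on noiseless input.

## Transient fitting

The stopped-flow model is offset + Σᵢ Aᵢ exp(−(kᵢ t)^bᵢ): the stretch bᵢ
sits inside the power so kᵢ keeps units of s⁻¹, and b = 1 is an ordinary
exponential (b near 1 in real data indicates no unresolved extra phases).
b is bounded in (0, 1.5].

Exponential fitting is initialisation sensitive, so the fitter multi-starts
from 8 log-spaced rate guesses spanning the record with seed-controlled
jitter and keeps the best converged solution. Rates are constrained to the
identifiable window 0.5/t_span ≤ k ≤ 5/Δt: a phase slower than half an
e-fold over the record is indistinguishable from the offset (in noisy data
such a degenerate phase can even have marginally lower residuals while
corrupting the amplitude split), and a faster one decays between the first
two samples. Solutions at these bounds carry a warning flag. Phases are
ordered by decreasing amplitude fraction |Aᵢ|/Σ|Aⱼ| (ties by faster rate).

Phase-count selection (1 vs 2) uses the small-sample corrected AIC so that
nested and non-nested comparisons (e.g. stretch on/off) are handled
uniformly. The second phase must improve AICc by more than 2 units — the
conventional threshold for substantial support; anything closer resolves to
the single phase. Exact-tie breaking alone turned out to prefer two phases
on pure single-exponential data with noise, which is the wrong answer.

## Steady-state kinetics

Michaelis–Menten fits run nonlinear least squares with multi-start K_M
initialisation. Substrate inhibition uses the uncompetitive single-K_i form
v = V_max S / (K_M + S + S²/K_i) — the standard choice for rate loss at
high substrate, and mechanistically consistent with a nonproductive binding
orientation filling at high concentration. Its rate maximum sits at
S* = √(K_M K_i) (verified against dense grid search). In `auto` mode both
forms are fitted and the inhibition form is kept only if it wins AICc and
its K_i is identifiable (not driven above 10⁴·K_M, where the two forms are
indistinguishable). k_cat = V_max / [E] with velocity and enzyme
concentration in consistent units; per-monomer active-site concentration is
the default convention, configurable by the caller, since the tetramer
convention is not standardised.

## REES / QUBES

CSM is the intensity-weighted mean emission wavelength; it is exactly
invariant to uniform intensity scaling and always lies inside the emission
range. The QUBES model CSM(λ_Ex) = CSM₀ + A exp(R Δλ_Ex) measures Δλ_Ex
from the bluest excitation in the curve, so A is the amplitude above CSM₀
there; CSM₀ is fitted freely. R multi-starts over a decade of curvatures. A
flat curve (variance < 10⁻⁹ nm²) returns A = 0, CSM₀ = mean and an
unidentifiable-R flag instead of a spurious exponential. Optional constant
baseline subtraction uses the mean of the 10 reddest emission points (off
by default). No Raman/scatter masking is applied beyond an optional
emission-window restriction. In reports a larger A/R is labelled "less
rigid" (broader equilibrium of emissive conformational substates); this is
an interpretive convention, not an asserted mechanism.

## Ensemble statistics

Superposition is the Kabsch closed form (SVD with determinant correction,
proper rotations only); degenerate (collinear, < 3 atoms) fits raise.
Average structures iterate align-to-mean / recompute-mean until the mean
shifts < 10⁻⁶ Å. RMSF is computed per atom after alignment and averaged
within residues; monomer averaging maps equal-length chains onto a common
residue numbering and averages positionally (unequal chains are an error,
never a silent truncation). Replicate RMSF profiles are compared per
residue with a two-tailed Welch t-test (Benjamini–Hochberg adjusted values
reported alongside raw p); residues with zero variance in both groups get
p = 1 and a flag.

The DCCM uses the isotropic dot-product definition
C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) on one atom per residue
(Cα by convention); zero-variance atoms get zeroed rows/columns and a flag.
Per-axis correlation variants are out of scope.

Orientation clustering aligns all frames on the fit selection (active-site
Cα) to the iterative average structure, computes pairwise RMSD over the
non-hydrogen substrate atoms in that shared frame — deliberately without
per-pair refitting, matching the shared-alignment protocol — and runs
average-linkage agglomerative clustering, cutting where the minimum
inter-cluster distance exceeds epsilon (1.5 Å default). Clusters are
relabelled by decreasing population with medoid representatives; the
procedure is deterministic and permutation-consistent.

Hydrogen bonds use heavy-atom distance ≤ 3.0 Å and D–H···A angle ≥ 135° by
default — common trajectory-analysis practice, fully configurable since no
single criterion is canonical. Donor–acceptor distances (substrate C1 to
nicotinamide C4 for hydride transfer) are plain per-frame Euclidean
distances with a 0.1 Å default histogram bin.

## Synthetic data: what it emulates and what it does not

Generators produce: exponential stopped-flow transients; Michaelis–Menten
concentration series with optional substrate inhibition; MMRT-curved
temperature–rate series; excitation–emission matrices whose CSM curve
follows the QUBES exponential; and Gaussian coordinate ensembles with
factor-model block covariance, optional rigid-body motion, and two-pose
substrate orientation mixtures. Scenario defaults
(`synthetic.SUBSTRATE_SCENARIOS`) carry the study system's published
constants: turnover numbers (s⁻¹ scale from min⁻¹ tables), K_M values, the
4-deoxy substrate-inhibition constant (29.5 mM), activation enthalpies at
348 K, and heat capacities of activation from −3.0 to +1.4 kJ mol⁻¹ K⁻¹.
Noise is multiplicative log-normal for rates (homoscedastic in ln k,
matching the fitting space) and additive Gaussian for absorbance and
fluorescence intensities. Noise streams are split per data point from a
seed tree, so extending a grid never reshuffles earlier points, and every
generator's manifest suffices to regenerate output bit-identically.

For the EEM generator, each excitation row is a Gaussian emission band
(default sd 20 nm, roughly a tryptophan band) whose centre is root-solved
so that the *discrete* CSM on the sampled emission grid equals the target
exactly; zero-noise output is therefore an exact fixed point of the
CSM/QUBES analysis despite band-tail truncation at the grid edges.

What the generators do **not** emulate: instrument dead time and detector
shot noise; photophysics beyond a single Gaussian band (no Raman/scatter
peaks, no per-tryptophan decomposition); real MD force-field physics,
solvent, or periodic boundary effects; heteroscedastic kinetic noise. A
passing recovery test therefore demonstrates the estimators are correct and
well calibrated for data of the assumed structure — not that real
instrument data meet those assumptions.

The stopped-flow sampling rate and record length are not specified by the
study; fixtures use 500 points over 2 s, which resolves both phases of the
biphasic regime (rates 3 and 30 s⁻¹).

## Problem sizes and determinism

Recovery experiments (`thermocat.experiments`) use the documented study
conditions: 14 temperatures over 293–358 K at 2% rate noise (10 seeds) for
MMRT; 10–12 concentrations at 3–5% noise (20 seeds) for Michaelis–Menten;
500-point transients at 1% additive noise (10 seeds); 500-frame two-pose
ensembles at 0.3 Å thermal noise for clustering. Every stochastic path
derives its seeds from one master seed through `numpy.random.SeedSequence`,
so all reported numbers are exactly reproducible; pipeline reruns with the
same config and seed are byte-identical.

## Known limitations

- Global (shared-parameter) fitting across temperatures, pre-steady-state
  burst analysis and dead-time correction are not implemented.
- MMRT fits assume a single rate-limiting step over the whole temperature
  range; the package measures curvature, it cannot itself rule out
  convolved processes (the transient-phase analysis is the tool for that).
- Binary trajectory formats (DCD/XTC/NetCDF) and mmCIF are not supported;
  ensembles travel as multi-model PDB and are assumed imaged.
- Asymptotic SEs are first-order; for strongly correlated parameters
  (V_max/K_i at sparse high-substrate coverage) the bootstrap is the more
  honest interval.
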