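# thermocat

Analysis toolkit for the temperature dependence of enzyme turnover, built
around macromolecular rate theory (MMRT). It covers the full experimental
chain used to dissect how individual enzyme–substrate interactions shape
temperature activity in a hyperthermophilic glucose dehydrogenase working
on a panel of pyranose sugars:

- **Stopped-flow transients** — sums of (optionally stretched) exponentials,
  `A(t) = offset + Σᵢ Aᵢ exp(−(kᵢ t)^bᵢ)`, with AICc phase-count selection.
- **Steady-state kinetics** — Michaelis–Menten fits, optionally with
  uncompetitive substrate inhibition `v = V_max S / (K_M + S + S²/K_i)`.
- **MMRT** — the heat capacity of activation ΔC_P‡ from curved ln k vs T:

  ```
  ln k(T) = ln(κ k_B T / h) − [ΔH‡_T0 + ΔC_P‡ (T − T0)] / (R T)
                            + [ΔS‡_T0 + ΔC_P‡ ln(T/T0)] / R
  ```

  With y = ln k − ln(k_B T / h) this model is linear in {1, 1/T, ln T}, so
  the fit is a closed-form least squares with exact covariance propagation —
  no nonlinear optimiser, no initialisation sensitivity.
- **Kinetic isotope effects** — paired H/D MMRT fits give KIE(T) = k_H/k_D
  and the isotope difference ΔΔC_P‡ with quadrature errors.
- **REES / QUBES** — center of spectral mass CSM = Σ fᵢλᵢ / Σ fᵢ per
  excitation wavelength, fitted to CSM(λ_Ex) = CSM₀ + A·exp(R·Δλ_Ex); the
  A/R ratio is a compact protein-flexibility metric.
- **Ensemble dynamics** — Kabsch superposition, iterative average structures,
  per-residue RMSF with replicate Welch t-tests, dynamical cross-correlation
  matrices, average-linkage orientation clustering (epsilon cutoff),
  donor–acceptor distances and hydrogen-bond occupancies on multi-model PDB
  ensembles.
- **Synthetic data** — seed-deterministic generators for every input class,
  parameterised by the study's published kinetic constants, so the whole
  pipeline is testable without any instrument data.

## Worked example

Fit the MMRT model to a noisy synthetic k_cat(T) series (14 temperatures,
293–358 K, 2% rate noise) generated from the d-glucose scenario:

```python
import numpy as np
from thermocat import fit_mmrt
from thermocat.synthetic import NoiseSpec, scenario_mmrt_series

T = np.linspace(293.0, 358.0, 14)
series, _ = scenario_mmrt_series("d-glucose", T, noise=NoiseSpec(sigma=0.02, seed=1))
fit = fit_mmrt(series, T0=348.0)
print(fit.params.dCp, fit.se["dCp"])
```

Running `python examples/01_mmrt_fit.py` prints:

```
dCp   =  -2.970 +/- 0.033 kJ/mol/K
dH_T0 =   55.13 +/- 0.86 kJ/mol   (T0 = 348 K)
residual RMS in ln k: 0.0227
dG at 298 K: 86.57 kJ/mol; at 348 K: 78.82 kJ/mol
```

The fitted ΔC_P‡ ≈ −3.0 kJ mol⁻¹ K⁻¹ recovers the generating value: a
negative heat capacity of activation makes ΔH‡ fall with temperature and
produces the characteristic curvature (and rate optimum) in ln k vs T.
`examples/02_michaelis_menten.py` does the same for substrate inhibition:

```
k_cat =  708.4 min^-1
K_M   =  13.36 mM
K_i   =  32.22 mM  (inhibition detected: True)
rate maximum at S* = sqrt(K_M K_i) = 20.7 mM
```

The other examples cover the KIE profile (`03`), REES/QUBES (`04`),
trajectory statistics (`05`) and the orchestrated multi-substrate pipeline
(`06`). A thin CLI mirrors the library:
`thermocat fit-mmrt series.csv --t0 348 --boot 1000 --seed 1`,
`thermocat kie --protiated h.csv --deuterated d.csv`,
`thermocat rees --eem eem.csv`, `thermocat traj cluster ens.pdb ...`,
`thermocat run config.yaml`.

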