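"""Michaelis-Menten fits with and without substrate inhibition.

The 4-deoxy sugar scenario shows apparent substrate inhibition: rate falls
at high substrate as a nonproductive binding mode fills. The uncompetitive
single-K_i form v = Vmax S / (K_M + S + S^2/K_i) captures it; auto model
selection keeps the K_i term only when AICc supports it.
"""

import numpy as np

from thermocat import fit_michaelis, substrate_inhibition_optimum
from thermocat.synthetic import NoiseSpec, gen_mm_series

S = np.geomspace(1.0, 200.0, 12)
series, _ = gen_mm_series(kcat=761.4 / 60, K_M=15.04, substrate_conc=S, K_i=29.5,
                          noise=NoiseSpec(sigma=0.05, seed=11), substrate="4-deoxy")

fit = fit_michaelis(series, inhibition="auto")
print(f"k_cat = {fit.k_cat * 60:6.1f} min^-1")
print(f"K_M   = {fit.K_M:6.2f} mM")
print(f"K_i   = {fit.K_i:6.2f} mM  (inhibition detected: {fit.has_inhibition})")
print(f"rate maximum at S* = sqrt(K_M K_i) = "
      f"{substrate_inhibition_optimum(fit.K_M, fit.K_i):.1f} mM")

# K_i ~ 30 mM means the velocity peaks near 20 mM substrate and declines
# beyond it — the signature the clustering example traces back to a
# nonreactive substrate orientation.
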