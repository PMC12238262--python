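"""Simulate the six benchmark diffusion processes and verify their
mean-squared-displacement scaling.

Each process has a known MSD law  <r^2(t)> ~ t^alpha:  Brownian motion is
linear (alpha = 1), FBM/SBM recover the alpha they are driven with, a CTRW
and ATTM are subdiffusive, and a Lévy walk is superdiffusive.  The fitted
log-log slope printed for each process should match that expectation.
"""

import numpy as np

from lptraj.simulate import (simulate_attm, simulate_bm, simulate_ctrw,
                             simulate_fbm, simulate_lw, simulate_sbm)
from lptraj.stats import ensemble_msd

n, T = 1000, 300

runs = [
    ("BM", simulate_bm(T, n, seed=1), True, 1.0),
    ("FBM alpha=0.5", simulate_fbm(0.5, T, n, seed=2), True, 0.5),
    ("SBM alpha=0.5", simulate_sbm(0.5, T, n, seed=3), False, 0.5),
    ("CTRW alpha=0.5", simulate_ctrw(0.5, T, n, seed=4), False, None),
    ("ATTM alpha=0.5", simulate_attm(0.5, T, n, seed=5), False, None),
    ("LW alpha=1.5", simulate_lw(1.5, T, n, seed=6), False, None),
]

print(f"{n} trajectories x {T} frames per process")
print(f"{'process':<16}{'fitted alpha':>14}  expectation")
for name, ds, time_avg, alpha in runs:
    es = ensemble_msd(ds, 20, time_average=time_avg)
    note = (f"~ {alpha}" if alpha is not None
            else ("< 1 (subdiffusive)" if "LW" not in name
                  else "> 1 (superdiffusive)"))
    print(f"{name:<16}{es.alpha_hat:>14.3f}  {note}")

# Brownian motion additionally satisfies MSD(t) = 2 t exactly
# (two components, D = 1/2 per axis):
es = ensemble_msd(simulate_bm(300, 2000, seed=7), 5)
print("\nBM MSD at lags 1..5 (expect 2, 4, 6, 8, 10):",
      np.round(es.msd, 2))
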