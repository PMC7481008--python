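"""Autocorrelation analysis of a reaction-coordinate time series.

An AR(1) series with phi = 0.9 mimics a slowly decorrelating observable;
its statistical inefficiency g = (1+phi)/(1-phi) = 19 tells how many
correlated samples equal one independent one.
"""

import numpy as np

import mdinfer as m

x = m.gen_ar1(phi=0.9, sigma=1.0, n=100_000, seed=21)
res = m.acf(x, max_lag=100)
print(f"rho(1) = {res.acf[1]:.3f} (analytic 0.9)")
print(f"rho(10) = {res.acf[10]:.3f} (analytic {0.9**10:.3f})")
print(f"integrated autocorrelation time = {res.integrated_time:.1f} steps")
print(f"statistical inefficiency g = {res.inefficiency:.1f} (analytic 19)")
print(f"effective sample size: {len(x)} / g = {len(x)/res.inefficiency:.0f}")

sub = x[:: int(round(res.inefficiency))]
rho1 = np.corrcoef(sub[:-1], sub[1:])[0, 1]
print(f"after subsampling every g-th point: rho(1) = {rho1:.3f}")

# Error bars computed as if all samples were independent would be about
# sqrt(g) = 4.4 times too small for this series.
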