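"""Fit the LDRW indicator-dilution model to a noisy time-intensity curve.

Generates a synthetic TIC from known bolus parameters (lambda = 2, mu = 30 s),
adds 5%-of-peak Gaussian noise, and fits baseline + A*C(t; lambda, mu) by
nonlinear least squares.  The shape parameters and the derived time-to-peak
t* = mu(-1+sqrt(1+4 lambda^2))/(2 lambda) are recovered to within a percent.
"""
import numpy as np

import ceusdro as cd

true = cd.LDRWParams(m=1.0, Q=1.0, lam=2.0, mu=30.0)
t = np.arange(0.0, 200.0)  # 1 Hz sampling
clean = 0.1 + cd.ldrw_concentration(t, true)
peak = cd.ldrw_concentration(cd.ldrw_peak_time(true), true)
rng = np.random.default_rng(42)
noisy = np.clip(clean + rng.normal(0.0, 0.05 * peak, t.size), 0.0, None)

fit = cd.fit_ldrw(cd.TIC(times=t, values=noisy))
print(f"converged: {fit.converged}   residual norm: {fit.residual_norm:.4f}")
print(f"{'':<12}{'true':>10}{'fitted':>10}")
print(f"{'lambda':<12}{true.lam:>10.3f}{fit.params.lam:>10.3f}")
print(f"{'mu (s)':<12}{true.mu:>10.3f}{fit.params.mu:>10.3f}")
print(f"{'TTP (s)':<12}{cd.ldrw_peak_time(true):>10.3f}{cd.ldrw_peak_time(fit.params):>10.3f}")
print("(lambda: diffusion-related shape; mu: mean arrival time of the bolus)")
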