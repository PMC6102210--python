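"""Recovering Michaelis-Menten transport parameters from depletion data.

Generates a noisy synthetic 48 h medium time course (25 points, sigma = 0.5 mM)
from known parameters, then fits the integrated uptake model by nonlinear
least squares and prints the estimates with standard errors.
"""

import numpy as np

from petriflux import fit_mm
from petriflux.synth import simulate_uptake_observations

true_vmax, true_km, s0 = 1.3, 5.0, 25.0  # mM/h, mM, mM
times = np.linspace(0, 48, 25)
obs = simulate_uptake_observations(true_vmax, true_km, noise_sd=0.5, times=times,
                                   seed=42, s0=s0)
fit = fit_mm(obs["time"], obs["concentration"], s0=s0)
print(f"true      Vmax = {true_vmax:.3f} mM/h,  Km = {true_km:.3f} mM")
print(f"recovered Vmax = {fit.vmax:.3f} +/- {fit.vmax_se:.3f} mM/h,  "
      f"Km = {fit.km:.3f} +/- {fit.km_se:.3f} mM")
print("A flat time course would raise IdentifiabilityError instead of")
print("returning silent estimates.")
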