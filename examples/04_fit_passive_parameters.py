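"""Recover passive wall stiffness from a synthetic inflation experiment.

Generates a 20-point quasi-static pressure-radius table from known material
parameters plus Gaussian measurement noise (1% of the reference radius),
then re-estimates the identifiable passive coefficients — the ground-matrix
stiffness scale and the collagen recruitment amplitude — by trust-region
least squares, starting from a deliberately wrong guess at half the true
stiffness scale.
"""

import dataclasses

import numpy as np

from airwaymorph import MaterialParams, fit_passive_params, generate_synthetic_pr

true = MaterialParams()
pressures = np.linspace(0.05, 3.0, 20)
data = generate_synthetic_pr(true, pressures, noise_sd=0.018, seed=42)

guess = dataclasses.replace(true, c_ground=4.0, c_neo=4.0, k1_c=2.0, k1_e=12.0)
fit = fit_passive_params(data, guess)

print(f"data: {data.provenance}")
print(f"{'coefficient':<12} {'true':>8} {'guess':>8} {'fitted':>10}")
for name, truth, g in (("c_ground", true.c_ground, guess.c_ground),
                       ("k1_e", true.k1_e, guess.k1_e)):
    idx = fit.free_names.index(name)
    print(f"{name:<12} {truth:8.2f} {g:8.2f} {fit.fitted_values[idx]:10.3f}")
print(f"tied k1_c    {true.k1_c:8.2f} {guess.k1_c:8.2f} {fit.params.k1_c:10.3f}")
print(f"R^2 = {fit.r_squared:.5f}")
print("\nBoth free coefficients (and the proportionally tied muscle-fibre")
print("amplitude) land near truth despite the noisy data and the scale-wrong")
print("initial guess; R^2 close to 1 indicates the curve is well explained.")
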