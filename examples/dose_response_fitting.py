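"""Fit an agonist dose-response curve from simulated oocyte recordings.

Simulates five oocytes expressing a channel with a known EC50 and Hill slope,
normalizes each oocyte's peak currents to its own maximum (I/Imax), pools the
normalized points and fits a four-parameter Hill equation.
"""

import numpy as np

import chansyn as cs

TRUE_EC50, TRUE_H = 120.0, 2.0  # uM, cooperative activation
doses = TRUE_EC50 * np.geomspace(1 / 30, 30, 9)

series, truth = cs.gen_dose_response(
    ec50=TRUE_EC50, h=TRUE_H, doses=doses, n_oocytes=5, noise_cv=0.05, seed=42
)
normalized = [cs.normalize_by_imax(s) for s in series]
pooled_doses = np.concatenate([s.doses for s in normalized])
pooled_resp = np.concatenate([s.normalized for s in normalized])

fit = cs.fit_dose_response(pooled_doses, pooled_resp, n_params=4)

print(f"simulated truth : EC50 = {TRUE_EC50:.1f} uM, Hill slope = {TRUE_H:.2f}")
print(
    f"fitted          : EC50 = {fit.ec50:.1f} uM, Hill slope = {fit.hill_slope:.2f},"
    f" top = {fit.top:.3f}, bottom = {fit.bottom:.3f} (converged={fit.converged})"
)
print(
    "# EC50 is the agonist concentration giving a half-maximal current; a Hill\n"
    "# slope > 1 indicates positively cooperative ligand binding."
)
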