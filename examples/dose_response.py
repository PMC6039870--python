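"""Dose-response fitting: a stimulated and an inhibited interaction.

Simulates a rapamycin-style stimulation (rising BRET with dose) and a
Nutlin-style inhibition (falling BRET), fits the four-parameter logistic on
log10(dose), and reports EC50/IC50 with the inferred direction.
"""

import numpy as np

import luthy

doses = np.concatenate([[0.0], np.geomspace(1e-11, 1e-5, 9)])  # M, with vehicle

d, y, _ = luthy.simulate_dose_response(
    bottom=0.05, top=0.60, hill=1.0, ec50=2e-9, doses=doses,
    noise_cv=0.05, seed=4,
)
fit = luthy.fit_dose_response(d, y)
print(f"stimulation: EC50 = {fit.ec50:.2e} M (true 2.0e-09), "
      f"hill = {fit.hill:.2f}, direction = {fit.direction}")

d, y, _ = luthy.simulate_dose_response(
    bottom=0.55, top=0.08, hill=1.2, ec50=1e-8, doses=doses,
    noise_cv=0.05, seed=5,
)
fit = luthy.fit_dose_response(d, y)
print(f"inhibition:  IC50 = {fit.ec50:.2e} M (true 1.0e-08), "
      f"hill = {fit.hill:.2f}, direction = {fit.direction}")

print("\nEC50/IC50 is the inflection concentration of the logistic; the")
print("direction comes from the sign of (high-dose minus low-dose asymptote).")

# time-course normalization: a heat-shock style series against its control
treated = [(0, 0.10), (1.5, 0.16), (3, 0.18), (6, 0.15), (24, 0.11)]
control = [(0, 0.10), (1.5, 0.11), (3, 0.10), (6, 0.10), (24, 0.10)]
norm = luthy.normalize_timecourse(treated, control)
print("\ntime courses, treated/control ratio per time point (h):")
for t, v in norm:
    print(f"  t={t:>4} h  ratio={v:.2f}")
print("values > 1 mean the perturbation strengthened the interaction signal")
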