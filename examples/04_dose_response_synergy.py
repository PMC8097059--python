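"""Dose-response fitting and Bliss-independence synergy scoring.

Simulates triplicate viability plates for two agents plus their
combination surface with a planted synergy of epsilon = 0.1, fits 4PL
curves to recover the IC50s, and scores the surface against the Bliss
independence null (positive index = synergy).
"""

from kinsig import (DoseResponseConfig, bliss_surface, compare_ic50, fit_4pl,
                    generate_dose_response)

config = DoseResponseConfig(
    params_a=(0.0, 1.0, 1.0, 1.0),   # bottom, top, IC50 (uM), hill
    params_b=(0.0, 1.0, 2.0, 1.0),
    doses_a=(0.01, 0.03, 0.1, 0.3, 1.0, 3.0),
    doses_b=(0.01, 0.03, 0.1, 0.3, 1.0, 3.0),
    n_replicates=3, noise_sd=0.02, epsilon=0.10)
singles, combination, truth = generate_dose_response(config, seed=5)

for agent, table in singles.items():
    fit = fit_4pl(table)
    true_ic50 = truth.params_a[2] if agent == "A" else truth.params_b[2]
    print(f"agent {agent}: fitted IC50 = {fit.ic50:6.3f} uM "
          f"(true {true_ic50}), hill = {fit.hill:+.2f}")

surface = bliss_surface(singles["A"], singles["B"], combination)
print(f"mean Bliss index over the dose grid: "
      f"{surface['bliss_index'].mean():+.3f} (planted {truth.epsilon})")
print(surface.sort_values('bliss_index', ascending=False)
      .head(3).to_string(index=False))
# The mean index sits near the planted epsilon wherever the combination
# fraction is not clipped at zero; fits recover the true IC50s within noise.
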