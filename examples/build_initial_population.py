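"""Construct a synthetic initial population from marginal inputs.

Builds a smoking-like scenario (3 exposure states, 8 diseases), derives
the exact joint distribution of risk-factor and disease states from the
marginal prevalence tables, verifies the prevalence-odds-ratio identity
that defines the construction, and samples a discrete population.
"""

import numpy as np

import dynapop as dp

scenario = dp.make_synthetic_scenario(dp.ScenarioSpec(preset="smoking_like", seed=1))
joint = dp.build_joint_distribution(scenario)

# Marginals are recovered: risk-factor shares exactly, disease prevalence
# to solver tolerance.
w = np.transpose(scenario.risk_factor.prevalence_array(), (1, 2, 0))
print("max risk-marginal error:   %.2e" % np.abs(joint.risk_marginal() - w).max())
err = max(
    np.abs(joint.disease_marginal(d.name) - d.prevalence.values).max()
    for d in scenario.diseases
)
print("max disease-marginal error: %.2e" % err)

# The constitutive assumption: the prevalence odds ratio between current
# and never smokers equals the input incidence rate ratio, exactly.
i = joint.disease_names.index("copd")
pres = joint.combos[:, i] >= 1
m = joint.mass[0, 60]  # male, age 60
odds = m[:, pres].sum(axis=1) / m[:, ~pres].sum(axis=1)
por = odds[joint.risk_states.index("current")] / odds[0]
rr = scenario.disease("copd").rr_from_risk["current"].values[0, 60]
print(f"COPD POR (current vs never, men aged 60): {por:.6f}  input RR: {rr:.6f}")

# Of the men aged 60 with COPD, how are they spread over smoking states?
table = dp.risk_within_disease(joint)
sub = table[(table.sex == "male") & (table.age == 60) & (table.disease == "copd")]
print("\nwithin-COPD smoking distribution (men, 60):")
print(sub[["risk_state", "proportion"]].to_string(index=False))

# Quota-first sampling of a discrete population.
population = dp.sample_initial_population(joint, n_per_cell=100, seed=1)
print(f"\nsampled population: {len(population)} individuals, columns:")
print(list(population.columns))
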