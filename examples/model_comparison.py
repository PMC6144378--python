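"""Six-model AICc comparison and group-level model selection.

Simulates a small cohort of AL-NL observers (trial-by-trial adaptation plus
non-linear sequential effect), fits all six response models to every
participant by maximum likelihood, and compares them by summed AICc and by
protected exceedance probability — the probability that each model is the
most frequent in the population, protected against the null of equal
frequencies.
"""

import numpy as np
import pandas as pd

import relfreq as rf

gen = rf.ObserverParams(
    model="AL-NL", beta0=0.8, beta_lags=(0.05,), betaC=0.0,
    kappa=0.05, omega=2.0, sigma_noise=0.3,
)
cohort = rf.simulate_cohort(
    rf.ExperimentDesign(n_participants=6), "U", gen, rf.condition_pmf("U"), seed=11
)

rows = []
rng = np.random.default_rng(12)
for pid, grp in cohort.groupby("participant_id"):
    for family in rf.MODELS:
        fit = rf.fit_model(family, grp, n_restarts=20, seed=int(rng.integers(0, 2**31)))
        rows.append({"participant_id": pid, "family": family, "aicc": fit.aicc})
fits = pd.DataFrame(rows)

table = rf.compare_models(fits)
evidence = fits.pivot(index="participant_id", columns="family", values="aicc") * -0.5
pxp = rf.protected_exceedance_probability(evidence.to_numpy(), seed=13)
table["pxp"] = [float(pxp["pxp"][list(evidence.columns).index(f)]) for f in table.index]

print(table.round(3).to_string())
print(
    "\nThe generating family (AL-NL) should have the lowest summed AICc and"
    "\nthe bulk of the protected exceedance probability; the delta column is"
    "\nthe summed-AICc gap to the winner."
)
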