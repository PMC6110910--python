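"""Fit the dynamic CSF model: GEE with identity link and continuous-time
Markov working correlation corr = a^|Δt|, on a simulated cohort with
irregular scan times.

The simulator's defaults mirror cohort-scale effects: CSF falls ~22
ml/day with a positive quadratic term, rises ~3 ml per year of age, and
is ~33 ml lower with edema grade 3; residuals decay with a = 0.6/day.
"""

import numpy as np

from edemascan.phantom import GeeSimSpec, simulate_gee_cohort
from edemascan.stats import GeeDesign, fit_gee_markov

sim = GeeSimSpec(n_subjects=300, seed=5)
df = simulate_gee_cohort(sim)
print(f"simulated {sim.n_subjects} subjects, {len(df)} scans, 2-5 scans each over 5 days")

fit = fit_gee_markov(GeeDesign.from_frame(df))
print(fit.summary_frame().to_string(index=False))
print(f"working correlation a = {fit.a:.3f} per day (truth {sim.a}), "
      f"residual SD = {np.sqrt(fit.sigma2):.1f} ml (truth {sim.sigma})")
print(f"converged in {fit.iterations} two-stage iterations")
# Each estimate should sit within a couple of robust SEs of the simulator's
# coefficients; p-values use the sandwich covariance, so they stay valid
# even when the working correlation is misspecified.
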