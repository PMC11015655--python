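"""Generate a synthetic study cohort and inspect its calibration.

Draws an individual-level cohort at the study's default conditions —
13,398 girls, 235 instrument SNPs explaining 6.9% of the variance in age at
menarche — and prints the descriptives a data audit would check first.
"""

import numpy as np

from menarchemr import SimParams, generate_cohort

params = SimParams(seed=1)
cohort = generate_cohort(params)

print(f"cohort: {cohort.n} individuals, {cohort.n_snps} SNPs")
print(f"age at menarche (latent): mean {cohort.exposure_latent.mean():.2f}, "
      f"SD {cohort.exposure_latent.std(ddof=1):.2f} years")
print(f"right-censored at the questionnaire: "
      f"{100 * cohort.censored.mean():.2f}%")
y = cohort.outcomes_cont["depression"]
print(f"raw depressive symptoms: mean {y.mean():.2f}, SD {y.std():.2f} "
      "(right-skewed by construction)")
print(f"depression diagnosis prevalence: "
      f"{100 * cohort.outcomes_bin['depression'].mean():.1f}%")
print(f"participation rate: {100 * cohort.participation.mean():.1f}%")

# The printed numbers should sit close to the generator's calibration
# targets (12.69 / 1.18 years, 7.25% censored, scores 9.20 / 6.56, 5.2%
# prevalence); deviations are ordinary sampling noise at this n.
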