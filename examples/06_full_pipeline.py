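"""A configuration-driven end-to-end run.

Generates a cohort, builds the instrument, imputes the censored exposure,
fits every registered model, runs the two-sample battery, decides all 18
hypotheses, and renders the run report.  Sizes are reduced here so the
example finishes in seconds; remove the overrides for a study-scale run.
"""

from pathlib import Path

from menarchemr import report, run_pipeline

config = {
    "seed": 42,
    "simulation": {"n_individuals": 3000, "n_snps": 60},
    "imputation": {"m": 5},
    "mr": {"presso_sims": 300, "median_boot": 300},
}

out = run_pipeline(config, Path("scratch/example_run"))
print(report(out))

# The report lists, per outcome domain, the unadjusted/adjusted
# observational estimates, the one-sample MR and its negative control, the
# two-sample battery, and one verdict per hypothesis.  Re-running with the
# same config reproduces every table bit-for-bit.
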