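"""Pre-registered equivalence testing and the decision engine.

Shows how an estimate is combined with its smallest effect size of interest
(SESOI), one-sided NHST, and a negative-control comparison to yield one of
three verdicts: supported, practically equivalent to 0, or undecided.
"""

from menarchemr import (Estimate, HypothesisSpec, decide, equivalence_test,
                        inferiority_test, negative_control_test,
                        sesoi_to_scale)

spec = HypothesisSpec(id="H3a", direction="negative", sesoi_d=0.25,
                      outcome_scale="beta", requires_negcontrol=True)
bound = sesoi_to_scale(spec.sesoi_d, spec.outcome_scale)
print(f"SESOI D = {spec.sesoi_d} -> bound {bound:.4f} on the "
      "standardised-beta scale")

est = Estimate(theta_hat=-0.07, se=0.035, n=9832, scale="beta",
               exposure_unit="per_sd", direction="negative")
negcontrol = Estimate(theta_hat=-0.03, se=0.046, n=9832, scale="beta",
                      exposure_unit="per_sd", direction="negative")

inf = inferiority_test(est, bound, "negative")
print(f"inferiority test: p = {inf.p:.3f} "
      f"({'inside' if inf.reject else 'not inside'} the equivalence region)")
nc = negative_control_test(est, negcontrol)
print(f"negative control: bound {nc.bound:+.3f}, p = {nc.p:.3f} -> "
      f"{'pass' if nc.passed else 'fail'}")

decision = decide(spec, est, nc)
print(f"verdict for {decision.hypothesis_id}: {decision.verdict} "
      f"(NHST p = {decision.nhst_p:.3f})")

# A tiny, precisely estimated effect flips the verdict:
tiny = Estimate(theta_hat=-0.01, se=0.004, n=9832, scale="beta",
                exposure_unit="per_sd", direction="negative")
print("tiny precise estimate ->",
      decide(spec, tiny, negative_control_test(tiny, negcontrol)).verdict)

# Two-sided hypotheses use the TOST instead:
tost = equivalence_test(tiny, bound)
print(f"TOST on the tiny estimate: p = {tost.p:.2g} (reject = equivalent)")
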