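"""Pre-registered inference: smallest effect sizes of interest, inferiority
and equivalence tests, and the decision engine mapping test results to a
verdict.

Each registered hypothesis carries a smallest effect size of interest
(SESOI) expressed as a Cohen's D, converted to the analysis scale
(standardised beta via d/sqrt(d²+4); log odds ratio via d·pi/sqrt(3)).  A
hypothesis is declared *practically equivalent to 0* whenever the
inferiority/equivalence test rejects an effect at least as large as the
SESOI — irrespective of the null-hypothesis test.  Otherwise it is
*supported* when the NHST rejects 0 in the registered direction (and, where
required, the negative-control comparison passes), and *undecided* when
neither rejection is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

from .estimates import Estimate
from .mr_one_sample import NegControlResult

__all__ = ["HypothesisSpec", "Decision", "TestResult", "sesoi_to_scale",
           "inferiority_test", "equivalence_test", "decide", "HYPOTHESES"]


@dataclass(frozen=True)
class HypothesisSpec:
    """One registered hypothesis and its inference criteria."""

    id: str
    direction: str            # "negative" or "two_sided"
    sesoi_d: float            # Cohen's D
    outcome_scale: str        # "beta" or "log_or"
    requires_negcontrol: bool = False
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.sesoi_d > 0:
            raise ValueError("sesoi_d must be positive")
        if not (0 < self.alpha < 0.5):
            raise ValueError("alpha must be in (0, 0.5)")
        if self.direction not in ("negative", "two_sided"):
            raise ValueError("direction must be 'negative' or 'two_sided'")


@dataclass(frozen=True)
class TestResult:
    p: float
    reject: bool
    z: float


@dataclass(frozen=True)
class Decision:
    """Verdict on one hypothesis with its component test results."""

    hypothesis_id: str
    verdict: str              # supported / practically_equivalent_to_0 / undecided
    nhst_p: float
    equivalence_p: float
    negcontrol_pass: bool | None
    bound: float
    scale: str


def sesoi_to_scale(d: float, scale: str) -> float:
    """Convert a Cohen's D SESOI to the analysis scale.

    beta (standardised outcome, per-SD exposure): d/sqrt(d²+4), the
    correlation implied by D; log-OR: d·pi/sqrt(3), the logistic-variance
    conversion.
    """
    if d < 0:
        raise ValueError("d must be non-negative")
    if scale == "beta":
        return d / math.sqrt(d * d + 4.0)
    if scale == "log_or":
        return d * math.pi / math.sqrt(3.0)
    raise ValueError(f"unknown scale {scale!r}")


def inferiority_test(est: Estimate, bound: float, direction: str,
                     alpha: float = 0.05) -> TestResult:
    """One-sided test of H0: the effect is at least as extreme as the SESOI.

    For a negative-direction hypothesis H0 is theta <= -bound and
    z = (theta_hat + bound)/se; rejection means the effect is demonstrably
    *smaller* than the smallest effect of interest.
    """
    if direction == "negative":
        z = (est.theta_hat - (-bound)) / est.se
    elif direction == "positive":
        z = (bound - est.theta_hat) / est.se
    else:
        raise ValueError("inferiority test needs a one-sided direction")
    p = float(stats.norm.sf(z))
    return TestResult(p=p, reject=p < alpha, z=float(z))


def equivalence_test(est: Estimate, bound: float, alpha: float = 0.05
                     ) -> TestResult:
    """Two one-sided tests (TOST) against +/- bound; p is the larger tail.

    Rejection declares the effect practically equivalent to 0.
    """
    z_low = (est.theta_hat + bound) / est.se     # H0: theta <= -bound
    z_high = (bound - est.theta_hat) / est.se    # H0: theta >= +bound
    p = float(max(stats.norm.sf(z_low), stats.norm.sf(z_high)))
    return TestResult(p=p, reject=p < alpha, z=float(min(z_low, z_high)))


def decide(spec: HypothesisSpec, est: Estimate,
           negcontrol_result: NegControlResult | None = None) -> Decision:
    """Combine NHST, equivalence and negative-control criteria into a verdict.

    Equivalence rejection dominates: the verdict is
    ``practically_equivalent_to_0`` whenever the effect is demonstrably
    smaller than the SESOI, irrespective of the NHST.
    """
    if spec.requires_negcontrol and negcontrol_result is None:
        raise ValueError(f"{spec.id}: negative-control result required "
                         "but absent")
    bound = sesoi_to_scale(spec.sesoi_d, spec.outcome_scale)
    if est.scale != spec.outcome_scale:
        raise ValueError(f"{spec.id}: estimate scale {est.scale!r} does not "
                         f"match hypothesis scale {spec.outcome_scale!r}")
    if spec.direction == "two_sided":
        eq = equivalence_test(est, bound, spec.alpha)
        nhst_p = est.p_two
    else:
        eq = inferiority_test(est, bound, spec.direction, spec.alpha)
        nhst_p = est.p_one
    nc_pass = negcontrol_result.passed if negcontrol_result is not None else None
    if eq.reject:
        verdict = "practically_equivalent_to_0"
    elif nhst_p < spec.alpha and (not spec.requires_negcontrol or nc_pass):
        verdict = "supported"
    else:
        verdict = "undecided"
    return Decision(hypothesis_id=spec.id, verdict=verdict, nhst_p=nhst_p,
                    equivalence_p=eq.p, negcontrol_pass=nc_pass,
                    bound=bound, scale=spec.outcome_scale)


def _mk(id_, direction, d, scale, negcontrol=False):
    return HypothesisSpec(id=id_, direction=direction, sesoi_d=d,
                          outcome_scale=scale,
                          requires_negcontrol=negcontrol)


#: The registered hypothesis family: depression (one-tailed, negative),
#: other mental-health domains (two-tailed), observational (H1/H2) and
#: MR (H3/H4) branches, symptoms (a, beta scale) and diagnoses (b, log-OR).
HYPOTHESES: tuple[HypothesisSpec, ...] = (
    _mk("H1a", "negative", 0.23, "beta"),
    _mk("H1b", "negative", 0.23, "log_or"),
    _mk("H2.1a", "two_sided", 0.22, "beta"),
    _mk("H2.2a", "two_sided", 0.22, "beta"),
    _mk("H2.3a", "two_sided", 0.22, "beta"),
    _mk("H2.4a", "two_sided", 0.22, "beta"),
    _mk("H2.1b", "two_sided", 0.22, "log_or"),
    _mk("H2.2b", "two_sided", 0.22, "log_or"),
    _mk("H2.3b", "two_sided", 0.22, "log_or"),
    _mk("H3a", "negative", 0.25, "beta", negcontrol=True),
    _mk("H3b", "negative", 0.25, "log_or"),
    _mk("H4.1a", "two_sided", 0.20, "beta", negcontrol=True),
    _mk("H4.2a", "two_sided", 0.20, "beta", negcontrol=True),
    _mk("H4.3a", "two_sided", 0.20, "beta", negcontrol=True),
    _mk("H4.4a", "two_sided", 0.20, "beta", negcontrol=True),
    _mk("H4.1b", "two_sided", 0.20, "log_or"),
    _mk("H4.2b", "two_sided", 0.20, "log_or"),
    _mk("H4.3b", "two_sided", 0.20, "log_or"),
)
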