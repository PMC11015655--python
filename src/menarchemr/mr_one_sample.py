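"""One-sample Mendelian randomisation: two-stage least squares, a logistic
second stage for diagnoses, the negative-control comparison, and the
arithmetic for translating standardised estimates to per-year and
absolute-risk terms.

In 2SLS the exposure is first regressed on the instrument(s); the outcome is
then regressed on the first-stage fitted values ("genetically predicted"
exposure).  Standard errors use the proper 2SLS residual — the outcome minus
the *original* exposure times the estimate, not the fitted exposure — with a
heteroskedasticity-robust (HC1) sandwich.  No covariates enter the MR models;
confounding control is delegated to the instrument itself.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .estimates import Estimate

__all__ = ["tsls", "tsls_logistic", "first_stage_f", "negative_control_test",
           "NegControlResult", "rescale_per_year", "absolute_risk_shift",
           "odds_increase_per_earlier_year"]


def _design(instrument: np.ndarray) -> np.ndarray:
    Z = np.asarray(instrument, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    return np.column_stack([np.ones(Z.shape[0]), Z])


def first_stage_f(x: np.ndarray, instrument: np.ndarray) -> float:
    """F statistic of the instrument-on-exposure first stage."""
    x = np.asarray(x, dtype=float)
    Z = _design(instrument)
    mask = ~(np.isnan(x) | np.isnan(Z).any(axis=1))
    x, Z = x[mask], Z[mask]
    k = Z.shape[1] - 1
    coef, *_ = np.linalg.lstsq(Z, x, rcond=None)
    fitted = Z @ coef
    rss = float(np.sum((x - fitted) ** 2))
    tss = float(np.sum((x - x.mean()) ** 2))
    r2 = 1.0 - rss / tss
    n = x.shape[0]
    return (r2 / k) / ((1.0 - r2) / (n - k - 1))


def _complete(y, x, instrument):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    Z = _design(instrument)
    mask = ~(np.isnan(y) | np.isnan(x) | np.isnan(Z).any(axis=1))
    return y[mask], x[mask], Z[mask]


def tsls(y, x, instrument, robust: bool = True,
         direction: str = "negative", exposure_unit: str = "per_year",
         scale_label: str = "beta") -> Estimate:
    """Two-stage least squares estimate of the causal effect of x on y.

    With a single instrument this reduces exactly to the Wald ratio of the
    reduced-form to the first-stage coefficient.
    """
    y, x, Z = _complete(y, x, instrument)
    if np.ptp(Z[:, 1:], axis=0).min() == 0:
        raise ValueError("instrument column with zero variance")
    f = first_stage_f(x, Z[:, 1:])
    if f < 10:
        warnings.warn(f"weak instrument: first-stage F = {f:.2f} < 10",
                      UserWarning, stacklevel=2)
    coef1, *_ = np.linalg.lstsq(Z, x, rcond=None)
    xhat = Z @ coef1
    X2 = np.column_stack([np.ones_like(xhat), xhat])
    beta2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    # 2SLS residual uses the ORIGINAL exposure
    u = y - np.column_stack([np.ones_like(x), x]) @ beta2
    n, k = X2.shape
    bread = np.linalg.inv(X2.T @ X2)
    if robust:
        meat = X2.T @ (X2 * (u ** 2)[:, None])
        cov = bread @ meat @ bread * n / (n - k)
    else:
        cov = bread * float(u @ u) / (n - k)
    se = math.sqrt(cov[1, 1])
    return Estimate(theta_hat=float(beta2[1]), se=se, n=n,
                    scale=scale_label, exposure_unit=exposure_unit,
                    direction=direction)


def tsls_logistic(case, x, instrument, direction: str = "negative",
                  exposure_unit: str = "per_year",
                  method: str = "substitution") -> Estimate:
    """Two-stage instrumental-variable estimate with a logistic second stage.

    Default is two-stage predictor substitution: logistic regression of the
    case indicator on the first-stage fitted exposure, with HC1 standard
    errors.  ``method="residual_inclusion"`` instead keeps the observed
    exposure and adds the first-stage residual as a control function.
    """
    y, x, Z = _complete(case, x, instrument)
    if np.unique(y).size < 2:
        raise ValueError("both outcome classes must be present")
    coef1, *_ = np.linalg.lstsq(Z, x, rcond=None)
    xhat = Z @ coef1
    if method == "substitution":
        X2 = np.column_stack([np.ones_like(xhat), xhat])
    elif method == "residual_inclusion":
        X2 = np.column_stack([np.ones_like(xhat), x, x - xhat])
    else:
        raise ValueError(f"unknown method {method!r}")
    try:
        fit = sm.Logit(y, X2).fit(disp=0, maxiter=100, cov_type="HC1")
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"logistic second stage failed: {exc}")
    if not np.all(np.isfinite(fit.bse)) or fit.bse[1] > 1e3:
        raise ValueError("separation detected in the logistic second stage")
    return Estimate(theta_hat=float(fit.params[1]), se=float(fit.bse[1]),
                    n=int(y.shape[0]), scale="log_or",
                    exposure_unit=exposure_unit, direction=direction)


@dataclass(frozen=True)
class NegControlResult:
    """Outcome of the negative-control consistency test."""

    passed: bool
    p: float
    z: float
    bound: float


def negative_control_test(est_main: Estimate, est_negcontrol: Estimate,
                          alpha: float = 0.05,
                          direction: str | None = None,
                          bound: str = "farthest") -> NegControlResult:
    """Is the main estimate consistent with an effect at least as extreme as
    the negative-control confidence bound?

    ``L`` is the negative-control CI bound farthest from 0 in the registered
    direction (``bound="upper"`` instead always uses the upper CI bound, an
    alternative reading of the registered criterion).  ``z`` is signed so
    positive means the main estimate is *less* extreme than ``L``;
    ``p = 1 - Phi(z)``.  The criterion passes when ``p >= alpha`` — we fail
    to reject that the main effect is at least as extreme as the negative
    control allows.
    """
    if est_main.scale != est_negcontrol.scale:
        raise ValueError("estimates must share a scale")
    if bound not in ("farthest", "upper"):
        raise ValueError("bound must be 'farthest' or 'upper'")
    direction = direction or est_main.direction
    if direction == "two_sided":
        # fall back to the side of the main point estimate
        direction = "negative" if est_main.theta_hat < 0 else "positive"
    if direction == "negative":
        L = est_negcontrol.ci_low if bound == "farthest" \
            else est_negcontrol.ci_high
        z = (est_main.theta_hat - L) / est_main.se
    else:
        L = est_negcontrol.ci_high
        z = (L - est_main.theta_hat) / est_main.se
    p = float(stats.norm.sf(z))
    return NegControlResult(passed=p >= alpha, p=p, z=float(z), bound=float(L))


def rescale_per_year(est: Estimate, sd_exposure: float) -> Estimate:
    """Convert a per-SD-of-exposure estimate to per-year (or back).

    On the beta scale the estimate and SE are divided by the exposure SD; on
    the log-OR scale this is the exponent 1/sd on the odds ratio.  Calling
    twice with sd and 1/sd restores the original estimate.
    """
    if sd_exposure <= 0:
        raise ValueError("sd_exposure must be positive")
    new_unit = "per_year" if est.exposure_unit == "per_sd" else "per_sd"
    return est.with_(theta_hat=est.theta_hat / sd_exposure,
                     se=est.se / sd_exposure, exposure_unit=new_unit)


def odds_increase_per_earlier_year(or_per_year: float) -> float:
    """Percent increase in the odds per *earlier* year, for a protective
    per-year odds ratio: (1/OR - 1) * 100."""
    if or_per_year <= 0:
        raise ValueError("odds ratio must be positive")
    return (1.0 / or_per_year - 1.0) * 100.0


def absolute_risk_shift(baseline_risk: float, or_per_year: float) -> float:
    """Absolute risk after applying an odds ratio to a baseline risk."""
    if not (0 < baseline_risk < 1):
        raise ValueError("baseline risk must be in (0, 1)")
    if or_per_year <= 0:
        raise ValueError("odds ratio must be positive")
    odds = or_per_year * baseline_risk / (1.0 - baseline_risk)
    return odds / (1.0 + odds)
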