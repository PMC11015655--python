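"""Summary-data (two-sample) Mendelian randomisation estimators.

Given aligned per-SNP associations with the exposure (beta_X, years per
allele) and the outcome (beta_Y, SD units per allele), each SNP provides a
Wald ratio beta_Y / beta_X estimating the causal effect.  The battery here
combines them under progressively weaker assumptions about horizontal
pleiotropy:

* **IVW** — inverse-variance-weighted mean of the ratios (all instruments
  valid, or balanced pleiotropy), with Cochran's Q heterogeneity statistic
  and multiplicative random-effects SE inflation when Q/df > 1;
* **MR-Egger** — weighted regression of beta_Y on beta_X with an intercept;
  the intercept estimates directional pleiotropy, the slope the causal
  effect (InSIDE assumption);
* **weighted median** — consistent when at most half the weight comes from
  invalid instruments;
* **contamination mixture** — profile likelihood treating each SNP as drawn
  from a valid component N(theta, se²) or an invalid component N(0, psi²);
* **MR-PRESSO** — a resampling global test for outlying (pleiotropic) SNPs
  based on leave-one-out residual sums of squares;
* **MVMR** — multivariable MR regressing beta_Y on several exposures' betas
  jointly, with conditional instrument-strength F statistics and a modified
  Q for residual heterogeneity.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimates import Estimate
from .synthetic import SummaryPair

__all__ = ["MRResult", "wald_ratios", "ivw", "mr_egger", "weighted_median",
           "contamination_mixture", "mr_presso", "mvmr"]

log = logging.getLogger(__name__)


@dataclass
class MRResult:
    """A method-tagged causal estimate with its diagnostics."""

    method: str
    estimate: Estimate
    n_snps: int
    q_stat: dict | None = None            # {"Q", "df", "p"}
    per_snp_q: np.ndarray | None = None
    egger_intercept: Estimate | None = None
    outliers: list[str] = field(default_factory=list)
    global_p: float | None = None          # PRESSO global test
    conditional_f: dict | None = None      # MVMR, per exposure
    modified_q: dict | None = None         # MVMR residual heterogeneity
    estimates: dict | None = None          # MVMR, per exposure

    def __post_init__(self) -> None:
        if self.q_stat is not None and self.q_stat["Q"] < 0:
            raise ValueError("Q statistic must be non-negative")


def wald_ratios(pair: SummaryPair, second_order: bool = False
                ) -> pd.DataFrame:
    """Per-SNP Wald ratio estimates beta_Y / beta_X with delta-method SEs.

    First-order SE is se_Y / |beta_X|; ``second_order`` adds the
    exposure-uncertainty term.  SNPs with beta_X == 0 are dropped and logged.
    """
    bx = pair.exposure_stats["beta"].to_numpy(dtype=float)
    by = pair.outcome_stats["beta"].to_numpy(dtype=float)
    sx = pair.exposure_stats["se"].to_numpy(dtype=float)
    sy = pair.outcome_stats["se"].to_numpy(dtype=float)
    keep = bx != 0
    if not keep.all():
        log.info("dropping %d SNPs with zero exposure beta",
                 int((~keep).sum()))
    bx, by, sx, sy = bx[keep], by[keep], sx[keep], sy[keep]
    ratio = by / bx
    se = sy / np.abs(bx)
    if second_order:
        se = np.sqrt(sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4)
    return pd.DataFrame({"snp": pair.exposure_stats["snp"].to_numpy()[keep],
                         "ratio": ratio, "se": se})


def _ratio_arrays(ratios) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(ratios, pd.DataFrame):
        return (ratios["snp"].to_numpy(), ratios["ratio"].to_numpy(dtype=float),
                ratios["se"].to_numpy(dtype=float))
    r, s = ratios
    r = np.asarray(r, dtype=float)
    return np.arange(len(r)).astype(str), r, np.asarray(s, dtype=float)


def ivw(ratios, random_effects: str = "multiplicative",
        direction: str = "negative", exposure_unit: str = "per_year"
        ) -> MRResult:
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    Fixed-effect weighted mean with weights 1/se²; Cochran's Q on J-1 df.
    With ``random_effects="multiplicative"`` the SE is inflated by
    sqrt(Q/df) when Q/df > 1 (never deflated); ``"fixed"`` disables this.
    """
    snps, r, se = _ratio_arrays(ratios)
    J = r.shape[0]
    if J < 2:
        raise ValueError("IVW needs at least 2 ratios; use the Wald ratio "
                         "directly for a single SNP")
    w = 1.0 / se ** 2
    est = float(np.sum(w * r) / np.sum(w))
    se_fixed = math.sqrt(1.0 / float(np.sum(w)))
    per_snp_q = w * (r - est) ** 2
    Q = float(per_snp_q.sum())
    df = J - 1
    q_p = float(stats.chi2.sf(Q, df))
    se_out = se_fixed
    if random_effects == "multiplicative" and Q / df > 1:
        se_out = se_fixed * math.sqrt(Q / df)
    elif random_effects not in ("multiplicative", "fixed"):
        raise ValueError(f"unknown random_effects {random_effects!r}")
    estimate = Estimate(theta_hat=est, se=se_out, n=J, scale="beta",
                        exposure_unit=exposure_unit, direction=direction)
    return MRResult(method="ivw", estimate=estimate, n_snps=J,
                    q_stat={"Q": Q, "df": df, "p": q_p},
                    per_snp_q=per_snp_q)


def _oriented(pair: SummaryPair):
    """Flip SNPs so all exposure betas are positive (slope-invariant)."""
    bx = pair.exposure_stats["beta"].to_numpy(dtype=float).copy()
    by = pair.outcome_stats["beta"].to_numpy(dtype=float).copy()
    sx = pair.exposure_stats["se"].to_numpy(dtype=float)
    sy = pair.outcome_stats["se"].to_numpy(dtype=float)
    flip = bx < 0
    bx[flip] *= -1
    by[flip] *= -1
    return bx, by, sx, sy


def mr_egger(pair: SummaryPair, level: float = 0.95,
             direction: str = "negative", exposure_unit: str = "per_year"
             ) -> MRResult:
    """MR-Egger regression: weighted fit of beta_Y on beta_X with intercept.

    Exposure betas are oriented positive first.  Weights are 1/se_Y²; the
    covariance uses a multiplicative overdispersion floor of 1 and a t
    reference with J-2 df.  The intercept is the directional-pleiotropy
    test; the slope is the causal estimate.
    """
    J = pair.n_snps
    if J < 3:
        raise ValueError("MR-Egger needs at least 3 SNPs")
    bx, by, _, sy = _oriented(pair)
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(J), bx])
    WX = X * w[:, None]
    XtWX = X.T @ WX
    coef = np.linalg.solve(XtWX, WX.T @ by)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid ** 2))
    disp = max(1.0, rss_w / (J - 2))
    cov = np.linalg.inv(XtWX) * disp
    slope = Estimate(theta_hat=float(coef[1]), se=math.sqrt(cov[1, 1]),
                     n=J, scale="beta", exposure_unit=exposure_unit,
                     direction=direction, level=level, df=J - 2)
    intercept = Estimate(theta_hat=float(coef[0]), se=math.sqrt(cov[0, 0]),
                         n=J, scale="beta", exposure_unit=exposure_unit,
                         direction="two_sided", level=level, df=J - 2)
    return MRResult(method="mr_egger", estimate=slope, n_snps=J,
                    q_stat={"Q": rss_w, "df": J - 2,
                            "p": float(stats.chi2.sf(rss_w, J - 2))},
                    egger_intercept=intercept)


def weighted_median(ratios, n_boot: int = 1000, seed: int | None = None,
                    direction: str = "negative",
                    exposure_unit: str = "per_year") -> MRResult:
    """Weighted median of the Wald-ratio distribution.

    The estimate is the ratio at the 50% point of the cumulative
    inverse-variance weight, linearly interpolated; the SE comes from a
    seeded parametric bootstrap (ratios resampled from N(ratio_j, se_j²)).
    Consistent when valid instruments carry more than half the weight.
    """
    snps, r, se = _ratio_arrays(ratios)
    J = r.shape[0]
    if J < 3:
        raise ValueError("weighted median needs at least 3 ratios")
    w = 1.0 / se ** 2

    def wmedian(rv: np.ndarray) -> float:
        order = np.argsort(rv)
        rs, ws = rv[order], w[order]
        ws = ws / ws.sum()
        p = np.cumsum(ws) - ws / 2.0
        return float(np.interp(0.5, p, rs))

    est = wmedian(r)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        boot[b] = wmedian(r + rng.normal(size=J) * se)
    se_boot = float(boot.std(ddof=1))
    estimate = Estimate(theta_hat=est, se=max(se_boot, 1e-300), n=J,
                        scale="beta", exposure_unit=exposure_unit,
                        direction=direction)
    return MRResult(method="weighted_median", estimate=estimate, n_snps=J)


def contamination_mixture(ratios, psi: float | None = None,
                          n_grid: int = 2001, grid: np.ndarray | None = None,
                          direction: str = "negative",
                          exposure_unit: str = "per_year") -> MRResult:
    """Contamination-mixture estimator by profile likelihood over theta.

    Each SNP contributes the larger of a valid log-density N(theta, se_j²)
    and an invalid log-density N(0, psi²).  The estimate is the grid argmax;
    the 95% CI is the set where twice the log-likelihood drop is <= 3.84.
    ``psi`` defaults to 1.5 x the SD of the ratios.
    """
    snps, r, se = _ratio_arrays(ratios)
    J = r.shape[0]
    if J < 3:
        raise ValueError("contamination mixture needs at least 3 ratios")
    if psi is None:
        psi = 1.5 * float(np.std(r, ddof=1))
    if psi <= 0:
        raise ValueError("psi must be positive")
    if grid is None:
        # span the bulk of the ratio distribution, not the noisiest tails,
        # so the grid resolves the likelihood peak
        pad = 3.0 * float(np.median(se))
        lo = float(np.quantile(r, 0.02)) - pad
        hi = float(np.quantile(r, 0.98)) + pad
        grid = np.linspace(min(lo, 0.0), max(hi, 0.0), n_grid)
    grid = np.asarray(grid, dtype=float)
    if grid.size < 3 or np.ptp(grid) == 0:
        raise ValueError("degenerate theta grid")
    invalid_ll = stats.norm.logpdf(r, loc=0.0, scale=psi)          # (J,)
    valid_ll = stats.norm.logpdf(r[None, :], loc=grid[:, None],
                                 scale=se[None, :])                # (G, J)
    ll = np.maximum(valid_ll, invalid_ll[None, :]).sum(axis=1)
    best = int(np.argmax(ll))
    inside = 2.0 * (ll[best] - ll) <= stats.chi2.ppf(0.95, 1)
    ci_low = float(grid[inside].min())
    ci_high = float(grid[inside].max())
    est = float(grid[best])
    se_eff = max((ci_high - ci_low) / (2 * stats.norm.ppf(0.975)), 1e-300)
    estimate = Estimate(theta_hat=est, se=se_eff, n=J, scale="beta",
                        exposure_unit=exposure_unit, direction=direction)
    # report the profile-likelihood CI verbatim (can be asymmetric)
    estimate.ci_low, estimate.ci_high = ci_low, ci_high
    return MRResult(method="contamination_mixture", estimate=estimate,
                    n_snps=J)


def _loo_ivw(by: np.ndarray, bx: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slope for each SNP, vectorised.

    The IVW slope on ratios equals the weighted no-intercept regression of
    beta_Y on beta_X with weights 1/se_Y² expressed per ratio; here we work
    directly on the ratio scale.
    """
    r = by / bx
    sw, swr = float(np.sum(w)), float(np.sum(w * r))
    return (swr - w * r) / (sw - w)


def mr_presso(pair: SummaryPair, n_sim: int = 1000, seed: int | None = None,
              outlier_alpha: float = 0.05, direction: str = "negative",
              exposure_unit: str = "per_year") -> MRResult:
    """MR-PRESSO style global pleiotropy test and outlier search.

    The observed global statistic is the weighted sum of squared residuals
    of each SNP from the IVW fit that leaves it out.  The null distribution
    is built by parametric resampling of the outcome betas around their
    leave-one-out predictions.  Per-SNP outlier p-values are the analogous
    componentwise exceedance fractions, Bonferroni-flagged.  The reported
    estimate is the IVW recomputed after removing flagged outliers.
    """
    J = pair.n_snps
    if J < 4:
        raise ValueError("MR-PRESSO needs at least 4 SNPs")
    if n_sim < 100:
        warnings.warn("n_sim < 100 gives a coarse null distribution",
                      UserWarning, stacklevel=2)
    bx, by, _, sy = _oriented(pair)
    r = by / bx
    se_r = sy / np.abs(bx)
    w = 1.0 / se_r ** 2
    loo = _loo_ivw(by, bx, w)
    obs_comp = w * (r - loo) ** 2
    rss_obs = float(obs_comp.sum())

    rng = np.random.default_rng(seed)
    sim_rss = np.empty(n_sim)
    exceed = np.zeros(J)
    for s in range(n_sim):
        r_sim = loo + rng.normal(size=J) * se_r
        sw, swr = float(np.sum(w)), float(np.sum(w * r_sim))
        loo_sim = (swr - w * r_sim) / (sw - w)
        comp = w * (r_sim - loo_sim) ** 2
        sim_rss[s] = comp.sum()
        exceed += comp >= obs_comp
    global_p = float((1 + np.sum(sim_rss >= rss_obs)) / (n_sim + 1))
    snp_p = (1 + exceed) / (n_sim + 1)
    flagged = snp_p < outlier_alpha / J
    outliers = list(pair.exposure_stats["snp"].to_numpy()[flagged])
    keep = ~flagged
    sub = pd.DataFrame({"snp": pair.exposure_stats["snp"].to_numpy()[keep],
                        "ratio": r[keep], "se": se_r[keep]})
    base = ivw(sub, direction=direction, exposure_unit=exposure_unit)
    return MRResult(method="mr_presso", estimate=base.estimate, n_snps=J,
                    q_stat=base.q_stat, outliers=outliers, global_p=global_p)


def mvmr(exposure_betas: pd.DataFrame, exposure_ses: pd.DataFrame,
         outcome_beta: np.ndarray, outcome_se: np.ndarray,
         direction: str = "negative", exposure_unit: str = "per_year"
         ) -> MRResult:
    """Multivariable MR: joint direct effects of K exposures.

    Weighted no-intercept regression of the outcome betas on the K columns
    of exposure betas (weights 1/se_Y²).  Conditional instrument strength
    for exposure k is the heterogeneity statistic of regressing its betas on
    the other exposures' betas (weighted by 1/se_Xk²), divided by (J - K).
    Residual heterogeneity is the modified Q on J - K df.  All-zero exposure
    columns are dropped with a warning; genuinely collinear columns raise.
    """
    B = exposure_betas.to_numpy(dtype=float)
    S = exposure_ses.to_numpy(dtype=float)
    names = list(exposure_betas.columns)
    by = np.asarray(outcome_beta, dtype=float)
    sy = np.asarray(outcome_se, dtype=float)
    zero = np.all(B == 0, axis=0)
    if zero.any():
        dropped = [n for n, z in zip(names, zero) if z]
        warnings.warn(f"dropping all-zero exposure column(s): {dropped}",
                      UserWarning, stacklevel=2)
        B, S = B[:, ~zero], S[:, ~zero]
        names = [n for n, z in zip(names, zero) if not z]
    J, K = B.shape
    if J <= K + 1:
        raise ValueError("need more SNPs than exposures plus one")
    if np.linalg.matrix_rank(B) < K:
        raise ValueError("collinear exposure-beta columns")
    w = 1.0 / sy ** 2
    WB = B * w[:, None]
    BtWB = B.T @ WB
    theta = np.linalg.solve(BtWB, WB.T @ by)
    resid = by - B @ theta
    mod_q = float(np.sum(w * resid ** 2))
    df_q = J - K
    disp = max(1.0, mod_q / df_q)
    cov = np.linalg.inv(BtWB) * disp

    cond_f = {}
    for k in range(K):
        wk = 1.0 / S[:, k] ** 2
        if K == 1:
            fitted = np.zeros(J)
            q_k = float(np.sum(wk * (B[:, k] - fitted) ** 2))
            cond_f[names[k]] = q_k / J
            continue
        others = np.delete(B, k, axis=1)
        A = others * wk[:, None]
        coefs = np.linalg.solve(others.T @ A, A.T @ B[:, k])
        fitted = others @ coefs
        q_k = float(np.sum(wk * (B[:, k] - fitted) ** 2))
        cond_f[names[k]] = q_k / (J - K)

    estimates = {
        names[k]: Estimate(theta_hat=float(theta[k]),
                           se=math.sqrt(cov[k, k]), n=J, scale="beta",
                           exposure_unit=exposure_unit, direction=direction)
        for k in range(K)}
    return MRResult(method="mvmr", estimate=estimates[names[0]], n_snps=J,
                    conditional_f=cond_f,
                    modified_q={"Q": mod_q, "df": df_q,
                                "p": float(stats.chi2.sf(mod_q, df_q))},
                    estimates=estimates)
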