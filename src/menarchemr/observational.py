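"""Observational regression models with outcome transformation.

Raw symptom scores are non-negative and right-skewed; before modelling, each
outcome is passed through whichever of identity / log(y+1) / sqrt(y) best
symmetrises it, then z-standardised so regression betas are in SD units.
Continuous outcomes get (weighted) least squares, diagnoses get logistic
regression; when inverse-probability weights are supplied the covariance is
heteroskedasticity-robust with the small-sample n/(n-k) (HC1) scale.
Continuous covariate values more than 3 SD from the mean are set missing
before fitting.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .estimates import Estimate

__all__ = ["select_transform", "standardize", "fit_linear", "fit_logistic"]

log = logging.getLogger(__name__)


def select_transform(y: np.ndarray) -> tuple[np.ndarray, str]:
    """Pick the transformation that minimises |skewness|.

    Candidates are identity, log(y+1) and sqrt(y); ties break on
    |kurtosis - 3|.  Returns (transformed values, label).
    """
    y = np.asarray(y, dtype=float)
    if (y < 0).any():
        raise ValueError("scores must be non-negative")
    if np.ptp(y[~np.isnan(y)]) == 0:
        warnings.warn("constant outcome; identity transform used",
                      UserWarning, stacklevel=2)
        return y, "identity"
    candidates = {"identity": y, "log": np.log1p(y), "sqrt": np.sqrt(y)}
    scores = {}
    for label, t in candidates.items():
        t_obs = t[~np.isnan(t)]
        scores[label] = (abs(stats.skew(t_obs)),
                         abs(stats.kurtosis(t_obs, fisher=False) - 3.0))
    best = min(scores, key=lambda k: scores[k])
    return candidates[best], best


def standardize(y: np.ndarray) -> np.ndarray:
    """z-scores with the sample (ddof=1) SD convention."""
    y = np.asarray(y, dtype=float)
    obs = y[~np.isnan(y)]
    sd = obs.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a zero-variance vector")
    return (y - obs.mean()) / sd


def _mask_outliers(covars: pd.DataFrame | None, threshold: float = 3.0
                   ) -> pd.DataFrame | None:
    """Set continuous covariate values beyond `threshold` SDs to missing."""
    if covars is None:
        return None
    out = covars.copy()
    for name in out.columns:
        col = out[name].to_numpy(dtype=float)
        uniq = np.unique(col[~np.isnan(col)])
        if uniq.size <= 2:
            continue  # binary / categorical indicator: leave alone
        mu, sd = np.nanmean(col), np.nanstd(col, ddof=1)
        if sd == 0:
            continue
        flag = np.abs(col - mu) > threshold * sd
        if flag.any():
            col = col.copy()
            col[flag] = np.nan
            out[name] = col
    return out


def _assemble(y, x, covars, weights, outlier_sd=3.0):
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if outlier_sd is not None:
        covars = _mask_outliers(covars, outlier_sd)
    parts = {"exposure": x}
    names = ["exposure"]
    if covars is not None:
        for name in covars.columns:
            parts[name] = covars[name].to_numpy(dtype=float)
            names.append(name)
    X = pd.DataFrame(parts)
    mask = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        mask &= ~np.isnan(w)
        w = w[mask]
    X = X.loc[mask]
    # drop collinear covariate columns (keep the exposure always)
    keep = ["exposure"]
    rank = np.linalg.matrix_rank(
        np.column_stack([np.ones(mask.sum()), X["exposure"]]))
    for name in names[1:]:
        trial = np.column_stack([np.ones(mask.sum()),
                                 X[keep + [name]].to_numpy()])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            keep.append(name)
            rank = r
        else:
            warnings.warn(f"dropping collinear covariate {name!r}",
                          UserWarning, stacklevel=3)
    return y[mask], sm.add_constant(X[keep]), w, tuple(keep[1:])


def fit_linear(y, x, covars: pd.DataFrame | None = None,
               weights: np.ndarray | None = None,
               direction: str = "negative", robust: bool | None = None,
               scale_label: str = "beta", exposure_unit: str = "per_sd",
               outlier_sd: float | None = 3.0) -> Estimate:
    """(Weighted) least-squares regression of y on the exposure and covariates.

    Returns the exposure coefficient as an :class:`Estimate`.  With weights
    (or ``robust=True``) the covariance is HC1.  ``outlier_sd=None`` disables
    the continuous-covariate outlier rule.
    """
    yv, X, w, adjusted = _assemble(y, x, covars, weights, outlier_sd)
    if yv.shape[0] < X.shape[1] + 1:
        raise ValueError("too few complete rows for the design")
    use_robust = robust if robust is not None else (w is not None)
    cov_kw = {"cov_type": "HC1"} if use_robust else {}
    model = sm.WLS(yv, X, weights=w) if w is not None else sm.OLS(yv, X)
    fit = model.fit(**cov_kw)
    se = float(fit.bse["exposure"])
    se = max(se, 1e-300)
    return Estimate(theta_hat=float(fit.params["exposure"]), se=se,
                    n=int(yv.shape[0]), scale=scale_label,
                    exposure_unit=exposure_unit, direction=direction,
                    adjusted_for=adjusted)


def fit_logistic(case, x, covars: pd.DataFrame | None = None,
                 weights: np.ndarray | None = None,
                 direction: str = "negative", exposure_unit: str = "per_sd"
                 ) -> Estimate:
    """Logistic regression of a case indicator on the exposure and covariates.

    Returns the log odds ratio per unit exposure.  With weights the model is
    fit by weighted maximum likelihood with a robust (HC1) covariance.
    """
    case = np.asarray(case, dtype=float)
    yv, X, w, adjusted = _assemble(case, x, covars, weights)
    classes = np.unique(yv)
    if classes.size < 2:
        raise ValueError("both outcome classes must be present")
    try:
        if w is not None:
            model = sm.GLM(yv, X, family=sm.families.Binomial(),
                           freq_weights=w)
            fit = model.fit(cov_type="HC1")
        else:
            fit = sm.Logit(yv, X).fit(disp=0, maxiter=100)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise ValueError(f"logistic fit failed (possible separation): {exc}")
    params = fit.params
    if not np.all(np.isfinite(fit.bse)) or float(fit.bse["exposure"]) > 1e3:
        raise ValueError("separation detected: exposure coefficient "
                         "unidentified")
    return Estimate(theta_hat=float(params["exposure"]),
                    se=float(fit.bse["exposure"]), n=int(yv.shape[0]),
                    scale="log_or", exposure_unit=exposure_unit,
                    direction=direction, adjusted_for=adjusted)
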