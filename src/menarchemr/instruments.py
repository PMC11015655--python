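"""Construction and auditing of the genetic instrument.

The instrument for the exposure is a weighted allele score: genome-wide
significant SNPs are clumped for independence, each individual's effect-allele
dosages are multiplied by the published per-SNP weights, summed and divided by
the number of SNPs.  Genotyping batch and ancestry principal components are
regressed out of the score before use.  Relevance is audited by the variance
explained (R²) and the first-stage F statistic, and directionality is guarded
by Steiger filtering: SNPs explaining more variance in the outcome than in
the exposure are removed.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SummaryPair

__all__ = ["GwasSummaryRow", "InstrumentSet", "clump", "compute_grs",
           "residualize", "instrument_audit", "steiger_filter"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GwasSummaryRow:
    """One SNP's association with a trait, as printed in a summary table."""

    snp: str
    chrom: int
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError("se must be positive")
        if not (0 < self.pval <= 1):
            raise ValueError("pval must be in (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError("eaf must be in (0, 1) when present")


@dataclass
class InstrumentSet:
    """A built instrument: the SNP weights, the per-individual score, and
    its relevance diagnostics."""

    rows: pd.DataFrame
    score: np.ndarray
    r2_exposure: float
    f_stat: float

    def __post_init__(self) -> None:
        if (self.rows["se"] <= 0).any():
            raise ValueError("all SEs must be positive")
        if not (0 <= self.r2_exposure <= 1):
            raise ValueError("r2_exposure must be in [0, 1]")
        if np.isnan(self.score).any():
            raise ValueError("score must have no missing values")


def clump(rows: pd.DataFrame, ld: pd.DataFrame,
          r2_threshold: float = 0.001, window_kb: float = 10_000
          ) -> pd.DataFrame:
    """Greedy LD clumping by ascending p-value.

    ``ld`` is a square SNP x SNP matrix of squared correlations (unit
    diagonal, symmetric), indexed by SNP id.  A candidate SNP is retained
    only if its LD r² with every already-retained SNP within ``window_kb``
    on the same chromosome is below ``r2_threshold``.  Ties on p-value break
    by (chrom, pos) so the result is deterministic.  SNPs absent from the
    LD matrix are treated as independent and logged.
    """
    if not ld.index.equals(ld.columns):
        raise ValueError("ld matrix must have identical row/column index")
    mat = ld.to_numpy()
    if not np.allclose(mat, mat.T):
        raise ValueError("ld matrix must be symmetric")
    if not np.allclose(np.diag(mat), 1.0):
        raise ValueError("ld matrix must have unit diagonal")

    ordered = rows.sort_values(["pval", "chrom", "pos"], kind="mergesort")
    window_bp = window_kb * 1_000
    kept: list[int] = []
    for idx, row in ordered.iterrows():
        ok = True
        in_panel = row["snp"] in ld.index
        if not in_panel:
            log.info("SNP %s missing from LD panel; treated as independent",
                     row["snp"])
        for kidx in kept:
            other = rows.loc[kidx]
            if other["chrom"] != row["chrom"]:
                continue
            if abs(other["pos"] - row["pos"]) > window_bp:
                continue
            if not in_panel or other["snp"] not in ld.index:
                continue
            if ld.loc[row["snp"], other["snp"]] >= r2_threshold:
                ok = False
                break
        if ok:
            kept.append(idx)
    return rows.loc[kept]


def compute_grs(dosages: np.ndarray, weights: np.ndarray,
                eaf: np.ndarray | None = None,
                mean_impute: bool = False) -> np.ndarray:
    """Weighted allele score: score_i = sum_j d_ij * w_j / J.

    Dosages must lie in [0, 2].  Missing dosages are an error unless
    ``mean_impute`` is set, in which case 2*eaf is substituted (and logged).
    """
    dosages = np.asarray(dosages, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if dosages.ndim != 2 or dosages.shape[1] != weights.shape[0]:
        raise ValueError("dosage column count must equal weight count")
    finite = dosages[~np.isnan(dosages)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise ValueError("dosages must lie in [0, 2]")
    n_missing = int(np.isnan(dosages).sum())
    if n_missing:
        if not mean_impute:
            raise ValueError(
                f"{n_missing} missing dosages; set mean_impute=True to "
                "substitute 2*eaf")
        if eaf is None:
            raise ValueError("mean_impute requires eaf")
        log.info("mean-imputing %d missing dosages with 2*eaf", n_missing)
        fill = np.broadcast_to(2.0 * np.asarray(eaf, dtype=float),
                               dosages.shape)
        dosages = np.where(np.isnan(dosages), fill, dosages)
    return dosages @ weights / weights.shape[0]


def residualize(score: np.ndarray, nuisance: np.ndarray | pd.DataFrame
                ) -> np.ndarray:
    """Regress nuisance structure (batch, principal components) out of the
    score; the result is centred and orthogonal to every retained column.

    Constant columns are absorbed by the intercept; collinear columns are
    dropped with a warning.
    """
    score = np.asarray(score, dtype=float)
    X = np.asarray(nuisance, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = score.shape[0]
    design = [np.ones(n)]
    rank = 1
    dropped = 0
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.ptp(col) == 0:
            continue  # constant: absorbed by the intercept
        trial = np.column_stack(design + [col])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            design.append(col)
            rank = r
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} collinear nuisance column(s)",
                      UserWarning, stacklevel=2)
    D = np.column_stack(design)
    coef, *_ = np.linalg.lstsq(D, score, rcond=None)
    return score - D @ coef


def instrument_audit(score: np.ndarray, exposure_x: np.ndarray,
                     covariates: pd.DataFrame, level: float = 0.95) -> dict:
    """Relevance and independence audit of a built score.

    Reports R² of the score-on-exposure regression, the first-stage
    F = (R²/1) / ((1-R²)/(n-2)), and a table of standardised associations
    between the score and each covariate (which should be null when the
    instrument is valid).  Complete cases only; needs at least 30.
    """
    score = np.asarray(score, dtype=float)
    exposure_x = np.asarray(exposure_x, dtype=float)
    mask = ~(np.isnan(score) | np.isnan(exposure_x))
    s, x = score[mask], exposure_x[mask]
    n = s.shape[0]
    if n < 30:
        raise ValueError("instrument audit needs at least 30 complete cases")
    r = float(np.corrcoef(s, x)[0, 1])
    r2 = r * r
    if r2 >= 1.0:
        r2, f_stat = 1.0, math.inf
    else:
        f_stat = (r2 / 1.0) / ((1.0 - r2) / (n - 2))

    rows = []
    zcrit = stats.norm.ppf(0.5 + level / 2)
    s_std = (s - s.mean()) / s.std(ddof=1)
    for name in covariates.columns:
        col = covariates[name].to_numpy(dtype=float)[mask]
        if np.ptp(col) == 0:
            log.info("covariate %s has zero variance; skipped", name)
            continue
        c_std = (col - col.mean()) / col.std(ddof=1)
        beta = float(np.mean(s_std * c_std) * n / (n - 1))
        se = math.sqrt(max(1e-300, (1 - beta ** 2)) / (n - 2))
        rows.append({"covariate": name, "beta_std": beta, "se": se,
                     "ci_low": beta - zcrit * se, "ci_high": beta + zcrit * se,
                     "pval": 2 * stats.norm.sf(abs(beta) / se)})
    return {"r2": r2, "f_stat": f_stat, "n": n,
            "associations": pd.DataFrame(rows)}


def _per_snp_r2(stats_table: pd.DataFrame) -> np.ndarray:
    z = stats_table["beta"].to_numpy() / stats_table["se"].to_numpy()
    n = stats_table["n"].to_numpy(dtype=float)
    if np.isnan(n).any():
        raise ValueError("per-SNP sample size required on both sides")
    return z ** 2 / (z ** 2 + n)


def steiger_filter(pair: SummaryPair, require_significance: bool = False,
                   alpha: float = 0.05) -> tuple[SummaryPair, pd.DataFrame]:
    """Remove SNPs that explain more outcome than exposure variance.

    Per-SNP variance explained is z²/(z²+n) on each side.  By default a SNP
    is removed whenever r²(outcome) > r²(exposure) (direction only; ties
    retain the SNP).  With ``require_significance`` the removal additionally
    requires Steiger's z-test on the difference of the implied correlations
    to reject at ``alpha``.
    """
    r2_exp = _per_snp_r2(pair.exposure_stats)
    r2_out = _per_snp_r2(pair.outcome_stats)
    reverse = r2_out > r2_exp  # strict: ties retained
    n_exp = pair.exposure_stats["n"].to_numpy(dtype=float)
    n_out = pair.outcome_stats["n"].to_numpy(dtype=float)
    z_exp = np.arctanh(np.sqrt(r2_exp))
    z_out = np.arctanh(np.sqrt(r2_out))
    se_diff = np.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z_steiger = (z_out - z_exp) / se_diff
    p_diff = stats.norm.sf(z_steiger)  # small when outcome r2 credibly larger
    if require_significance:
        removed = reverse & (p_diff < alpha)
    else:
        removed = reverse
    removal_log = pd.DataFrame({
        "snp": pair.exposure_stats["snp"],
        "r2_exposure": r2_exp, "r2_outcome": r2_out,
        "steiger_z": z_steiger, "steiger_p": p_diff,
        "removed": removed})
    return pair.subset(~removed), removal_log
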