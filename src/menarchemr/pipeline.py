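"""Configuration-driven end-to-end runs.

``run_pipeline`` executes the registered analysis sequence on one synthetic
cohort: generate -> build instrument -> impute and weight -> observational
models -> one-sample MR with negative controls -> two-sample MR battery ->
decision engine; every table is written tab-delimited with '#'-prefixed
metadata lines into a fresh run directory, together with a manifest holding
the config hash and seed so a re-run with the same config reproduces every
table bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .estimates import Estimate
from .inference import HYPOTHESES, decide
from .instruments import compute_grs, instrument_audit, residualize
from .missing import impute_censored, ipw_weights, pool_rubin
from .mr_one_sample import (negative_control_test, rescale_per_year, tsls,
                            tsls_logistic)
from .mr_two_sample import (contamination_mixture, ivw, mr_egger, mr_presso,
                            mvmr, wald_ratios, weighted_median)
from .observational import fit_linear, fit_logistic, select_transform, \
    standardize
from .instruments import steiger_filter
from .synthetic import (BIN_DOMAINS, CONT_DOMAINS, SimParams,
                        generate_cohort, generate_mvmr_tables,
                        generate_summary_pair, write_cohort_table,
                        write_gwas_table)

__all__ = ["DEFAULT_CONFIG", "ConfigError", "validate_config",
           "run_pipeline", "report"]

log = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": None,
    "simulation": {},            # overrides to SimParams fields
    "imputation": {"m": 20, "lower_bound": 15.0},
    "ipw": {"truncate": [0.01, 0.99]},
    "mr": {"steiger": True, "presso_sims": 1000, "median_boot": 1000},
    "output": {"include_dosages": False},
}

_SIM_FIELDS = {f.name for f in dataclasses.fields(SimParams)}


class ConfigError(ValueError):
    """A run configuration failed validation."""


def validate_config(config: dict) -> dict:
    """Merge a user config over the defaults, rejecting unknown keys and
    configs without an explicit seed (no silent nondeterminism)."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, value in config.items():
        if key not in merged:
            raise ConfigError(f"unknown config key: {key!r}")
        if key == "seed":
            merged["seed"] = value
        elif key == "simulation":
            for sk in value:
                if sk not in _SIM_FIELDS or sk == "seed":
                    raise ConfigError(f"unknown config key: simulation.{sk!r}")
            merged["simulation"].update(value)
        else:
            for sk in value:
                if sk not in merged[key]:
                    raise ConfigError(f"unknown config key: {key}.{sk!r}")
            merged[key].update(value)
    if merged["seed"] is None:
        raise ConfigError("config must set an integer seed")
    return merged


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write(frame: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def _est_row(est: Estimate, **tags) -> dict:
    return {**tags, "estimate": est.theta_hat, "se": est.se,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "p_one": est.p_one, "p_two": est.p_two, "n": est.n,
            "scale": est.scale, "exposure_unit": est.exposure_unit}


def _pooled_fit(imputations, fitter) -> Estimate:
    """Apply ``fitter(cohort_completed)`` to every imputed dataset and pool."""
    ests = [fitter(imputations.completed(i)) for i in range(imputations.m)]
    return pool_rubin(ests)


def run_pipeline(config: dict, out_dir: str | Path) -> Path:
    """Run the full analysis and write all tables into ``out_dir``.

    Returns the run directory path.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    meta = {"config_hash": _config_hash(cfg), "seed": seed,
            "package_version": __version__}

    params = SimParams(**cfg["simulation"], seed=seed)
    cohort = generate_cohort(params)
    write_cohort_table(cohort, out / "cohort.tsv",
                       include_dosages=cfg["output"]["include_dosages"])
    pair = generate_summary_pair(params)
    write_gwas_table(pair.exposure_stats, out / "gwas_exposure.tsv", meta)
    write_gwas_table(pair.outcome_stats, out / "gwas_outcome.tsv", meta)

    # ---- instrument -----------------------------------------------------
    weights = pair.exposure_stats["beta"].to_numpy()
    score = compute_grs(cohort.dosages, weights)
    nuisance = cohort.covariates[["batch"] +
                                 [f"pc{k}" for k in range(1, 21)]]
    score_resid = residualize(score, nuisance)
    audit = instrument_audit(score_resid, cohort.exposure_x,
                             cohort.covariates[["edu", "income", "batch"]])
    _write(audit["associations"], out / "instrument_audit.tsv",
           {**meta, "r2": f"{audit['r2']:.6f}",
            "f_stat": f"{audit['f_stat']:.2f}", "n": audit["n"]})

    # ---- missing data ---------------------------------------------------
    imputations = impute_censored(cohort, m=cfg["imputation"]["m"],
                                  seed=seed + 1,
                                  lower_bound=cfg["imputation"]["lower_bound"])
    ws = ipw_weights(cohort, truncate=tuple(cfg["ipw"]["truncate"]))
    _write(ws.balance, out / "ipw_balance.tsv", meta)

    part = cohort.participation
    sd_x = float(np.nanstd(cohort.exposure_x, ddof=1))

    # transformed + standardised continuous outcomes (shared across models)
    y_std, labels = {}, {}
    for d in CONT_DOMAINS:
        t, label = select_transform(cohort.outcomes_cont[d].to_numpy())
        y_std[d] = standardize(t)
        labels[d] = label
        t_nc, _ = select_transform(cohort.negcontrol_cont[d].to_numpy())
        y_std[f"nc_{d}"] = standardize(t_nc)

    # ---- observational models -------------------------------------------
    obs_rows = []
    obs_estimates = {}
    base_covars = cohort.covariates[["edu", "income", "batch"]]
    for d in CONT_DOMAINS:
        def unadj(c, d=d):
            return fit_linear(y_std[d], standardize(c.exposure_x), None)
        est_u = _pooled_fit(imputations, unadj)
        adj_cols = {**{k: base_covars[k].to_numpy() for k in base_covars},
                    "prepubertal": y_std[f"nc_{d}"]}
        if d != "depression":
            adj_cols["depression_sym"] = y_std["depression"]

        def adj(c, d=d, adj_cols=adj_cols):
            covars = pd.DataFrame(adj_cols).loc[part].reset_index(drop=True)
            return fit_linear(y_std[d][part],
                              standardize(c.exposure_x)[part],
                              covars, weights=ws.weights)
        est_a = _pooled_fit(imputations, adj)
        obs_estimates[("cont", d)] = est_a
        obs_rows.append(_est_row(est_u, outcome=d, outcome_type="symptoms",
                                 model="unadjusted", transform=labels[d]))
        obs_rows.append(_est_row(est_a, outcome=d, outcome_type="symptoms",
                                 model="adjusted", transform=labels[d]))
    for d in BIN_DOMAINS:
        case = cohort.outcomes_bin[d].to_numpy()

        def unadj_b(c, case=case):
            return fit_logistic(case, standardize(c.exposure_x), None)
        est_u = _pooled_fit(imputations, unadj_b)

        def adj_b(c, case=case):
            covars = base_covars.loc[part].reset_index(drop=True)
            return fit_logistic(case[part], standardize(c.exposure_x)[part],
                                covars, weights=ws.weights)
        est_a = _pooled_fit(imputations, adj_b)
        obs_estimates[("bin", d)] = est_a
        obs_rows.append(_est_row(est_u, outcome=d, outcome_type="diagnosis",
                                 model="unadjusted", transform="identity"))
        obs_rows.append(_est_row(est_a, outcome=d, outcome_type="diagnosis",
                                 model="adjusted", transform="identity"))
    _write(pd.DataFrame(obs_rows), out / "observational.tsv", meta)

    # ---- one-sample MR ---------------------------------------------------
    mr1_rows = []
    mr1_estimates, negcontrols = {}, {}
    for d in CONT_DOMAINS:
        def mr_fit(c, d=d):
            per_year = tsls(y_std[d], c.exposure_x, score_resid)
            return rescale_per_year(per_year, 1.0 / sd_x)  # -> per SD
        est = _pooled_fit(imputations, mr_fit)
        mr1_estimates[("cont", d)] = est

        def nc_fit(c, d=d):
            per_year = tsls(y_std[f"nc_{d}"], c.exposure_x, score_resid,
                            direction="negative")
            return rescale_per_year(per_year, 1.0 / sd_x)
        est_nc = _pooled_fit(imputations, nc_fit)
        negcontrols[d] = negative_control_test(est, est_nc)
        mr1_rows.append(_est_row(est, outcome=d, outcome_type="symptoms",
                                 model="1SMR", transform=labels[d]))
        mr1_rows.append(_est_row(est_nc, outcome=d, outcome_type="symptoms",
                                 model="1SMR_negcontrol",
                                 transform=labels[d]))
    for d in BIN_DOMAINS:
        case = cohort.outcomes_bin[d].to_numpy()

        def mr_fit_b(c, case=case):
            per_year = tsls_logistic(case, c.exposure_x, score_resid)
            return rescale_per_year(per_year, 1.0 / sd_x)
        est = _pooled_fit(imputations, mr_fit_b)
        mr1_estimates[("bin", d)] = est
        mr1_rows.append(_est_row(est, outcome=d, outcome_type="diagnosis",
                                 model="1SMR", transform="identity"))
    _write(pd.DataFrame(mr1_rows), out / "mr_onesample.tsv", meta)

    # ---- two-sample MR battery ------------------------------------------
    mr2_rows = []
    ratios = wald_ratios(pair)

    def add(res, variant="full"):
        row = _est_row(res.estimate, method=res.method, variant=variant)
        row["n_snps"] = res.n_snps
        row["q"] = res.q_stat["Q"] if res.q_stat else np.nan
        row["q_p"] = res.q_stat["p"] if res.q_stat else np.nan
        row["egger_intercept"] = (res.egger_intercept.theta_hat
                                  if res.egger_intercept else np.nan)
        row["egger_intercept_p"] = (res.egger_intercept.p_two
                                    if res.egger_intercept else np.nan)
        row["presso_global_p"] = res.global_p if res.global_p else np.nan
        row["outliers"] = ";".join(res.outliers) if res.outliers else ""
        mr2_rows.append(row)

    add(ivw(ratios))
    add(mr_egger(pair))
    add(weighted_median(ratios, n_boot=cfg["mr"]["median_boot"],
                        seed=seed + 2))
    add(contamination_mixture(ratios))
    add(mr_presso(pair, n_sim=cfg["mr"]["presso_sims"], seed=seed + 3))
    if cfg["mr"]["steiger"]:
        filtered, steiger_log = steiger_filter(pair)
        _write(steiger_log, out / "steiger_log.tsv", meta)
        if filtered.n_snps >= 3:
            fr = wald_ratios(filtered)
            add(ivw(fr), variant="steiger")
            add(contamination_mixture(fr), variant="steiger")
    bexp, bse, ostats, _truth = generate_mvmr_tables(params)
    res_mv = mvmr(bexp, bse, ostats["beta"].to_numpy(),
                  ostats["se"].to_numpy())
    add(res_mv, variant="mvmr")
    mv_direct = {k: v.theta_hat for k, v in res_mv.estimates.items()}
    _write(pd.DataFrame(mr2_rows), out / "mr_twosample.tsv",
           {**meta, "mvmr_conditional_f": json.dumps(
               {k: round(v, 2) for k, v in res_mv.conditional_f.items()}),
            "mvmr_direct_effects": json.dumps(
                {k: round(v, 4) for k, v in mv_direct.items()})})

    # ---- decisions -------------------------------------------------------
    domain_map_cont = {"H1a": "depression", "H2.1a": "anxiety",
                       "H2.2a": "cd", "H2.3a": "odd", "H2.4a": "adhd",
                       "H3a": "depression", "H4.1a": "anxiety",
                       "H4.2a": "cd", "H4.3a": "odd", "H4.4a": "adhd"}
    domain_map_bin = {"H1b": "depression", "H2.1b": "anxiety",
                      "H2.2b": "dbd", "H2.3b": "adhd", "H3b": "depression",
                      "H4.1b": "anxiety", "H4.2b": "dbd", "H4.3b": "adhd"}
    dec_rows = []
    for spec in HYPOTHESES:
        is_mr = spec.id.startswith(("H3", "H4"))
        store = mr1_estimates if is_mr else obs_estimates
        if spec.id in domain_map_cont:
            est = store[("cont", domain_map_cont[spec.id])]
            nc = negcontrols.get(domain_map_cont[spec.id]) \
                if spec.requires_negcontrol else None
        else:
            est = store[("bin", domain_map_bin[spec.id])]
            nc = None
        est = est.with_(direction=spec.direction
                        if spec.direction != "two_sided" else "two_sided")
        d = decide(spec, est, nc)
        dec_rows.append({"hypothesis": d.hypothesis_id, "verdict": d.verdict,
                         "estimate": est.theta_hat, "se": est.se,
                         "nhst_p": d.nhst_p, "equivalence_p": d.equivalence_p,
                         "negcontrol_pass": d.negcontrol_pass,
                         "sesoi_bound": d.bound, "scale": d.scale})
    _write(pd.DataFrame(dec_rows), out / "decisions.tsv", meta)

    manifest = {**meta, "config": cfg,
                "tables": sorted(p.name for p in out.glob("*.tsv"))}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return out


_EXPECTED_TABLES = ["observational.tsv", "mr_onesample.tsv",
                    "mr_twosample.tsv", "decisions.tsv"]


def report(run_dir: str | Path) -> str:
    """Render a human-readable summary of a completed run.

    Numbers are read back from the emitted tables (never recomputed), so the
    report cannot drift from the run artefacts.  Missing tables are listed,
    not fatal.
    """
    run = Path(run_dir)
    lines = [f"Run report: {run}", "=" * 60]
    missing = [t for t in _EXPECTED_TABLES if not (run / t).exists()]
    if missing:
        lines.append("Missing tables: " + ", ".join(missing))

    def load(name):
        p = run / name
        if not p.exists():
            return None
        return pd.read_csv(p, sep="\t", comment="#")

    obs = load("observational.tsv")
    mr1 = load("mr_onesample.tsv")
    if obs is not None:
        lines.append("\nObservational and one-sample MR estimates "
                     "(per SD of exposure)")
        for d in sorted(obs["outcome"].unique()):
            lines.append(f"\n  [{d}]")
            sub = obs[obs["outcome"] == d]
            for _, r in sub.iterrows():
                lines.append(
                    f"    {r['model']:<18} {r['scale']:<7} "
                    f"{r['estimate']:+.3f} [{r['ci_low']:+.3f}, "
                    f"{r['ci_high']:+.3f}]  p1={r['p_one']:.3g}")
            if mr1 is not None:
                for _, r in mr1[mr1["outcome"] == d].iterrows():
                    lines.append(
                        f"    {r['model']:<18} {r['scale']:<7} "
                        f"{r['estimate']:+.3f} [{r['ci_low']:+.3f}, "
                        f"{r['ci_high']:+.3f}]  p1={r['p_one']:.3g}")
    mr2 = load("mr_twosample.tsv")
    if mr2 is not None:
        lines.append("\nTwo-sample MR battery (per year of exposure)")
        for _, r in mr2.iterrows():
            lines.append(
                f"  {r['method']:<22} {r['variant']:<8} "
                f"{r['estimate']:+.3f} [{r['ci_low']:+.3f}, "
                f"{r['ci_high']:+.3f}]  J={r['n_snps']}")
    dec = load("decisions.tsv")
    if dec is not None:
        if len(dec) == 0:
            lines.append("\nno hypotheses evaluated")
        else:
            lines.append("\nDecisions")
            for _, r in dec.iterrows():
                lines.append(f"  {r['hypothesis']:<7} {r['verdict']:<28} "
                             f"est={r['estimate']:+.3f} "
                             f"nhst_p={r['nhst_p']:.3g} "
                             f"eq_p={r['equivalence_p']:.3g}")
    text = "\n".join(lines) + "\n"
    (run / "report.txt").write_text(text)
    return text
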