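"""Run orchestration: simulate → fit → covsearch → bootstrap → vpc → report.

A run is driven by a config mapping (usually loaded from YAML) and writes
every stage artifact into a run directory.  Each stage draws its randomness
from its own stream derived from the master seed and a fixed stage index,
so enabling or disabling one stage never shifts another stage's draws and
rerunning with the same config reproduces every numeric output.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bootstrap as bs
from . import vpc as vpcmod
from .cohort import CohortConfig, simulate_cohort
from .covariates import run_covariate_search
from .estimation import (
    FitSettings,
    compute_rse,
    fit_population,
    naive_two_stage_init,
    residual_diagnostics,
)
from .io import EventTable, read_event_table, write_event_table
from .model import PopulationModel, omega2_to_cv, sigma2_to_cv

__all__ = ["run_pipeline", "build_report", "load_config", "stage_seed"]

_STAGE_INDEX = {"simulate": 0, "fit": 1, "covsearch": 2, "bootstrap": 3, "vpc": 4}

_REPORT_LAYOUT = [
    ("theta_v_c", "Volume of central compartment", "L"),
    ("theta_cl", "Systemic clearance", "L/h"),
    ("theta_v_t", "Volume of peripheral compartment", "L"),
    ("theta_q", "Inter-compartmental clearance", "L/h"),
    ("omega_v_c", "Inter-individual variability of V_C", "%CV"),
    ("omega_cl", "Inter-individual variability of CL", "%CV"),
    ("omega_v_t", "Inter-individual variability of V_T", "%CV"),
    ("omega_q", "Inter-individual variability of Q", "%CV"),
    ("sigma", "Proportional residual error variability", "%CV"),
]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2³¹) from the master seed."""
    ss = np.random.SeedSequence([int(master_seed), _STAGE_INDEX[stage]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def _model_dict(model: PopulationModel, convention: str = "lognormal") -> dict:
    return {
        "theta": {k: float(v) for k, v in model.theta.items()},
        "omega2": {k: float(v) for k, v in model.omega2.items()},
        "omega_cv_percent": {
            k: float(omega2_to_cv(v, convention)) for k, v in model.omega2.items()
        },
        "omega_cv_percent_naive": {
            k: float(omega2_to_cv(v, "naive")) for k, v in model.omega2.items()
        },
        "sigma2": float(model.sigma2),
        "sigma_cv_percent": float(sigma2_to_cv(model.sigma2)),
        "covariate_terms": [
            {"parameter": t.parameter, "covariate": t.covariate, "form": t.form,
             "beta": float(t.beta), "reference": t.reference}
            for t in model.covariate_terms
        ],
        "error_model": model.error_model,
        "cv_convention": convention,
    }


def build_report(fit, boot: bs.BootstrapResult | None = None,
                 convention: str = "lognormal") -> pd.DataFrame:
    """Final-estimates table mirroring the published layout: one row per
    parameter with estimate, %RSE, shrinkage and bootstrap median/CI."""
    m = fit.model
    rse = fit.rse_percent or {}
    rows = []

    def boot_cols(label, transform=lambda x: x):
        if boot is None or boot.estimates.empty or label not in boot.estimates:
            return {"boot_median": np.nan, "boot_ci5": np.nan, "boot_ci95": np.nan}
        vals = transform(boot.estimates[label].to_numpy())
        return {
            "boot_median": float(np.percentile(vals, 50)),
            "boot_ci5": float(np.percentile(vals, 5)),
            "boot_ci95": float(np.percentile(vals, 95)),
        }

    for key, desc, unit in _REPORT_LAYOUT:
        if key.startswith("theta_"):
            p = key[len("theta_"):]
            if p not in m.theta:
                continue
            rows.append({
                "parameter": key, "description": desc, "unit": unit,
                "estimate": float(m.theta[p]),
                "rse_percent": rse.get(key, np.nan),
                "shrinkage_percent": np.nan,
                **boot_cols(key),
            })
        elif key.startswith("omega_"):
            p = key[len("omega_"):]
            if p not in m.omega2:
                continue
            rows.append({
                "parameter": key, "description": desc, "unit": unit,
                "estimate": float(omega2_to_cv(m.omega2[p], convention)),
                "rse_percent": rse.get(f"omega2_{p}", np.nan),
                "shrinkage_percent": fit.shrinkage_percent.get(p, np.nan),
                **boot_cols(f"omega2_{p}", lambda x: omega2_to_cv(x, convention)),
            })
        else:
            rows.append({
                "parameter": "sigma", "description": desc, "unit": unit,
                "estimate": float(sigma2_to_cv(m.sigma2)),
                "rse_percent": rse.get("sigma2", np.nan),
                "shrinkage_percent": np.nan,
                **boot_cols("sigma2", lambda x: 100.0 * np.sqrt(x)),
            })
    for t in m.covariate_terms:
        rows.append({
            "parameter": f"beta_{t.label}", "description": f"Covariate effect {t.label}",
            "unit": "-", "estimate": float(t.beta),
            "rse_percent": rse.get(f"beta_{t.label}", np.nan),
            "shrinkage_percent": np.nan, **boot_cols(f"beta_{t.label}"),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: dict | str | Path, output_dir=None) -> Path:
    """Execute the configured stages and return the run directory.

    A stage failure halts downstream stages but preserves the artifacts
    written so far.  See the README for the config schema.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(output_dir or config.get("output_dir", "dexpopk_run"))
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))

    logger = logging.getLogger(f"dexpopk.run.{out.name}")
    logger.setLevel(logging.INFO)
    logger.handlers = [logging.FileHandler(out / "run.log", mode="w")]
    logger.addHandler(logging.StreamHandler())
    logger.info("config: %s", json.dumps(config, default=str))

    stages = config.get("stages", {})

    def enabled(name, default=True):
        v = stages.get(name, default)
        return bool(v) if not isinstance(v, dict) else v.get("enabled", True)

    t0 = time.time()
    # ---- data: simulate or load --------------------------------------
    if config.get("data"):
        table = read_event_table(config["data"])
        subjects = table.to_subjects()
        logger.info("loaded %d subjects from %s", len(subjects), config["data"])
    else:
        ccfg = CohortConfig(
            **{**config.get("cohort", {}), "seed": stage_seed(master_seed, "simulate")}
        )
        sim = simulate_cohort(ccfg)
        subjects = sim.subjects
        table = EventTable.from_subjects(subjects)
        write_event_table(table, out / "cohort.csv")
        (out / "truth.json").write_text(
            json.dumps(_model_dict(sim.config.truth), indent=2)
        )
        sim.eta.to_csv(out / "truth_eta.csv")
        logger.info(
            "simulated %d subjects (%d observations), seed %d",
            len(subjects), sum(s.n_obs for s in subjects), ccfg.seed,
        )
    if not enabled("fit"):
        return out

    # ---- fit ----------------------------------------------------------
    fit_cfg = config.get("fit", {})
    settings = FitSettings(method=fit_cfg.get("method", "foce_i"))
    init = naive_two_stage_init(subjects)
    fit = fit_population(subjects, init, settings=settings)
    if fit_cfg.get("compute_rse", True):
        compute_rse(fit)
    fit_payload = {
        "ofv": fit.ofv, "converged": fit.converged, "method": fit.method,
        "n_subjects": fit.n_subjects, "n_obs": fit.n_obs,
        "model": _model_dict(fit.model),
        "rse_percent": fit.rse_percent,
        "shrinkage_percent": fit.shrinkage_percent,
    }
    (out / "fit.json").write_text(json.dumps(fit_payload, indent=2, default=float))
    fit.eta_hat.to_csv(out / "eta_hat.csv")
    residual_diagnostics(fit).to_csv(out / "diagnostics.csv", index=False)
    logger.info("fit: ofv=%.3f converged=%s (%.1fs)", fit.ofv, fit.converged, time.time() - t0)

    # ---- covariate search --------------------------------------------
    if enabled("covsearch", default=False):
        cs_cfg = stages.get("covsearch", {}) if isinstance(stages.get("covsearch"), dict) else {}
        trace = run_covariate_search(
            fit, subjects,
            covariates=cs_cfg.get("covariates", list(fit._design.covariates.columns)),
            settings=settings,
        )
        trace.to_frame().to_csv(out / "covsearch.csv", index=False)
        if trace.final_fit is not None and trace.final_model.covariate_terms:
            fit = trace.final_fit
        logger.info("covsearch: %d terms selected", len(trace.selected))

    # ---- bootstrap ----------------------------------------------------
    boot = None
    if enabled("bootstrap", default=False):
        b_cfg = stages.get("bootstrap", {}) if isinstance(stages.get("bootstrap"), dict) else {}
        boot = bs.nonparametric_bootstrap(
            subjects, fit.model, fit_settings=settings,
            n_reps=int(b_cfg.get("n_reps", 1000)),
            seed=stage_seed(master_seed, "bootstrap"),
        )
        boot.estimates.to_csv(out / "bootstrap_replicates.csv")
        boot.summary.to_csv(out / "bootstrap_summary.csv", index=False)
        logger.info(
            "bootstrap: %d/%d converged%s", boot.n_converged, boot.n_requested,
            " (UNRELIABLE)" if boot.unreliable else "",
        )

    # ---- vpc ----------------------------------------------------------
    if enabled("vpc", default=False):
        v_cfg = stages.get("vpc", {}) if isinstance(stages.get("vpc"), dict) else {}
        summary = vpcmod.pcvpc(
            fit,
            n_sim=int(v_cfg.get("n_sim", 1000)),
            n_bins=int(v_cfg.get("n_bins", 10)),
            seed=stage_seed(master_seed, "vpc"),
        )
        summary.to_csv(out / "vpc.csv")
        try:
            ax = vpcmod.plot_vpc(summary)
            ax.figure.savefig(out / "vpc.png", dpi=120)
        except Exception as exc:  # plotting must never sink a run
            logger.warning("vpc plot skipped: %s", exc)
        logger.info("vpc: %d bins, %d replicates", summary.metadata["n_bins"], summary.n_sim)

    # ---- report -------------------------------------------------------
    report = build_report(fit, boot)
    report.to_csv(out / "report.csv", index=False)
    (out / "report.json").write_text(
        report.to_json(orient="records", indent=2)
    )
    logger.info("run complete in %.1fs -> %s", time.time() - t0, out)
    return out
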