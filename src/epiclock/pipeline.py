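"""End-to-end orchestration: config handling, staged execution, reporting.

The pipeline runs import -> spike-in calibration -> methylation calling ->
age-DML scan -> correlation filter -> elastic-net clock -> prediction ->
trajectory statistics -> survival statistics, from a single config with one
seed.  The seed fans out to per-stage derived seeds (stage-name hashed) so any
stage can be reproduced in isolation.  Every run can write the resolved
config, a machine-readable JSON report with the counts at each funnel stage,
and Dataset-style CSV tables for each stage's output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import clock as clock_mod
from . import dml as dml_mod
from . import io as io_mod
from . import status as status_mod
from . import survival as surv_mod
from . import synthetic as synth_mod
from . import trajectory as traj_mod

logger = logging.getLogger("epiclock")


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    return (zlib.crc32(stage.encode()) ^ (seed & 0xFFFFFFFF)) & 0x7FFFFFFF


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _from_dict(cls, data: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class SyntheticBlock:
    """Synthetic-mode inputs mirroring the generator's parameter types."""

    design: synth_mod.StudyDesign = field(default_factory=synth_mod.StudyDesign)
    architecture: synth_mod.ClockArchitecture = field(default_factory=synth_mod.ClockArchitecture)
    survival: synth_mod.SurvivalScenario = field(default_factory=synth_mod.SurvivalScenario)
    n_lambda_cpgs: int = 300

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticBlock":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys for SyntheticBlock: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        if "design" in data:
            d = dict(data["design"])
            for key in ("treatments", "timepoints"):
                if key in d:
                    d[key] = tuple(d[key])
            kwargs["design"] = _from_dict(synth_mod.StudyDesign, d)
        if "architecture" in data:
            d = dict(data["architecture"])
            for key in ("baseline_logit_range", "slope_logit_range"):
                if key in d:
                    d[key] = tuple(d[key])
            kwargs["architecture"] = _from_dict(synth_mod.ClockArchitecture, d)
        if "survival" in data:
            kwargs["survival"] = _from_dict(synth_mod.SurvivalScenario, dict(data["survival"]))
        if "n_lambda_cpgs" in data:
            kwargs["n_lambda_cpgs"] = data["n_lambda_cpgs"]
        return cls(**kwargs)


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths for one run."""

    coverage_dir: str | None = None
    sample_sheet: str | None = None
    survival_file: str | None = None
    output_dir: str | None = None
    spikein_contig: str = synth_mod.SPIKEIN_CONTIG
    min_coverage: int = 10
    status_fdr: float = 0.05
    min_samples: int | None = None
    status_mode: str = "pooled"
    dml_fdr: float = 0.05
    adjust_treatment: bool = False
    dispersion_threshold: float = 1.0
    dispersion_mode: str = "pooled"
    r_min: float = 0.3
    p_max: float = 0.05
    alpha: float = 0.5
    k_folds: int = 10
    repeats: int = 3
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-3
    contrast_days: tuple[float, ...] = (6.0, 30.0)
    seed: int = 0
    synthetic: SyntheticBlock | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        synth = data.pop("synthetic", None)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "contrast_days" in data:
            data["contrast_days"] = tuple(float(d) for d in data["contrast_days"])
        cfg = cls(**data)
        if synth is not None:
            cfg.synthetic = SyntheticBlock.from_dict(synth)
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        out = {}
        for f in dataclasses.fields(self):
            out[f.name] = plain(getattr(self, f.name))
        return out

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def default_synthetic_config(seed: int = 0, output_dir: str | None = None) -> PipelineConfig:
    """The default synthetic study: 2 treatments x 5 timepoints x 4 pools,
    50 clock + 950 null CpGs, rate ratio 0.708, emergence offset 2.8 d."""
    block = SyntheticBlock()
    block.design = dataclasses.replace(block.design, seed=derive_seed(seed, "synthetic"))
    block.survival = dataclasses.replace(block.survival, seed=derive_seed(seed, "survival_sim"))
    return PipelineConfig(seed=seed, output_dir=output_dir, synthetic=block)


def run_pipeline(config: PipelineConfig, write_outputs: bool = True) -> dict:
    """Execute all stages; returns the machine-readable run report.

    In synthetic mode (``config.synthetic`` set and no coverage_dir) the
    inputs are generated in memory.  With ``write_outputs`` and an
    ``output_dir``, the resolved config, report JSON, Dataset-style tables and
    a MANIFEST of completed stages are written.
    """
    out_dir = Path(config.output_dir) if (config.output_dir and write_outputs) else None
    manifest: list[str] = []
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "resolved_config.yaml")

    def finish_stage(name: str, t0: float, detail: str = "") -> None:
        manifest.append(name)
        logger.info("stage %-22s done in %6.2fs %s", name, time.perf_counter() - t0, detail)
        if out_dir:
            (out_dir / "MANIFEST").write_text("\n".join(manifest) + "\n")

    def run_stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            if out_dir:
                (out_dir / "MANIFEST").write_text("\n".join(manifest) + "\n")
            raise PipelineError(name, exc) from exc
        finish_stage(name, t0)
        return result

    report: dict[str, Any] = {"seed": config.seed, "funnel": {}}

    # -- stage: import -----------------------------------------------------
    def stage_import():
        if config.synthetic is not None:
            block = config.synthetic
            matrix, sheet, truth = synth_mod.generate_methylation_dataset(
                block.design, block.architecture)
            spike = synth_mod.generate_spikein_counts(block.design, block.architecture,
                                                      block.n_lambda_cpgs)
            cohort = synth_mod.generate_survival_cohort(block.survival)
            return matrix, spike, sheet, cohort, truth
        if not (config.coverage_dir and config.sample_sheet):
            raise ValueError("either synthetic mode or coverage_dir + sample_sheet required")
        sheet = io_mod.read_sample_sheet(config.sample_sheet)
        cov_dir = Path(config.coverage_dir)
        paths = {}
        for lib in sheet["library_id"]:
            for suffix in (".cov", ".cov.gz"):
                p = cov_dir / f"{lib}{suffix}"
                if p.exists():
                    paths[lib] = p
                    break
            else:
                raise FileNotFoundError(f"no coverage file for library {lib!r} in {cov_dir}")
        full = io_mod.read_coverage_files(paths, sheet)
        matrix, spike = io_mod.split_spikein(full, config.spikein_contig)
        cohort = None
        if config.survival_file:
            cohort = pd.read_csv(config.survival_file)
        return matrix, spike, sheet, cohort, None

    matrix, spike, sheet, cohort, truth = run_stage("import", stage_import)
    report["funnel"]["n_sites_total"] = matrix.n_sites
    report["n_libraries"] = matrix.n_libraries

    # -- stage: spike-in calibration --------------------------------------
    est = run_stage("conversion_estimate",
                    lambda: status_mod.estimate_conversion_error(spike))
    report["conversion"] = {"error_rate": est.error_rate,
                            "total_reads": est.total_reads,
                            "methylated_reads": est.methylated_reads}

    # -- stage: methylation calling ----------------------------------------
    def stage_status():
        return status_mod.call_methylated_sites(
            matrix, est, min_coverage=config.min_coverage, fdr_q=config.status_fdr,
            min_samples=config.min_samples, mode=config.status_mode)

    called = run_stage("methylation_status", stage_status)
    report["funnel"]["n_methylated"] = len(called)
    meth_matrix = matrix.subset_sites(called.site_ids)

    # -- stage: age-DML scan ------------------------------------------------
    def stage_dml():
        return dml_mod.run_dml_scan(meth_matrix, sheet, fdr_q=config.dml_fdr,
                                    adjust_treatment=config.adjust_treatment,
                                    dispersion_threshold=config.dispersion_threshold,
                                    dispersion_mode=config.dispersion_mode)

    dml_table = run_stage("dml_age", stage_dml)
    dml_sites = list(dml_table.index[dml_table["significant"]])
    report["funnel"]["n_age_dml"] = len(dml_sites)

    # -- stage: correlation filter ------------------------------------------
    treatments = list(pd.unique(sheet["treatment"]))
    control, treated = treatments[0], treatments[1]
    control_libs = sheet.loc[sheet["treatment"] == control, "library_id"].tolist()
    treated_libs = sheet.loc[sheet["treatment"] == treated, "library_id"].tolist()
    ages = sheet.set_index("library_id")["age_days"]

    def stage_filter():
        props = meth_matrix.subset_sites(dml_sites).proportions()
        return clock_mod.correlation_filter(props[control_libs], ages.loc[control_libs],
                                            r_min=config.r_min, p_max=config.p_max)

    corr_table = run_stage("correlation_filter", stage_filter)
    filtered_sites = list(corr_table.index[corr_table["retained"]])
    report["funnel"]["n_correlation_filtered"] = len(filtered_sites)

    # -- stage: clock fit ----------------------------------------------------
    def stage_clock():
        props = meth_matrix.subset_sites(filtered_sites).proportions()
        features = props[control_libs].T  # library x site
        return clock_mod.fit_elastic_net_clock(
            features, ages.loc[control_libs], alpha=config.alpha,
            n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
            k_folds=min(config.k_folds, len(control_libs)), repeats=config.repeats,
            seed=derive_seed(config.seed, "clock"))

    model, control_val = run_stage("clock_fit", stage_clock)
    report["funnel"]["n_panel"] = len(model.panel())
    report["clock"] = {
        "alpha": model.alpha,
        "lambda": model.lam,
        "panel_size": len(model.panel()),
        "control_cv_r2": control_val.r2,
        "control_cv_rmse": control_val.rmse,
    }

    # -- stage: prediction ----------------------------------------------------
    def stage_predict():
        props_all = meth_matrix.proportions()
        panel = model.panel()
        feats = props_all.loc[[s for s in panel]].T if panel else props_all.T
        treated_pred = clock_mod.predict_epigenetic_age(model, feats.loc[treated_libs])
        # controls keep their cross-validated (out-of-fold) predictions
        control_pred = control_val.predictions["predicted_age"]
        return pd.concat([control_pred, treated_pred])

    predictions = run_stage("prediction", stage_predict)
    treated_val = clock_mod.validate_clock(predictions.loc[treated_libs],
                                           ages.loc[treated_libs], group=treated)
    report["clock"]["transfer_r2"] = treated_val.r2
    report["clock"]["transfer_rmse"] = treated_val.rmse

    # -- stage: trajectory -----------------------------------------------------
    def stage_trajectory():
        idx = predictions.index
        fit = traj_mod.fit_trajectory(predictions, ages.loc[idx],
                                      sheet.set_index("library_id").loc[idx, "treatment"],
                                      reference=control)
        contrasts = [traj_mod.contrast_at_day(fit, d) for d in config.contrast_days]
        return fit, contrasts

    fit, contrasts = run_stage("trajectory", stage_trajectory)
    slow, slow_lo, slow_hi = traj_mod.percent_slowdown_ci(fit)
    conv = traj_mod.convergence_day(fit)
    report["trajectory"] = {
        "control_slope": fit.slopes[control],
        "treatment_slope": fit.slopes[treated],
        "interaction_t": fit.interaction_t,
        "interaction_p": fit.interaction_p,
        "df": fit.df_resid,
        "percent_slowdown": slow,
        "percent_slowdown_ci": [slow_lo, slow_hi],
        "convergence_day": conv,
        "contrasts": {f"day_{c.day:g}": {"difference": c.difference, "se": c.se,
                                         "t": c.t, "p": c.p, "means": c.means}
                      for c in contrasts},
    }

    # -- stage: survival --------------------------------------------------------
    km = cox = None
    if cohort is not None:
        def stage_survival():
            return surv_mod.km_fit(cohort), surv_mod.cox_fit(cohort, reference=control)

        km, cox = run_stage("survival", stage_survival)
        medians = {g: e.median for g, e in km.groups.items()}
        report["survival"] = {
            "medians": medians,
            "median_cis": {g: list(e.median_ci) for g, e in km.groups.items()},
            "hazard_ratio": cox.hr,
            "hazard_ratio_ci": list(cox.hr_ci),
            "cox_p": cox.p,
            "hazard_reduction_percent": surv_mod.hazard_reduction_percent(cox.hr),
        }
        if medians.get(treated) and medians.get(control):
            report["survival"]["median_extension_percent"] = \
                surv_mod.median_extension_percent(medians[treated], medians[control])
        # translate the HR through the epigenetic-age gap at the last contrast day
        last = contrasts[-1]
        delta = last.means[control] - last.means[treated]
        if delta != 0 and cox.hr > 0:
            trans = surv_mod.hazard_per_epigenetic_day(cox.hr, delta)
            report["survival"]["hazard_translation"] = {
                "delta_days": trans.delta_days,
                "coefficient_per_day": trans.coefficient,
                "percent_hazard_increase_per_day": trans.percent_increase,
            }

    # -- ground-truth comparison (synthetic mode) -------------------------------
    if truth is not None:
        planted = set(truth.clock_cpg_ids)
        dml_set = set(dml_sites)
        panel_set = set(model.panel())
        n_true_dml = len(planted & dml_set)
        report["truth"] = {
            "n_planted_clock_cpgs": len(planted),
            "dml_recall": n_true_dml / len(planted) if planted else float("nan"),
            "dml_observed_fdr": (len(dml_set - planted) / len(dml_set)) if dml_set else 0.0,
            "panel_purity": (len(panel_set & planted) / len(panel_set)) if panel_set else float("nan"),
        }

    # -- outputs ---------------------------------------------------------------
    if out_dir:
        called.summary.to_csv(out_dir / "dataset_S1_methylation_calls.csv",
                              index_label="site_id")
        dml_table.to_csv(out_dir / "dataset_S2_age_dml.csv", index_label="site_id")
        corr_table.to_csv(out_dir / "dataset_S3_correlation_filter.csv",
                          index_label="site_id")
        panel_rows = pd.DataFrame({"coefficient": [model.coefficients[s] for s in model.panel()]},
                                  index=pd.Index(model.panel(), name="site_id"))
        panel_rows.to_csv(out_dir / "dataset_S4_clock_panel.csv")
        model.save(out_dir / "clock_model.json")
        io_mod.write_clock_panel(model, matrix.sites, out_dir / "clock_panel.bed")
        pred_out = pd.DataFrame({
            "predicted_age": predictions,
            "age_days": ages.loc[predictions.index],
            "treatment": sheet.set_index("library_id").loc[predictions.index, "treatment"],
        })
        pred_out.to_csv(out_dir / "predictions.csv", index_label="library_id")
        traj_mod.trajectory_table(fit, contrasts).to_csv(out_dir / "trajectory.csv", index=False)
        if km is not None:
            surv_mod.survival_table(km, cox).to_csv(out_dir / "survival.csv", index=False)
        (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True,
                                                        default=_json_default))
        _write_text_report(report, out_dir / "report.txt")
        finish_stage("outputs", time.perf_counter())
    return report


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_text_report(report: dict, path: Path) -> None:
    lines = ["epiclock run report", "===================", ""]
    fun = report["funnel"]
    lines.append("funnel: %s sites -> %s methylated -> %s age-DML -> %s filtered -> %s panel"
                 % (fun.get("n_sites_total"), fun.get("n_methylated"),
                    fun.get("n_age_dml"), fun.get("n_correlation_filtered"),
                    fun.get("n_panel")))
    ck = report.get("clock", {})
    lines.append(f"clock: lambda={ck.get('lambda'):.5g} panel={ck.get('panel_size')} "
                 f"control CV R2={ck.get('control_cv_r2'):.3f} RMSE={ck.get('control_cv_rmse'):.2f} d")
    if "transfer_r2" in ck:
        lines.append(f"       transfer R2={ck['transfer_r2']:.3f} RMSE={ck['transfer_rmse']:.2f} d")
    tj = report.get("trajectory", {})
    if tj:
        lines.append(f"trajectory: control slope={tj['control_slope']:.5f} "
                     f"treatment slope={tj['treatment_slope']:.5f} "
                     f"slowdown={tj['percent_slowdown']:.1f}% "
                     f"convergence day={tj['convergence_day'] if tj['convergence_day'] is None else round(tj['convergence_day'], 2)}")
    sv = report.get("survival", {})
    if sv:
        lines.append(f"survival: HR={sv['hazard_ratio']:.3f} "
                     f"medians={sv['medians']}")
        if "median_extension_percent" in sv:
            lines.append(f"          median extension={sv['median_extension_percent']:.1f}%")
        if "hazard_translation" in sv:
            ht = sv["hazard_translation"]
            lines.append(f"          implied hazard increase per epigenetic day="
                         f"{ht['percent_hazard_increase_per_day']:.1f}%")
    path.write_text("\n".join(lines) + "\n")


def run_synthetic_demo(out_dir: str | Path, seed: int = 0) -> dict:
    """One-command demo: write synthetic inputs to disk, then run the full
    pipeline from those files (exercising the on-disk formats)."""
    out_dir = Path(out_dir)
    inputs = out_dir / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    cfg = default_synthetic_config(seed=seed)
    block = cfg.synthetic
    matrix, sheet, truth = synth_mod.generate_methylation_dataset(block.design,
                                                                  block.architecture)
    spike = synth_mod.generate_spikein_counts(block.design, block.architecture,
                                              block.n_lambda_cpgs)
    cohort = synth_mod.generate_survival_cohort(block.survival)

    # combined per-library coverage files: genome + spike-in rows
    combined = io_mod.CpGCountMatrix(
        pd.concat([matrix.sites, spike.sites]),
        pd.concat([matrix.meth, spike.meth]),
        pd.concat([matrix.total, spike.total]))
    io_mod.write_coverage_files(combined, inputs / "coverage")
    io_mod.write_sample_sheet(sheet, inputs / "samples.csv")
    cohort.to_csv(inputs / "survival.csv", index=False)
    truth_frame = pd.DataFrame({"intercept_logit": truth.intercepts,
                                "slope_logit_per_day": truth.slopes,
                                "is_clock_cpg": truth.intercepts.index.isin(truth.clock_cpg_ids)})
    truth_frame.to_csv(inputs / "ground_truth_sites.csv", index_label="site_id")
    truth.latent_age.rename("latent_age_days").to_csv(inputs / "ground_truth_latent_age.csv",
                                                      index_label="library_id")

    run_cfg = PipelineConfig(
        coverage_dir=str(inputs / "coverage"),
        sample_sheet=str(inputs / "samples.csv"),
        survival_file=str(inputs / "survival.csv"),
        output_dir=str(out_dir / "results"),
        seed=seed,
    )
    report = run_pipeline(run_cfg)
    # planted-truth comparison is re-attached for the demo (file-based runs
    # cannot see the generator's truth object)
    planted = set(truth.clock_cpg_ids)
    report["truth"] = {"n_planted_clock_cpgs": len(planted)}
    return report
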