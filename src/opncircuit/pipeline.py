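"""End-to-end orchestration of the analysis stages.

Stage order mirrors the study design: synthetic data (optional) ->
digestion-kinetics inference -> steady-state parameter derivation ->
ensemble circuit simulation -> chemotactic indices & scenario grids ->
severity modelling.  Every stage writes plain CSV into its own
subdirectory and the run ends with a manifest (file checksums + seeds)
so reruns can be verified byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .chemotaxis import cell_type_comparison, scenario_grid
from .kinetics import KineticParamSet, MCMCConfig, infer_kinetics
from .model import (SPECIES, RelapseSchedule, equilibrium_state,
                    simulate_circuit, simulate_ensemble)
from .severity import (FEATURE_SETS, apply_model_to_group_b,
                       cohort_statistics, evaluate_feature_sets,
                       fit_severity_glm, simulate_cohort_patients)
from .steady_state import patient_phase_means, sample_parameter_distributions
from .synthetic import (GeneratorConfig, generate_clinical, generate_cohort,
                        generate_digestion, generate_migration,
                        generate_msss_reference, generate_severity,
                        truth_dict)

STAGES = ("synth", "kinetics", "params", "simulate", "chemotaxis", "severity")


@dataclass
class RunConfig:
    outdir: str = "opncircuit_run"
    seed: int = 0
    synth: bool = True
    cohort_path: str | None = None
    digestion_path: str | None = None
    migration_path: str | None = None
    clinical_path: str | None = None
    severity_path: str | None = None
    x_i: float = 0.5
    x_t: float = 0.5
    n_param_draws: int = 1000
    n_ensemble: int = 200
    n_kinetic_draws: int = 200
    mcmc_n_iter: int = 50_000
    mcmc_burn_in: int = 10_000
    grid_points: int = 6
    k_folds: int = 10
    schedule_onset_h: float = 672.0
    schedule_ramp_h: float = 336.0
    schedule_plateau_h: float = 336.0
    schedule_span_h: float = 2688.0
    n_t: int = 400
    generator: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def schedule(self) -> RelapseSchedule:
        return RelapseSchedule(
            onset_time=self.schedule_onset_h,
            ramp_duration=self.schedule_ramp_h,
            plateau_duration=self.schedule_plateau_h,
            total_span=self.schedule_span_h)

    def generator_config(self) -> GeneratorConfig:
        return GeneratorConfig(seed=self.seed, **self.generator)


def _register(manifest: dict, stage: str, path: Path):
    manifest["files"][str(path.relative_to(manifest["_outdir"]))] = io.sha256(path)
    manifest["stages"].setdefault(stage, []).append(path.name)


def run_pipeline(config: RunConfig, skip_stages=(), resume: bool = False) -> dict:
    """Execute the stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "config": dataclasses.asdict(config),
                "stages": {}, "files": {}, "_outdir": outdir}
    skip = set(skip_stages)
    schedule = config.schedule()

    # ---- synth ------------------------------------------------------------
    data_dir = outdir / "data"
    synth_files = [data_dir / f"{n}.csv" for n in
                   ("cohort", "digestion", "migration", "msss_reference",
                    "clinical")]
    if resume and all(p.exists() for p in synth_files):
        for p in synth_files:
            _register(manifest, "synth", p)
        if (data_dir / "truth.yaml").exists():
            _register(manifest, "synth", data_dir / "truth.yaml")
        skip = skip | {"synth"}
    if config.synth and "synth" not in skip:
        gen = config.generator_config()
        cohort_raw = generate_cohort(gen)
        digestion = generate_digestion(gen)
        migration = generate_migration(gen)
        reference = generate_msss_reference(gen)
        clinical = generate_clinical(gen, cohort_raw)
        for name, df in (("cohort", cohort_raw), ("digestion", digestion),
                         ("migration", migration),
                         ("msss_reference", reference),
                         ("clinical", clinical)):
            _register(manifest, "synth", io.write_csv(df, data_dir / f"{name}.csv"))
        with open(data_dir / "truth.yaml", "w") as fh:
            yaml.safe_dump(truth_dict(gen), fh, sort_keys=True)
        _register(manifest, "synth", data_dir / "truth.yaml")

    cohort_path = config.cohort_path or data_dir / "cohort.csv"
    digestion_path = config.digestion_path or data_dir / "digestion.csv"
    migration_path = config.migration_path or data_dir / "migration.csv"

    cohort = io.load_cohort(cohort_path)

    # ---- kinetics ---------------------------------------------------------
    kin_dir = outdir / "kinetics"
    if resume and (kin_dir / "posterior_draws.csv").exists() \
            and (kin_dir / "point_estimate.csv").exists():
        draw_df = pd.read_csv(kin_dir / "posterior_draws.csv", float_precision="round_trip")
        kinetic_draws = [KineticParamSet.from_dict(row)
                         for row in draw_df.to_dict("records")]
        point_df = pd.read_csv(kin_dir / "point_estimate.csv", float_precision="round_trip")
        kinetics_point = KineticParamSet.from_dict(point_df.iloc[0].to_dict())
        for name in ("posterior_summary.csv", "posterior_draws.csv",
                     "point_estimate.csv"):
            _register(manifest, "kinetics", kin_dir / name)
    elif "kinetics" not in skip:
        datasets = io.load_digestion(digestion_path)
        mcmc = MCMCConfig(n_iter=config.mcmc_n_iter,
                          burn_in=config.mcmc_burn_in, seed=config.seed)
        posterior = infer_kinetics(datasets, mcmc)
        _register(manifest, "kinetics",
                  io.write_csv(posterior.summary_table(),
                               kin_dir / "posterior_summary.csv"))
        draws = posterior.draw_paramsets(config.n_kinetic_draws,
                                         seed=config.seed + 11)
        draw_df = pd.DataFrame([d.to_dict() for d in draws])
        draw_df.insert(0, "draw", np.arange(len(draws)))
        _register(manifest, "kinetics",
                  io.write_csv(draw_df, kin_dir / "posterior_draws.csv"))
        kinetics_point = posterior.map_paramset()
        _register(manifest, "kinetics",
                  io.write_csv(pd.DataFrame([kinetics_point.to_dict()]),
                               kin_dir / "point_estimate.csv"))
        kinetic_draws = draws
    else:
        raise ValueError("the kinetics stage cannot be skipped: downstream "
                         "stages need the inferred parameters")

    # ---- params -----------------------------------------------------------
    if "params" not in skip:
        ens = sample_parameter_distributions(
            cohort, kinetics_point, n_draws=config.n_param_draws,
            seed=config.seed + 23, x_i=config.x_i, x_t=config.x_t,
            kinetic_draws=kinetic_draws)
        df = ens.to_frame()
        _register(manifest, "params",
                  io.write_csv(df, outdir / "params" / "param_ensemble.csv"))
        rej = pd.DataFrame(ens.rejected, columns=["draw", "reason"])
        _register(manifest, "params",
                  io.write_csv(rej, outdir / "params" / "rejected_draws.csv"))
    else:
        ens = None

    # ---- simulate ---------------------------------------------------------
    if "simulate" not in skip and ens is not None:
        t_grid = np.linspace(0.0, schedule.total_span, config.n_t)
        n_sim = min(config.n_ensemble, len(ens.draws))
        samples = ens.draws[:n_sim]
        inits = [equilibrium_state(p) for p in samples]
        summary = simulate_ensemble(samples, inits, schedule, t_grid)
        rows = []
        for name in SPECIES:
            env = summary.envelope[name]
            for qi, q in enumerate(summary.quantiles):
                rows.append(pd.DataFrame({
                    "time_h": t_grid, "species": name,
                    "quantile": q, "value": env[qi]}))
        _register(manifest, "simulate",
                  io.write_csv(pd.concat(rows, ignore_index=True),
                               outdir / "simulate" / "ensemble_envelope.csv"))

    # ---- chemotaxis -------------------------------------------------------
    if "chemotaxis" not in skip:
        migration = io.load_migration(migration_path)
        assays = migration[migration["substrate"] != "control"]
        comparison = cell_type_comparison(assays, kinetic_draws)
        idx_rows = []
        for ct, entry in comparison.items():
            idx = entry["indices"]
            for s, v in idx.ci_opn.items():
                idx_rows.append({"cell_type": ct, "species": f"opn_{s}",
                                 "ci_median": v, "ci_low": v, "ci_high": v})
            for (s, iso), v in idx.ci_frag.items():
                if v is None:
                    continue
                idx_rows.append({
                    "cell_type": ct, "species": f"frag_{s}_{iso}",
                    "ci_median": float(np.median(v)),
                    "ci_low": float(np.quantile(v, 0.025)),
                    "ci_high": float(np.quantile(v, 0.975))})
        _register(manifest, "chemotaxis",
                  io.write_csv(pd.DataFrame(idx_rows),
                               outdir / "chemotaxis" / "indices.csv"))

        means = patient_phase_means(cohort)
        phase = means.groupby("phase")[["opn_nm", "prot_nm"]].mean()
        grid = np.linspace(0.05, 0.95, config.grid_points)
        huvec_ci = comparison["HUVEC"]["indices"]
        surface = scenario_grid(
            grid, grid,
            phase.loc["remission", "opn_nm"], phase.loc["remission", "prot_nm"],
            phase.loc["relapse", "opn_nm"], phase.loc["relapse", "prot_nm"],
            kinetics_point, huvec_ci, schedule, n_t=config.n_t)
        _register(manifest, "chemotaxis",
                  io.write_csv(surface, outdir / "chemotaxis" / "scenario_grid.csv"))
        ci_map = huvec_ci.species_map()
    else:
        ci_map = None

    # ---- severity ---------------------------------------------------------
    if "severity" not in skip:
        features = simulate_cohort_patients(
            cohort, kinetics_point, schedule,
            x_i=config.x_i, x_t=config.x_t, ci_map=ci_map)
        feat_out = features.drop(columns=["derivation_error"], errors="ignore")
        _register(manifest, "severity",
                  io.write_csv(feat_out.reset_index(),
                               outdir / "severity" / "patient_features.csv"))

        if config.severity_path:
            sev = pd.read_csv(config.severity_path, float_precision="round_trip")
        else:
            sev, _ = generate_severity(features, config.generator_config())
            _register(manifest, "severity",
                      io.write_csv(sev, data_dir / "severity.csv"))
        sev = sev.set_index("patient_id").loc[features.index]

        group_a = features[features["group"] == "A"]
        group_b = features[features["group"] == "B"]
        outcomes = sev.loc[group_a.index,
                           ["msss_relapse", "delta_msss", "msss_prime"]]
        sets = {name: cols for name, cols in FEATURE_SETS.items()
                if all(c in features.columns for c in cols)}
        r2 = evaluate_feature_sets(group_a, outcomes, seed=config.seed + 31,
                                   k_folds=config.k_folds, feature_sets=sets)
        _register(manifest, "severity",
                  io.write_csv(r2, outdir / "severity" / "r2_by_feature_set.csv"))

        fit = fit_severity_glm(group_a, outcomes["msss_prime"],
                               feature_names=sets["opn_prot_frag"],
                               k_folds=config.k_folds, seed=config.seed + 31,
                               outcome_name="msss_prime")
        coefs = fit.coefficients.rename("coefficient").reset_index()
        coefs.columns = ["feature", "coefficient"]
        _register(manifest, "severity",
                  io.write_csv(coefs, outdir / "severity" / "glm_coefficients.csv"))

        pred_b = apply_model_to_group_b(
            fit, group_b, sev.loc[group_b.index, "msss_prime"]
            if not group_b.empty else None)
        _register(manifest, "severity",
                  io.write_csv(pred_b.reset_index(),
                               outdir / "severity" / "group_b_predictions.csv"))

        cs = cohort_statistics(cohort, seed=config.seed + 41)
        stats_df = pd.DataFrame([{
            "wilcoxon_p": cs.wilcoxon_p, "wilcoxon_statistic": cs.wilcoxon_statistic,
            "correlation_opn_inv_prot": cs.correlation,
            "boot_ci_low": cs.boot_ci_low, "boot_ci_high": cs.boot_ci_high,
            "n_patients": cs.n_patients}])
        _register(manifest, "severity",
                  io.write_csv(stats_df, outdir / "severity" / "cohort_statistics.csv"))

    manifest.pop("_outdir")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
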