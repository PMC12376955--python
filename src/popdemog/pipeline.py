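"""Configuration-driven orchestration of the full analysis.

Stages: missingness filters -> admixture removal -> per-population subsetting
-> summary statistics -> simulation-based neutrality tests -> projection
search -> 1D model fits per population -> 2D fits per within-dataset pair ->
AIC comparison, plus an expansion/contraction call per population (sign of
Tajima's D combined with the best-fitting 1D model's recent/ancestral size
ratio).  Every stage's seed derives from the master seed and is logged, so a
run is reproducible end to end.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib

import numpy as np
import yaml

from . import demography, genotype_io, neutrality, optimize, sfs_builder, sumstats

__all__ = ["RunConfig", "run", "load_config"]


@dataclasses.dataclass
class RunConfig:
    """All inputs and thresholds of a pipeline run (defaults = study values)."""

    vcf: str = ""
    population_map: str = ""
    q_matrix: str | None = None
    output_dir: str = "popdemog_out"
    locus_presence: float = 0.70
    max_sample_missing: float = 0.50
    admixture_threshold: float = 0.25
    min_alleles: int = 10
    null_R: int = 1000
    null_mode: str = "fixed_S"
    models_1d: tuple[str, ...] = ("snm", "two_epoch", "three_epoch")
    models_2d: tuple[str, ...] = ("split_nomig", "split_symmig", "sec_contact")
    run_2d: bool = False
    engine_reps_1d: int = 50_000
    engine_reps_2d: int = 10_000
    optimizer_rounds: tuple[tuple[int, float, int], ...] = (
        (50, 3, 20), (50, 2, 20), (100, 1, 20)
    )
    seed: int = 0

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def load_config(path: str) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    cfg = RunConfig(**raw)
    cfg.models_1d = tuple(cfg.models_1d)
    cfg.models_2d = tuple(cfg.models_2d)
    cfg.optimizer_rounds = tuple(tuple(r) for r in cfg.optimizer_rounds)
    return cfg


def _rounds(cfg: RunConfig):
    return tuple(
        optimize.RoundConfig(replicates=r, fold=f, maxiter=m)
        for r, f, m in cfg.optimizer_rounds
    )


def _size_trajectory_call(fit: demography.ModelFit) -> str | None:
    """Expansion/contraction direction implied by a 1D model fit."""
    if fit.model == "two_epoch":
        nu = fit.params[0]
    elif fit.model == "three_epoch":
        nu = fit.params[1]  # nuF, the contemporary size
    else:
        return None
    if nu > 1:
        return "expansion"
    if nu < 1:
        return "contraction"
    return "stable"


def run(config: RunConfig) -> dict:
    """Execute the pipeline; returns the report dict (also written to disk).

    Stage failures are recorded per population and do not abort independent
    stages.
    """
    out = pathlib.Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    # one stable child seed per named stage
    stage_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("thin", "null", "fit1d", "fit2d"), ss.spawn(4)
        )
    }
    report: dict = {"config": dataclasses.asdict(config), "seeds": stage_seeds,
                    "populations": {}, "errors": {}}

    matrix = genotype_io.read_vcf(config.vcf)
    popmap = genotype_io.read_population_map(config.population_map,
                                            config.q_matrix)
    matrix = genotype_io.filter_missingness(
        matrix, config.locus_presence, config.max_sample_missing
    )
    if popmap.q_matrix is not None:
        popmap = genotype_io.remove_admixed(popmap, config.admixture_threshold)
    popmap = genotype_io.PopulationMap(
        {s: p for s, p in popmap.assignments.items() if s in matrix.sample_ids},
        popmap.q_matrix,
    )
    thinned = genotype_io.thin_one_snp_per_locus(matrix, stage_seeds["thin"])

    engine = demography.EngineConfig(
        reps_1d=config.engine_reps_1d,
        reps_2d=config.engine_reps_2d,
        seed_base=int(ss.spawn(1)[0].generate_state(1)[0] % (2**31)),
    )
    rounds = _rounds(config)
    menu = {m.name: m for m in demography.model_menu()}
    fst = sumstats.pairwise_fst_matrix(thinned, popmap)
    fst.to_csv(out / "fst_matrix.tsv", sep="\t")
    report["fst_matrix"] = fst.to_dict()

    pop_spectra: dict[str, sfs_builder.Spectrum] = {}
    for label in popmap.populations:
        entry: dict = {}
        report["populations"][label] = entry
        try:
            sub = genotype_io.subset_population(matrix, popmap, label)
        except ValueError as exc:
            report["errors"][label] = f"subset: {exc}"
            continue
        stats = sumstats.summarize_population(sub)
        stats.per_locus.to_csv(out / f"{label}_per_locus.tsv", sep="\t")
        entry["summary"] = stats.genome
        entry["neutrality"] = dict(stats.neutrality)

        d_obs = stats.neutrality["tajima_d"]
        s_obs = stats.neutrality["S"]
        if d_obs is not None and s_obs >= 1:
            tests = {}
            for stat_name in ("tajima_d", "fu_li_dstar", "fu_li_fstar"):
                observed = stats.neutrality[stat_name]
                if observed is None:
                    continue
                null = neutrality.build_null(
                    n=stats.neutrality["n_alleles"],
                    observed_S=s_obs,
                    statistic=stat_name,
                    mode=config.null_mode,
                    R=config.null_R,
                    seed=stage_seeds["null"],
                )
                tests[stat_name] = neutrality.empirical_p(observed, null)
            entry["neutrality_tests"] = tests

        sub_thin = genotype_io.subset_population(thinned, popmap, label)
        samples = sub_thin.sample_ids
        try:
            proj, seg = sfs_builder.choose_projection(
                sub_thin, [samples], config.min_alleles
            )
        except sfs_builder.ProjectionNotRunnable as exc:
            entry["runnable"] = False
            entry["projection_error"] = str(exc)
            continue
        entry["runnable"] = True
        entry["projection"] = {"alleles": proj, "segregating_sites": seg}
        spec = sfs_builder.sfs_from_matrix(sub_thin, [samples], proj)
        spec.to_file(str(out / f"{label}_sfs.txt"))
        pop_spectra[label] = spec

        fits = []
        for mname in config.models_1d:
            fit = demography.fit_model(spec, menu[mname], engine,
                                       seed=stage_seeds["fit1d"], rounds=rounds)
            fits.append(fit)
        ranking = demography.compare_models(fits)
        ranking.to_csv(out / f"{label}_fits_1d.tsv", sep="\t", index=False)
        entry["fits_1d"] = ranking.drop(columns=["params"]).to_dict("records")
        best = fits[int(np.argmin([f.aic for f in fits]))]
        entry["best_1d_model"] = best.model
        model_call = _size_trajectory_call(best)
        d_call = None
        if d_obs is not None:
            d_call = "expansion" if d_obs < 0 else "contraction" if d_obs > 0 else None
        entry["demographic_call"] = {
            "tajima_d_sign": d_call,
            "best_1d_model_direction": model_call,
            "call": model_call or d_call,
        }

    if config.run_2d:
        labels = [l for l in popmap.populations if l in pop_spectra]
        report["pairs"] = {}
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                key = f"{la}__{lb}"
                sa = [s for s in popmap.samples_in(la) if s in thinned.sample_ids]
                sb = [s for s in popmap.samples_in(lb) if s in thinned.sample_ids]
                try:
                    proj, seg = sfs_builder.choose_projection(
                        thinned, [sa, sb], config.min_alleles
                    )
                except sfs_builder.ProjectionNotRunnable as exc:
                    report["pairs"][key] = {"runnable": False, "error": str(exc)}
                    continue
                spec2 = sfs_builder.sfs_from_matrix(thinned, [sa, sb], proj)
                fits = [
                    demography.fit_model(spec2, menu[mname], engine,
                                         seed=stage_seeds["fit2d"], rounds=rounds)
                    for mname in config.models_2d
                ]
                ranking = demography.compare_models(fits)
                ranking.to_csv(out / f"{key}_fits_2d.tsv", sep="\t", index=False)
                report["pairs"][key] = {
                    "runnable": True,
                    "projection": list(proj),
                    "ranking": ranking.drop(columns=["params"]).to_dict("records"),
                }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)
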