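"""End-to-end pipeline orchestration.

Runs simulate -> harmonize -> brain-age/BAG -> sCCA -> group models ->
spatial decoding from a single YAML config, with per-stage seeds, a JSON
run manifest (config hash, output checksums, wall times) and optional
resume from existing stage outputs. Stages communicate only through
serialized artifacts (TSV/JSON) in the output directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tractage import brainage, decode, groupstats, harmonize, scca, simulate

__all__ = ["default_config", "load_config", "run_pipeline", "plan"]

STAGES = ("simulate", "harmonize", "brainage", "scca", "group_models", "decode")


def default_config() -> dict:
    """Default run configuration (moderate sizes for a single-CPU demo run)."""
    return {
        "seed": 0,
        "outdir": "tractage_run",
        "stages": {s: True for s in STAGES},
        "cohort": {"n_subjects": 500},
        "harmonize": {"eb": True},
        "brainage": {
            # one representative bilateral pair per tract system + whole-brain
            "tracts": ["AF", "IFOF", "C_FP", "CST", "TR_A", "CS_A", "CC_Body"],
            "whole_brain": True,
            "kfold": 5,
            "n_restarts": 1,
        },
        "scca": {
            "n_modes": 2,
            "grid": False,
            "c1": 1.0,
            "c2": 1.0,
            "n_perm": 100,
            "n_boot": 100,
        },
        "group_models": {"n_behaviors": 10, "gam_outcomes": 3},
        "decode": {"n_surr": 200, "shape": [24, 24, 24], "prob_threshold": 0.5},
        "resume": False,
    }


def load_config(path) -> dict:
    cfg = default_config()
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def plan(config: dict) -> list[str]:
    """Ordered list of stages that would run under this config."""
    return [s for s in STAGES if config["stages"].get(s, False)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: dict) -> str:
    # hash the scientific configuration only, not where it is written
    core = {k: v for k, v in config.items() if k not in ("outdir", "resume")}
    return hashlib.sha256(
        json.dumps(core, sort_keys=True, default=str).encode()
    ).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index=True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: dict | str | Path, dry_run: bool = False) -> dict:
    """Execute the configured stages in dependency order; return the manifest.

    A stage failure halts the run; the manifest records the stages
    completed up to that point. With ``resume=True`` in the config, a
    stage whose output files already exist is skipped.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    stages = plan(config)
    if dry_run:
        return {"plan": stages, "config_hash": _config_hash(config)}

    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
        "outputs": {},
    }
    runners = {
        "simulate": _stage_simulate,
        "harmonize": _stage_harmonize,
        "brainage": _stage_brainage,
        "scca": _stage_scca,
        "group_models": _stage_group_models,
        "decode": _stage_decode,
    }
    expected = {
        "simulate": ["cohort.tsv", "behavior.tsv", "diagnoses.tsv",
                     "profiles.tsv", "puberty_hormones.tsv",
                     "cohort_config.yaml"],
        "harmonize": ["profiles_harmonized.tsv", "combat_model.json"],
        "brainage": ["bag_table.tsv", "brainage_performance.tsv"],
        "scca": ["scca_loadings_x.tsv", "scca_loadings_y.tsv",
                 "scca_model.json"],
        "group_models": ["glm_bag_behavior.tsv", "glm_groups.tsv",
                         "glm_groups_posthoc.tsv", "gam_delta_r2.tsv",
                         "lmm_developmental.tsv",
                         "effect_pattern_similarity.json"],
        "decode": ["decode_profiles.tsv", "decode_results.tsv",
                   "network_overlap.tsv"],
    }
    for name in STAGES:
        if name not in stages:
            manifest["stages"][name] = {"status": "skipped"}
            continue
        if config.get("resume") and all(
            (outdir / f).exists() for f in expected[name]
        ):
            manifest["stages"][name] = {"status": "cached"}
            manifest["outputs"].update(
                {f: _sha256(outdir / f) for f in expected[name]}
            )
            continue
        t0 = time.perf_counter()
        try:
            outputs = runners[name](config, outdir)
        except Exception as exc:  # halt, but leave a complete manifest
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, outdir)
            raise
        elapsed = time.perf_counter() - t0
        checks = {str(p.name): _sha256(p) for p in outputs}
        manifest["stages"][name] = {
            "status": "done",
            "wall_time_s": round(elapsed, 3),
        }
        manifest["outputs"].update(checks)
    _write_manifest(manifest, outdir)
    return manifest


def _write_manifest(manifest: dict, outdir: Path) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _stage_seed(config: dict, stage: str) -> int:
    offset = {s: i for i, s in enumerate(STAGES)}[stage]
    return int(config["seed"]) * 10 + offset


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config: dict, outdir: Path) -> list[Path]:
    cc = simulate.CohortConfig(**config.get("cohort", {}),
                               seed=_stage_seed(config, "simulate"))
    cohort, profiles, behavior, diagnoses = simulate.simulate_cohort(cc)
    ph = simulate.simulate_puberty_hormones(cohort, cc)
    paths = {
        "cohort.tsv": cohort,
        "behavior.tsv": behavior,
        "diagnoses.tsv": diagnoses,
    }
    out = []
    for name, df in paths.items():
        _write_tsv(df, outdir / name)
        out.append(outdir / name)
    simulate.write_profiles(profiles, outdir / "profiles.tsv")
    out.append(outdir / "profiles.tsv")
    _write_tsv(ph, outdir / "puberty_hormones.tsv", index=False)
    out.append(outdir / "puberty_hormones.tsv")
    simulate.write_config(cc, outdir / "cohort_config.yaml")
    out.append(outdir / "cohort_config.yaml")
    return out


def _load_inputs(outdir: Path):
    cohort = simulate.read_cohort(outdir / "cohort.tsv")
    profiles = simulate.read_profiles(outdir / "profiles.tsv")
    behavior = pd.read_csv(outdir / "behavior.tsv", sep="\t", index_col=0)
    diagnoses = pd.read_csv(outdir / "diagnoses.tsv", sep="\t", index_col=0)
    return cohort, profiles, behavior, diagnoses


def _stage_harmonize(config: dict, outdir: Path) -> list[Path]:
    cohort, profiles, _, diagnoses = _load_inputs(outdir)
    # biological covariates to preserve: age, sex and the diagnosis-count
    # class encoded as two dummy columns
    diag = diagnoses.loc[profiles.index, "diagnosis_count_baseline"]
    covs = np.column_stack(
        [
            cohort.loc[profiles.index, "age"],
            cohort.loc[profiles.index, "sex"],
            (diag == 1).astype(float),
            (diag >= 2).astype(float),
        ]
    )
    model = harmonize.fit_combat(
        profiles,
        site=cohort.loc[profiles.index, "site"].to_numpy(),
        covariates=covs,
        eb=config["harmonize"].get("eb", True),
    )
    harmonized = harmonize.apply_combat(
        model, profiles, site=cohort.loc[profiles.index, "site"].to_numpy(),
        covariates=covs,
    )
    simulate.write_profiles(harmonized, outdir / "profiles_harmonized.tsv")
    model.to_json(outdir / "combat_model.json")
    return [outdir / "profiles_harmonized.tsv", outdir / "combat_model.json"]


def _stage_brainage(config: dict, outdir: Path) -> list[Path]:
    cohort, _, _, _ = _load_inputs(outdir)
    profiles = simulate.read_profiles(outdir / "profiles_harmonized.tsv")
    ages = cohort.loc[profiles.index, "age"].to_numpy()
    bcfg = config["brainage"]
    seed = _stage_seed(config, "brainage")
    tables, perf_rows = [], []
    targets: list[str | None] = list(bcfg.get("tracts", []))
    if bcfg.get("whole_brain", True):
        targets.append(None)
    for tract in targets:
        table, perf = brainage.crossval_bag_table(
            profiles,
            ages,
            tract,
            k=bcfg.get("kfold", 5),
            seed=seed,
            n_restarts=bcfg.get("n_restarts", 1),
        )
        tables.append(table)
        perf_rows.append(
            {"tract": table["tract"].iloc[0], **perf.to_dict()}
        )
    bag = pd.concat(tables, ignore_index=True)
    _write_tsv(bag, outdir / "bag_table.tsv", index=False)
    _write_tsv(pd.DataFrame(perf_rows), outdir / "brainage_performance.tsv",
               index=False)
    return [outdir / "bag_table.tsv", outdir / "brainage_performance.tsv"]


def _bag_matrix(outdir: Path) -> pd.DataFrame:
    bag = pd.read_csv(outdir / "bag_table.tsv", sep="\t")
    return bag.pivot(index="subject_id", columns="tract", values="bag_corrected")


def _stage_scca(config: dict, outdir: Path) -> list[Path]:
    cohort, _, behavior, _ = _load_inputs(outdir)
    X = _bag_matrix(outdir)
    Y = behavior.loc[X.index]
    covs = cohort.loc[X.index, ["age", "sex"]].to_numpy()
    Xr = scca.residualize(X, covs)
    Yr = scca.residualize(Y, covs)
    scfg = config["scca"]
    seed = _stage_seed(config, "scca")
    if scfg.get("grid", False):
        c1, c2 = scca.grid_search_sparsity(Xr, Yr, seed=seed)
    else:
        c1, c2 = scfg.get("c1", 1.0), scfg.get("c2", 1.0)
    sign_block = np.array([c.startswith("cog") for c in Y.columns])
    model = scca.SparseCCA(
        n_modes=scfg.get("n_modes", 2), c1=c1, c2=c2, sign_block=sign_block
    ).fit(Xr, Yr)
    perm = scca.permutation_test_modes(
        Xr, Yr, model, n_perm=scfg.get("n_perm", 100), seed=seed
    )
    boot = scca.bootstrap_loadings(
        Xr, Yr, model, n_boot=scfg.get("n_boot", 100), seed=seed
    )
    spec = scca.mode_specificity(boot["boot_y"])

    modes = [f"mode_{k + 1}" for k in range(model.n_modes)]
    x_load = pd.DataFrame(model.x_loadings_, index=X.columns, columns=modes)
    x_load[[f"weight_{m}" for m in modes]] = model.u_
    for k, m in enumerate(modes):
        x_load[f"sig_{m}"] = boot["x_significant"][:, k]
    y_load = pd.DataFrame(model.y_loadings_, index=Y.columns, columns=modes)
    y_load[[f"weight_{m}" for m in modes]] = model.v_
    for k, m in enumerate(modes):
        y_load[f"sig_{m}"] = boot["y_significant"][:, k]
        y_load[f"specific_{m}"] = spec["specific"][:, k]
    _write_tsv(x_load, outdir / "scca_loadings_x.tsv")
    _write_tsv(y_load, outdir / "scca_loadings_y.tsv")
    summary = {
        "c1": float(c1),
        "c2": float(c2),
        "canonical_R": model.R_.tolist(),
        "p": perm["p"].tolist(),
        "p_fdr": perm["p_fdr"].tolist(),
        "n_perm": int(scfg.get("n_perm", 100)),
        "n_boot": int(scfg.get("n_boot", 100)),
    }
    with open(outdir / "scca_model.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return [
        outdir / "scca_loadings_x.tsv",
        outdir / "scca_loadings_y.tsv",
        outdir / "scca_model.json",
    ]


def _stage_group_models(config: dict, outdir: Path) -> list[Path]:
    cohort, _, behavior, diagnoses = _load_inputs(outdir)
    X = _bag_matrix(outdir)
    age = cohort.loc[X.index, "age"].to_numpy()
    sex = cohort.loc[X.index, "sex"].to_numpy()
    gcfg = config["group_models"]

    # BAG x behavior GLM family with FDR over all tested pairs
    behav_cols = list(behavior.columns[: gcfg.get("n_behaviors", 10)])
    rows = []
    for tract in X.columns:
        for col in behav_cols:
            r = groupstats.glm_bag_behavior(
                X[tract].to_numpy(), behavior.loc[X.index, col].to_numpy(),
                age, sex, outcome_id=tract, predictor_id=col,
            )
            rows.append({"tract": tract, "behavior": col, "coef": r.coef,
                         "t": r.stat, "p": r.p})
    assoc = pd.DataFrame(rows)
    assoc["p_fdr"] = groupstats.bh_fdr(assoc["p"].to_numpy())
    _write_tsv(assoc, outdir / "glm_bag_behavior.tsv", index=False)

    # diagnosis-count and transition group effects with Tukey post-hocs
    grp_rows, posthoc_rows = [], []
    factors = {
        "count_baseline": diagnoses.loc[X.index, "diagnosis_count_baseline"],
        "count_followup": diagnoses.loc[X.index, "diagnosis_count_followup"],
        "transition": diagnoses.loc[X.index, "transition"],
    }
    for fname, factor in factors.items():
        for tract in X.columns:
            r = groupstats.glm_group_effect(
                X[tract].to_numpy(), factor.to_numpy(), age, sex,
                outcome_id=tract, predictor_id=fname,
            )
            grp_rows.append({"tract": tract, "factor": fname, "F": r.stat,
                             "df_num": r.df[0], "df_den": r.df[1], "p": r.p})
            ph = r.posthoc.copy()
            ph.insert(0, "factor", fname)
            ph.insert(0, "tract", tract)
            posthoc_rows.append(ph)
    groups_df = pd.DataFrame(grp_rows)
    groups_df["p_fdr"] = groupstats.bh_fdr(groups_df["p"].to_numpy())
    _write_tsv(groups_df, outdir / "glm_groups.tsv", index=False)
    _write_tsv(pd.concat(posthoc_rows, ignore_index=True),
               outdir / "glm_groups_posthoc.tsv", index=False)

    # GAM incremental variance for follow-up cognition stand-ins
    gam_rows = []
    for col in behavior.columns[: gcfg.get("gam_outcomes", 3)]:
        for tract in X.columns:
            g = groupstats.gam_delta_r2(
                behavior.loc[X.index, col].to_numpy(), X[tract].to_numpy(),
                age, sex, outcome_id=col, predictor_id=tract,
            )
            gam_rows.append({"outcome": col, "tract": tract, "F": g.f_stat,
                             "delta_r2_pct": g.delta_r2_pct, "p": g.p})
    gam_df = pd.DataFrame(gam_rows)
    gam_df["p_fdr"] = groupstats.bh_fdr(gam_df["p"].to_numpy())
    _write_tsv(gam_df, outdir / "gam_delta_r2.tsv", index=False)

    # developmental LMMs: pubertal stage and hormones, two visits
    ph = pd.read_csv(outdir / "puberty_hormones.tsv", sep="\t")
    wb = _bag_matrix(outdir)["whole-brain"] if "whole-brain" in X.columns else X.iloc[:, 0]
    ph = ph[ph["subject_id"].isin(wb.index)].copy()
    ph["bag"] = wb.loc[ph["subject_id"]].to_numpy()
    ph["timepoint"] = (ph["visit"] == "followup2y").astype(float)
    ph["stage"] = [
        PDS_ORDER[groupstats.pds_categorize(s, t, m)]
        for s, t, m in zip(ph["sex"], ph["pds_sum"], ph["menarche"])
    ]
    lmm_rows = []
    r = groupstats.lmm_developmental(
        ph["bag"], ph["stage"], ph["age"], ph["sex"], ph["timepoint"],
        ph["subject_id"], predictor_id="pds_stage",
    )
    lmm_rows.append({"predictor": "pds_stage", "coef": r.coef, "t": r.stat,
                     "df": r.df, "p": r.p, "re_var": r.re_variance,
                     "singular": r.singular})
    extra = {k: ph[k] for k in ["caffeine_intake", "physical_activity",
                                "collection_time", "collection_duration",
                                "freeze_time"]}
    for hormone in ["dhea", "testosterone", "estradiol"]:
        r = groupstats.lmm_developmental(
            ph["bag"], ph[hormone], ph["age"], ph["sex"], ph["timepoint"],
            ph["subject_id"], extra_covariates=extra, predictor_id=hormone,
        )
        lmm_rows.append({"predictor": hormone, "coef": r.coef, "t": r.stat,
                         "df": r.df, "p": r.p, "re_var": r.re_variance,
                         "singular": r.singular})
    lmm_df = pd.DataFrame(lmm_rows)
    lmm_df["p_fdr"] = groupstats.bh_fdr(lmm_df["p"].to_numpy())
    _write_tsv(lmm_df, outdir / "lmm_developmental.tsv", index=False)

    # FA-vs-BAG effect-pattern comparison across tracts (first behavior)
    col = behav_cols[0]
    profiles = simulate.read_profiles(outdir / "profiles_harmonized.tsv")
    t_bag, t_fa = [], []
    for tract in X.columns:
        if tract == "whole-brain":
            continue
        fa_mean = brainage.assemble_features(profiles, tract).mean(axis=1)
        t_bag.append(groupstats.glm_bag_behavior(
            X[tract].to_numpy(), behavior.loc[X.index, col].to_numpy(),
            age, sex).stat)
        t_fa.append(groupstats.glm_bag_behavior(
            fa_mean.loc[X.index].to_numpy(),
            behavior.loc[X.index, col].to_numpy(), age, sex).stat)
    if len(t_bag) >= 5:
        rho, p = groupstats.effect_pattern_similarity(t_bag, t_fa)
        payload = {"behavior": col, "rho": rho, "p": p, "n_tracts": len(t_bag)}
    else:  # too few tract models configured for a rank comparison
        payload = {"behavior": col, "rho": None, "p": None,
                   "n_tracts": len(t_bag)}
    with open(outdir / "effect_pattern_similarity.json", "w") as fh:
        json.dump(payload, fh, indent=2)

    return [outdir / "glm_bag_behavior.tsv", outdir / "glm_groups.tsv",
            outdir / "glm_groups_posthoc.tsv", outdir / "gam_delta_r2.tsv",
            outdir / "lmm_developmental.tsv",
            outdir / "effect_pattern_similarity.json"]


PDS_ORDER = {s: i + 1 for i, s in enumerate(groupstats.PDS_STAGES)}


def _stage_decode(config: dict, outdir: Path) -> list[Path]:
    dcfg = config["decode"]
    seed = _stage_seed(config, "decode")
    x_load = pd.read_csv(outdir / "scca_loadings_x.tsv", sep="\t", index_col=0)
    tract_names = [t for t in x_load.index if t != "whole-brain"]
    loadings = x_load.loc[tract_names, "mode_1"].to_numpy()

    atlas = decode.demo_atlas(
        n_tracts=len(tract_names), shape=tuple(dcfg.get("shape", [24, 24, 24])),
        seed=seed,
    )
    atlas.volumes = dict(zip(tract_names, atlas.volumes.values()))
    rng = np.random.default_rng(seed + 1)
    shape = atlas.shape
    grad = np.linspace(0, 1, shape[0])[:, None, None] * np.ones(shape)
    maps = {
        "CI": 2.0 + grad + 0.1 * rng.random(shape),
        "CII": 1.5 + 0.5 * grad + 0.1 * rng.random(shape),
        "CIV": 1.0 + 0.8 * grad + 0.1 * rng.random(shape),
        "MitoD": 0.5 + 0.4 * grad + 0.05 * rng.random(shape),
    }
    trc, mrc = decode.derive_trc_mrc(
        maps["CI"], maps["CII"], maps["CIV"], maps["MitoD"]
    )
    maps["TRC"], maps["MRC"] = trc, mrc

    thr = dcfg.get("prob_threshold", 0.5)
    profiles = {
        name: decode.tract_map_profile(vol, atlas, prob_threshold=thr)
        for name, vol in maps.items()
    }
    prof_df = pd.DataFrame({name: p["z"] for name, p in profiles.items()})
    _write_tsv(prof_df, outdir / "decode_profiles.tsv")

    dist = atlas.distance_matrix(prob_threshold=thr).to_numpy()
    rows = []
    observed, nulls = [], []
    for name, p in profiles.items():
        rho = decode.spearman_decode(loadings, p["z"].to_numpy())
        surr = decode.variogram_surrogates(
            p["z"].to_numpy(), dist, n_surr=dcfg.get("n_surr", 200), seed=seed
        )
        null_rho = np.array(
            [decode.spearman_decode(loadings, s) for s in surr]
        )
        observed.append(rho)
        nulls.append(null_rho)
        rows.append({"map": name, "rho": rho})
    pv = decode.surrogate_pvalue(np.array(observed), np.column_stack(nulls))
    res = pd.DataFrame(rows)
    res["p"] = pv["p"]
    res["p_fdr"] = pv["p_fdr"]
    _write_tsv(res, outdir / "decode_results.tsv", index=False)

    parc = rng.integers(1, 8, size=shape)
    props = decode.network_overlap_proportions(atlas, parc, prob_threshold=thr)
    _write_tsv(props.to_frame("proportion"), outdir / "network_overlap.tsv")
    return [outdir / "decode_profiles.tsv", outdir / "decode_results.tsv",
            outdir / "network_overlap.tsv"]
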