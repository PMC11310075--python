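"""End-to-end study orchestration from a single config.

Runs, in order: the BBM model fits (single, multiple-slopes, quadratic) →
evidence table with Bayes factors against the single-slope baseline → the
variable-rates run on the quadratic model → median rate-scaled tree and
pathwise rates → trend regressions (overall and per group) → a body-only
variable-rates run → ancestral imputation of body then brain mass →
branchwise change decomposition → ANCOVA + Tukey letters. Every artifact is
plain text (Newick / CSV / JSON) under the output directory, and a run
manifest records the config snapshot, seeds, diagnostics and file
inventory.

The expensive stage (the variable-rates posterior) can be resumed from its
on-disk samples with ``resume=True``; cheap stages recompute.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import allometry, branchwise, evidence, phylo_gls, synthgen, treeio, trends

_version = "0.1.0"
from .varrates import (MCMCSettings, RatePosterior, VarRatesPriors,
                       fit_variable_rates, mean_scaled_tree,
                       median_scaled_tree)

__all__ = ["RunManifest", "run_study", "load_config", "DEFAULT_STUDY_CONFIG"]


DEFAULT_STUDY_CONFIG = {
    "seed": 0,
    # either a synth block, or tree/traits paths (+ optional schema)
    "synth": None,
    "tree": None,
    "traits": None,
    "schema": None,
    "min_group_size": 20,
    "mcmc": {"n_iter": 40_000, "burn_frac": 0.25, "thin": 20, "n_chains": 2},
    "evidence": {"stones": 0, "iters": 20_000},   # stones=0: closed-form only
    "trend_per_group": True,
    "ancova_include_ancestor": True,
    "n_samples": 2000,
}


def load_config(source) -> dict:
    if isinstance(source, dict):
        return source
    import yaml
    with open(source) as fh:
        return yaml.safe_load(fh)


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    stages: dict = field(default_factory=dict)     # stage -> status/info
    diagnostics: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def to_json(self) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {k: clean(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            return o
        return json.dumps(clean(asdict(self)), indent=2, sort_keys=True)


def _merge(base, over):
    out = dict(base)
    for k, v in (over or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = {**out[k], **v}
        else:
            out[k] = v
    return out


def _posterior_to_files(post: RatePosterior, stem: Path):
    df = post.to_frame()
    df.to_csv(stem.with_suffix(".params.tsv"), sep="\t", index=False)
    rdf = pd.DataFrame(post.samples_r,
                       columns=[f"b{int(b)}" for b in post.branches])
    rdf.to_csv(stem.with_suffix(".rates.tsv"), sep="\t", index=False,
               float_format="%.6g")


def _posterior_from_files(stem: Path, settings, priors) -> RatePosterior:
    df = pd.read_csv(stem.with_suffix(".params.tsv"), sep="\t")
    rdf = pd.read_csv(stem.with_suffix(".rates.tsv"), sep="\t")
    names = [c for c in df.columns
             if c not in ("sigma2_b", "log_ml", "n_shifts", "chain")]
    branches = np.array([int(c[1:]) for c in rdf.columns])
    return RatePosterior(
        names=names, branches=branches, samples_r=rdf.to_numpy(float),
        samples_beta=df[names].to_numpy(float),
        samples_sigma2=df["sigma2_b"].to_numpy(float),
        samples_logml=df["log_ml"].to_numpy(float),
        samples_k=df["n_shifts"].to_numpy(np.int64),
        chain_id=df["chain"].to_numpy(np.int64),
        settings=settings, priors=priors, diagnostics={}, converged=True)


def run_study(config, out_dir, resume: bool = False) -> RunManifest:
    """Execute the full analysis described by ``config``; see
    ``DEFAULT_STUDY_CONFIG`` for keys. Returns the run manifest (also
    written to ``manifest.json``)."""
    cfg = _merge(DEFAULT_STUDY_CONFIG, load_config(config))
    if cfg["synth"] is None and (cfg["tree"] is None or cfg["traits"] is None):
        raise ValueError("config must provide either a 'synth' block or "
                         "'tree' and 'traits' paths")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(config=cfg, seed=seed, version=_version)

    def done(stage, **info):
        manifest.stages[stage] = {"status": "ok", **info}

    def emit(name):
        manifest.outputs.append(name)

    try:
        # -- stage: data -----------------------------------------------
        if cfg["synth"] is not None:
            synth_cfg = dict(cfg["synth"])
            synth_cfg.setdefault("seed", seed)
            tree, table, truth, nodes_truth = synthgen.generate_study(
                synth_cfg, out_dir=out)
            emit("tree.nwk"); emit("traits.csv"); emit("truth.json")
            done("data", source="synthetic", n_tips=tree.n_tips)
        else:
            with open(cfg["tree"]) as fh:
                text = fh.read()
            tree = (treeio.read_nexus(text) if text.lstrip().lower()
                    .startswith("#nexus") else treeio.read_newick(text))
            raw = treeio.read_trait_table(cfg["traits"],
                                          schema=cfg.get("schema"))
            tree, table, report = treeio.match_and_prune(tree, raw, seed)
            truth = None
            done("data", source=str(cfg["traits"]), n_tips=tree.n_tips,
                 dropped_tips=len(report["dropped_tips"]))
        tree2, table, _ = treeio.match_and_prune(tree, table, seed)
        tree = tree2

        mg = int(cfg["min_group_size"])
        n_samp = int(cfg["n_samples"])

        # -- stage: ML fits --------------------------------------------
        fits = {}
        specs = {
            "single": allometry.AllometryModelSpec("single"),
            "quadratic": allometry.AllometryModelSpec("quadratic",
                                                      min_group_size=mg),
        }
        try:
            specs["multiple-slopes"] = allometry.AllometryModelSpec(
                "multiple-slopes", min_group_size=mg)
            fits["multiple-slopes"] = allometry.fit_bbm(
                tree, table, specs["multiple-slopes"], engine="ml")
        except ValueError as exc:
            manifest.stages["fit:multiple-slopes"] = {
                "status": "skipped", "reason": str(exc)}
        for v in ("single", "quadratic"):
            fits[v] = allometry.fit_bbm(tree, table, specs[v], engine="ml")
        with open(out / "fits_ml.txt", "w") as fh:
            for v, f in fits.items():
                fh.write(f"== {v} ==\n{f.result.summary()}\n\n")
        emit("fits_ml.txt")
        done("fits_ml", r2={v: round(f.r2, 4) for v, f in fits.items()})

        # -- stage: evidence -------------------------------------------
        rows = []
        for v, f in fits.items():
            info = f.design
            sub = table.loc[info.retained].reset_index(drop=True)
            sub_tree = (tree if info.retained.all()
                        else treeio.prune_to_tips(tree, sub["species"]))
            lm = phylo_gls.gls_log_evidence(
                sub_tree, info.X, sub["log_brain"].to_numpy(float),
                sub_tree.length)
            rows.append({"model": v, "log_ml": lm, "method": "closed-form",
                         "n": int(info.retained.sum())})
        stones = int(cfg["evidence"]["stones"])
        if stones > 0:
            ss_model = evidence.VariableRatesEvidence(
                tree, fits["quadratic"].design.X,
                table["log_brain"].to_numpy(float))
            ml = evidence.stepping_stone(ss_model, stones=stones,
                                         iters=int(cfg["evidence"]["iters"]),
                                         seed=seed)
            rows.append({"model": "quadratic+variable-rates",
                         "log_ml": ml.log_ml,
                         "method": f"stepping-stone({stones})",
                         "n": tree.n_tips})
        ev = pd.DataFrame(rows)
        base = ev.loc[ev["model"] == "single", "log_ml"].iloc[0]
        ev["bf_vs_single"] = [evidence.bayes_factor(v, base)
                              for v in ev["log_ml"]]
        ev.to_csv(out / "evidence.csv", index=False)
        emit("evidence.csv")
        done("evidence", best=str(ev.loc[ev["log_ml"].idxmax(), "model"]))

        # -- stage: variable rates on the quadratic model --------------
        mcfg = cfg["mcmc"]
        settings = MCMCSettings(n_iter=int(mcfg["n_iter"]),
                                burn_frac=float(mcfg["burn_frac"]),
                                thin=int(mcfg["thin"]),
                                n_chains=int(mcfg["n_chains"]), seed=seed)
        priors = VarRatesPriors()
        stem = out / "varrates_brain"
        if resume and stem.with_suffix(".params.tsv").exists():
            post = _posterior_from_files(stem, settings, priors)
            done("varrates", resumed=True)
        else:
            bbm_bayes = allometry.fit_bbm(tree, table, specs["quadratic"],
                                          engine="variable-rates",
                                          priors=priors, settings=settings,
                                          seed=seed)
            post = bbm_bayes.result
            _posterior_to_files(post, stem)
            done("varrates", resumed=False, converged=post.converged,
                 **{k: round(v, 4) for k, v in post.diagnostics.items()
                    if np.isfinite(v)})
        emit("varrates_brain.params.tsv"); emit("varrates_brain.rates.tsv")
        manifest.diagnostics["varrates_brain"] = {
            k: float(v) for k, v in post.diagnostics.items()}
        quad_fit = allometry.fit_bbm(tree, table, specs["quadratic"],
                                     engine="bayes", n_samples=n_samp,
                                     seed=seed)
        # report the rate-heterogeneous posterior as the headline BBM fit
        quad_vr = allometry.BBMFit(
            specs["quadratic"], post.names,
            allometry._uncenter(np.median(post.samples_beta, axis=0),
                                post.names, quad_fit.design.x_mean),
            "variable-rates", quad_fit.design, post,
            allometry._uncenter(post.samples_beta, post.names,
                                quad_fit.design.x_mean),
            quad_fit.r2, table)

        # -- stage: scaled tree + pathwise rates -----------------------
        scaled = median_scaled_tree(post, tree)       # display convention
        treeio.write_newick(scaled, out / "scaled_tree.nwk")
        emit("scaled_tree.nwk")
        scaled_mean = mean_scaled_tree(post, tree)    # analysis substrate
        pw = trends.posterior_pathwise_rates(post, tree, summary="mean")
        pw.to_csv(out / "pathwise.csv", index=False)
        emit("pathwise.csv")
        done("scaled_tree", max_r=float(post.median_r().max()))

        # -- stage: trends ---------------------------------------------
        rel = trends.relative_brain(table, quad_vr)
        trend_rows = []
        try:
            common = trends.trend_regression(rel, pw, None, scaled_mean,
                                             per_group=False,
                                             n_samples=n_samp, seed=seed)
            trend_rows.append(common.table)
            if cfg["trend_per_group"] and table["group"].nunique() > 1:
                per = trends.trend_regression(rel, pw, table["group"],
                                              scaled_mean, per_group=True,
                                              min_group_size=mg,
                                              n_samples=n_samp, seed=seed)
                trend_rows.append(per.table)
            tr = pd.concat(trend_rows, ignore_index=True)
            tr.to_csv(out / "trends.csv", index=False)
            emit("trends.csv")
            done("trends", overall_slope=float(trend_rows[0]["slope"].iloc[0]))
        except ValueError as exc:
            manifest.stages["trends"] = {"status": "skipped",
                                         "reason": str(exc)}
            tr = pd.DataFrame()

        # -- stage: body-only variable rates + imputation --------------
        stem_b = out / "varrates_body"
        Xb = np.ones((tree.n_tips, 1))
        if resume and stem_b.with_suffix(".params.tsv").exists():
            post_body = _posterior_from_files(stem_b, settings, priors)
        else:
            post_body = fit_variable_rates(
                tree, Xb, table["log_body"].to_numpy(float), priors,
                settings, ["mean_body"])
            _posterior_to_files(post_body, stem_b)
        emit("varrates_body.params.tsv"); emit("varrates_body.rates.tsv")

        body_imp = branchwise.impute_ancestral_body(tree, post_body, table)
        trend_slopes = {}
        common_trend = 0.0
        if len(tr):
            for _, row in tr.iterrows():
                if row["group"] == "all":
                    common_trend = float(row["slope"])
                elif row["group"] != "rest":
                    trend_slopes[row["group"]] = float(row["slope"])
        brain_imp = branchwise.impute_ancestral_brain(
            tree, body_imp["node_body"], quad_vr, post, table,
            trend_slopes=trend_slopes, common_trend=common_trend)
        nodes = pd.DataFrame({
            "node": np.arange(tree.n_nodes),
            "log_body": body_imp["node_body"],
            "log_brain": brain_imp["node_brain"],
            "pathwise_brain": brain_imp["node_pathwise"],
            "pathwise_body": body_imp["node_pathwise"],
            "group": brain_imp["node_group"],
            "is_tip": np.isin(np.arange(tree.n_nodes), tree.tip_indices),
        })
        nodes.to_csv(out / "nodes.csv", index=False)
        emit("nodes.csv")
        done("imputation", alpha=body_imp["alpha"],
             beta_pathwise=body_imp["beta_pathwise"])

        # -- stage: branch changes + ANCOVA ----------------------------
        med_r = np.ones(tree.n_nodes)
        med_r[post.branches] = post.median_r()
        changes = branchwise.branch_changes(
            tree, brain_imp["node_brain"], body_imp["node_body"],
            groups=brain_imp["node_group"], rate_scalars=med_r)
        changes.to_csv(out / "branch_changes.csv", index=False)
        emit("branch_changes.csv")
        summary = branchwise.group_change_summary(changes)
        summary.to_csv(out / "group_change_summary.csv", index=False)
        emit("group_change_summary.csv")
        if changes["group"].notna().any() and table["group"].nunique() > 1:
            anc = branchwise.ancova_tukey(
                changes, include_ancestor=bool(cfg["ancova_include_ancestor"]))
            with open(out / "ancova.txt", "w") as fh:
                fh.write(f"group factor p = {anc.group_p:.3g}\n")
                fh.write("adjusted means:\n")
                fh.write(anc.adjusted_means.to_string() + "\n")
                fh.write("letters: " + json.dumps(anc.letters) + "\n")
                fh.write(anc.pairwise.to_string(index=False) + "\n")
            emit("ancova.txt")
            done("ancova", group_p=anc.group_p, letters=anc.letters)
        else:
            manifest.stages["ancova"] = {"status": "skipped",
                                         "reason": "fewer than two groups"}
        done("branch_changes", n_branches=len(changes))
    except Exception as exc:
        stage = max(manifest.stages) if manifest.stages else "data"
        manifest.stages["__error__"] = {"status": "failed",
                                        "after_stage": stage,
                                        "error": repr(exc)}
        (out / "manifest.json").write_text(manifest.to_json() + "\n")
        raise
    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    emit("manifest.json")
    return manifest
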