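"""Config-driven pipeline runner.

A YAML config declares stages, parameters, seeds and input paths; every
stage reads and writes plain CSV/JSON intermediates in the output
directory, so each subcommand is runnable standalone on saved files.  A
plain-text run log records the config hash and every stage seed; reruns
with the same config produce byte-identical outputs.

Stages: simulate, preprocess, fit, permtest, bootstrap, project, stats,
surrogate, classify, report.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .datatypes import CohortTable, align
from .errors import ConfigurationError
from .harmonize import apply_combat, fit_combat
from .inference import bootstrap_loadings, permutation_test
from .pls import PLSModel, fit_pls, project
from .preprocess import (
    BlockParams,
    PreprocessParams,
    apply_preprocess,
    average_hemispheres,
    drop_sparse_features,
    fit_preprocess,
    orient_scores,
)
from .stats import (
    age_slope,
    ancova_group,
    ancova_interaction,
    bonferroni_threshold,
    education_split,
)
from .synthetic import SimulationConfig, simulate_cohort
from .validation import classify_projections, surrogate_feature_test

STAGES = (
    "simulate",
    "preprocess",
    "fit",
    "permtest",
    "bootstrap",
    "project",
    "stats",
    "surrogate",
    "classify",
    "report",
)

_STAGE_SEED_OFFSET = {"simulate": 1, "permtest": 2, "bootstrap": 3, "surrogate": 4, "classify": 5}


def _stage_seed(base: int, stage: str) -> int:
    return (int(base) * 1009 + _STAGE_SEED_OFFSET.get(stage, 0)) % (2**31 - 1)


def _to_jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


class Pipeline:
    """Executes configured stages against an output directory."""

    def __init__(self, config: dict, config_path=None):
        self.config = config
        outdir = config.get("outdir", "braincog_out")
        base = Path(config_path).parent if config_path else Path(".")
        self.outdir = (base / outdir) if not Path(outdir).is_absolute() else Path(outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(config.get("seed", 0))
        self.log_path = self.outdir / "run_log.txt"
        self._log_lines: list[str] = []
        if config_path is not None:
            digest = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
            self.log(f"config_sha256 {digest}")
        self.log(f"base_seed {self.seed}")

    # -- plumbing ---------------------------------------------------------

    def log(self, line: str) -> None:
        self._log_lines.append(line)

    def flush_log(self) -> None:
        self.log_path.write_text("\n".join(self._log_lines) + "\n")

    def path(self, name: str) -> Path:
        return self.outdir / name

    def _load_tables(self):
        inputs = self.config.get("inputs", {})
        cohort = bio.read_cohort(inputs.get("cohort", self.path("cohort.csv")))
        brain = bio.read_block(inputs.get("brain", self.path("brain.csv")), "brain")
        cog = bio.read_block(inputs.get("cognition", self.path("cognition.csv")), "cognition")
        brain, cog = align(cohort, brain, cog)
        return cohort, brain, cog

    def _fit_ids(self, cohort: CohortTable) -> list[str]:
        group = self.config.get("preprocess", {}).get("fit_group", "HC")
        if group == "all":
            return cohort.subject_ids
        mask = cohort.df["diagnosis"].astype(str) == group
        ids = cohort.df.loc[mask, "subject_id"].astype(str).tolist()
        if not ids:
            raise ConfigurationError(f"no subjects in fit group {group!r}")
        return ids

    # -- stages -----------------------------------------------------------

    def simulate(self) -> None:
        params = dict(self.config.get("simulate", {}))
        params.setdefault("seed", _stage_seed(self.seed, "simulate"))
        cfg = SimulationConfig(**params)
        self.log(f"simulate seed {cfg.seed}")
        cohort, brain, cog, truth = simulate_cohort(cfg)
        bio.write_cohort(cohort, self.path("cohort.csv"))
        bio.write_block(brain, self.path("brain.csv"))
        bio.write_block(cog, self.path("cognition.csv"))
        bio.write_truth(truth, brain.feature_labels, cog.feature_labels,
                        cohort.subject_ids, self.path("truth"))

    def preprocess(self) -> None:
        opts = self.config.get("preprocess", {})
        cohort, brain, cog = self._load_tables()

        orientation = opts.get("orientation")
        if orientation:
            cog = orient_scores(cog, orientation)
        brain = average_hemispheres(brain)
        max_missing = float(opts.get("max_missing_frac", 0.5))
        brain, dropped_b = drop_sparse_features(brain, max_missing)
        cog, dropped_c = drop_sparse_features(cog, max_missing)
        self.log(f"preprocess dropped_brain {dropped_b}")
        self.log(f"preprocess dropped_cognition {dropped_c}")

        if opts.get("harmonize", True) and cohort.df["site"].nunique() > 1:
            model = fit_combat(brain, cohort)
            brain = apply_combat(brain, model, cohort)
            self.log(f"preprocess combat_sites {model.site_list}")
        bio.write_block(brain, self.path("brain_ready.csv"))
        bio.write_block(cog, self.path("cognition_ready.csv"))

        fit_ids = self._fit_ids(cohort)
        residualize = bool(opts.get("residualize", False))
        params = fit_preprocess(brain, cog, cohort, fit_ids, residualize=residualize)
        self._write_params(params)
        X_all = apply_preprocess(brain, cohort, params)
        Y_all = apply_preprocess(cog, cohort, params)
        ids = cohort.subject_ids
        pos = {s: i for i, s in enumerate(ids)}
        fit_idx = [pos[s] for s in fit_ids]
        self._write_matrix(X_all[fit_idx], fit_ids, params.brain.kept_features, "X_fit.csv")
        self._write_matrix(Y_all[fit_idx], fit_ids, params.cognition.kept_features, "Y_fit.csv")
        self._write_matrix(X_all, ids, params.brain.kept_features, "X_all.csv")
        self._write_matrix(Y_all, ids, params.cognition.kept_features, "Y_all.csv")

    def fit(self) -> None:
        X, x_ids, x_feats = self._read_matrix("X_fit.csv")
        Y, _, y_feats = self._read_matrix("Y_fit.csv")
        n_modes = self.config.get("fit", {}).get("n_modes")
        model = fit_pls(X, Y, n_modes=n_modes)
        self._write_model(model, x_feats, y_feats)
        scores = pd.DataFrame({"subject_id": x_ids})
        for k in range(model.n_modes):
            scores[f"brain_mode{k + 1}"] = model.x_scores[:, k]
            scores[f"cog_mode{k + 1}"] = model.y_scores[:, k]
        scores.to_csv(self.path("scores_fit.csv"), index=False)

    def permtest(self) -> None:
        X, _, _ = self._read_matrix("X_fit.csv")
        Y, _, _ = self._read_matrix("Y_fit.csv")
        opts = self.config.get("permtest", {})
        seed = int(opts.get("seed", _stage_seed(self.seed, "permtest")))
        self.log(f"permtest seed {seed}")
        res = permutation_test(
            X, Y, n_perm=int(opts.get("n_perm", 1000)), seed=seed,
            n_modes=opts.get("n_modes"),
        )
        pd.DataFrame(
            {
                "mode": np.arange(1, res.observed_cov.size + 1),
                "covariance": res.observed_cov,
                "z_covariance": res.z_cov,
                "p_value": res.p_value,
                "robust": res.p_value < 0.05,
            }
        ).to_csv(self.path("permtest.csv"), index=False)
        pd.DataFrame({"null_cov_first_mode": res.null_cov_first_mode}).to_csv(
            self.path("permtest_null.csv"), index=False
        )

    def bootstrap(self) -> None:
        cohort, _, _ = self._load_tables()
        brain = bio.read_block(self.path("brain_ready.csv"), "brain")
        cog = bio.read_block(self.path("cognition_ready.csv"), "cognition")
        fit_ids = self._fit_ids(cohort)
        sub_cohort = cohort.subset(fit_ids)
        brain = brain.reorder(fit_ids)
        cog = cog.reorder(fit_ids)
        opts = self.config.get("bootstrap", {})
        seed = int(opts.get("seed", _stage_seed(self.seed, "bootstrap")))
        self.log(f"bootstrap seed {seed}")
        res = bootstrap_loadings(
            brain, cog, sub_cohort, n_boot=int(opts.get("n_boot", 1000)), seed=seed,
            residualize=bool(self.config.get("preprocess", {}).get("residualize", False)),
        )
        for kind, feats, loading, lo, hi, sig in (
            ("brain", brain.feature_labels, res.x_loading, res.x_lo, res.x_hi, res.x_significant),
            ("cognition", cog.feature_labels, res.y_loading, res.y_lo, res.y_hi, res.y_significant),
        ):
            pd.DataFrame(
                {
                    "feature": feats,
                    "loading": loading,
                    "ci_lo": lo,
                    "ci_hi": hi,
                    "significant": sig,
                }
            ).to_csv(self.path(f"bootstrap_{kind}.csv"), index=False)

    def project(self) -> None:
        model, _, _ = self._read_model()
        X, ids, _ = self._read_matrix("X_all.csv")
        Y, _, _ = self._read_matrix("Y_all.csv")
        xs, ys = project(model, X, Y)
        scores = pd.DataFrame({"subject_id": ids})
        for k in range(model.n_modes):
            scores[f"brain_mode{k + 1}"] = xs[:, k]
            scores[f"cog_mode{k + 1}"] = ys[:, k]
        scores.to_csv(self.path("scores_all.csv"), index=False)

    def stats(self) -> None:
        cohort, _, _ = self._load_tables()
        scores = pd.read_csv(self.path("scores_all.csv"), dtype={"subject_id": str})
        scores = scores.set_index("subject_id").loc[cohort.subject_ids]
        opts = self.config.get("stats", {})
        n_tests = int(opts.get("n_tests", 14))
        threshold = bonferroni_threshold(0.05, n_tests)
        self.log(f"stats n_tests {n_tests} threshold {threshold!r}")

        df = cohort.df
        hc = df["diagnosis"].astype(str) == "HC"
        rows = []
        for proj_name in ("brain_mode1", "cog_mode1"):
            proj = scores[proj_name].to_numpy(dtype=float)

            r = age_slope(proj[hc], df.loc[hc, "age"])
            rows.append((proj_name, "age", r))

            hc_cohort = CohortTable(df.loc[hc].reset_index(drop=True))
            r = ancova_group(proj[hc], df.loc[hc, "sex"], hc_cohort, covariates=("age",))
            rows.append((proj_name, "sex", r))

            r = ancova_group(proj, df["diagnosis"], cohort, covariates=("age", "sex"))
            rows.append((proj_name, "diagnosis", r))

            r = ancova_interaction(proj, df["diagnosis"], df["age"], cohort)
            rows.append((proj_name, "age_x_diagnosis", r))

            if "amyloid_status" in df.columns and df.loc[hc, "amyloid_status"].notna().any():
                r = ancova_group(
                    proj[hc], df.loc[hc, "amyloid_status"], hc_cohort,
                    covariates=("age", "sex"),
                )
                rows.append((proj_name, "amyloid", r))
            if "apoe4" in df.columns and df.loc[hc, "apoe4"].notna().any():
                r = ancova_group(
                    proj[hc], df.loc[hc, "apoe4"], hc_cohort, covariates=("age", "sex")
                )
                rows.append((proj_name, "apoe4", r))
            if "education" in df.columns and df.loc[hc, "education"].notna().any():
                split = education_split(
                    pd.to_numeric(df.loc[hc, "education"]).to_numpy(dtype=float), hc_cohort
                )
                r = ancova_group(proj[hc], split, hc_cohort, covariates=("age", "sex"))
                rows.append((proj_name, "education", r))

        pd.DataFrame(
            [
                {
                    "projection": proj_name,
                    "factor": factor,
                    "model": r.model,
                    "term": r.term,
                    "estimate": r.estimate,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "n_used": r.n_used,
                    "threshold": threshold,
                    "significant": r.p_value < threshold,
                }
                for proj_name, factor, r in rows
            ]
        ).to_csv(self.path("stats.csv"), index=False)

    def surrogate(self) -> None:
        cohort, _, _ = self._load_tables()
        model, _, _ = self._read_model()
        X, ids, _ = self._read_matrix("X_fit.csv")
        Y, _, _ = self._read_matrix("Y_fit.csv")
        age = cohort.subset(ids).df["age"].to_numpy(dtype=float)
        opts = self.config.get("surrogate", {})
        seed = int(opts.get("seed", _stage_seed(self.seed, "surrogate")))
        self.log(f"surrogate seed {seed}")
        n_surr = int(opts.get("n_surr", 1000))
        rows = []
        for stat in ("age_slope_brain", "age_slope_cog"):
            res = surrogate_feature_test(
                model, X, Y, statistic=stat, n_surr=n_surr, seed=seed, age=age
            )
            rows.append(
                {
                    "statistic": res.statistic_name,
                    "original": res.original_value,
                    "surrogate_mean": res.surrogate_values.mean(),
                    "surrogate_sd": res.surrogate_values.std(ddof=1),
                    "p_value": res.p_value,
                }
            )
        pd.DataFrame(rows).to_csv(self.path("surrogate.csv"), index=False)

    def classify(self) -> None:
        cohort, _, _ = self._load_tables()
        scores = pd.read_csv(self.path("scores_all.csv"), dtype={"subject_id": str})
        scores = scores.set_index("subject_id").loc[cohort.subject_ids].reset_index()
        labels = np.where(cohort.df["diagnosis"].astype(str) == "HC", "HC", "CC")
        opts = self.config.get("classify", {})
        seed = int(opts.get("seed", _stage_seed(self.seed, "classify")))
        self.log(f"classify seed {seed}")
        feature_sets = opts.get(
            "feature_sets",
            [["brain_mode1"], ["cog_mode1"], ["brain_mode1", "cog_mode1"]],
        )
        rows = []
        for fs in feature_sets:
            res = classify_projections(scores, labels, fs, seed=seed)
            row = {"feature_set": "+".join(fs), "auc_mean": res.auc_mean}
            row.update({f"auc_fold{k + 1}": a for k, a in enumerate(res.auc_per_fold)})
            rows.append(row)
        pd.DataFrame(rows).to_csv(self.path("classify.csv"), index=False)

    def report(self) -> None:
        lines = ["braincog pipeline report", "========================"]
        n_tests = int(self.config.get("stats", {}).get("n_tests", 14))
        thr = bonferroni_threshold(0.05, n_tests)
        lines.append(f"bonferroni: alpha=0.05 n_tests={n_tests} threshold={thr:.6g}")
        if self.path("permtest.csv").exists():
            pt = pd.read_csv(self.path("permtest.csv"))
            robust = pt.loc[pt["robust"], "mode"].tolist()
            lines.append(f"robust modes (p<0.05): {robust}")
            for _, row in pt.iterrows():
                lines.append(
                    f"  mode {int(row['mode'])}: cov={row['covariance']:.4f} "
                    f"z={row['z_covariance']:.2f} p={row['p_value']:.4g}"
                )
        for kind in ("brain", "cognition"):
            f = self.path(f"bootstrap_{kind}.csv")
            if f.exists():
                bt = pd.read_csv(f)
                lines.append(
                    f"reliable {kind} loadings: {int(bt['significant'].sum())}/{len(bt)}"
                )
        if self.path("stats.csv").exists():
            st = pd.read_csv(self.path("stats.csv"))
            sig = st.loc[st["significant"], ["projection", "factor"]]
            lines.append(
                "significant associations at corrected threshold: "
                + "; ".join(f"{p}~{f}" for p, f in sig.itertuples(index=False))
            )
        if self.path("classify.csv").exists():
            cl = pd.read_csv(self.path("classify.csv"))
            for _, row in cl.iterrows():
                lines.append(f"AUC {row['feature_set']}: {row['auc_mean']:.3f}")
        self.path("report.txt").write_text("\n".join(lines) + "\n")

    # -- intermediates ----------------------------------------------------

    def _write_matrix(self, M, ids, feats, name) -> None:
        out = pd.DataFrame(M, columns=feats)
        out.insert(0, "subject_id", ids)
        out.to_csv(self.path(name), index=False)

    def _read_matrix(self, name):
        p = self.path(name)
        if not p.exists():
            raise ConfigurationError(f"missing intermediate {p}; run earlier stages first")
        df = pd.read_csv(p, dtype={"subject_id": str})
        feats = [c for c in df.columns if c != "subject_id"]
        return df[feats].to_numpy(dtype=float), df["subject_id"].tolist(), feats

    def _write_params(self, params: PreprocessParams) -> None:
        payload = {
            "fit_subject_ids": params.fit_subject_ids,
            "residualize": params.residualize,
        }
        for kind in ("brain", "cognition"):
            bp: BlockParams = getattr(params, kind)
            payload[kind] = {
                "kept_features": bp.kept_features,
                "impute_means": bp.impute_means,
                "feature_means": bp.feature_means,
                "feature_sds": bp.feature_sds,
                "residual_coefs": bp.residual_coefs,
            }
        self.path("preprocess_params.json").write_text(
            json.dumps(_to_jsonable(payload), sort_keys=True, indent=1)
        )

    def _write_model(self, model: PLSModel, x_feats, y_feats) -> None:
        payload = {
            "n_modes": model.n_modes,
            "x_features": x_feats,
            "y_features": y_feats,
            "x_weights": model.x_weights,
            "y_weights": model.y_weights,
            "x_loadings": model.x_loadings,
            "y_loadings": model.y_loadings,
            "mode_cov": model.mode_cov,
            "sign_flipped": model.sign_flipped.astype(int),
            "x_deflation": model.x_deflation,
            "y_deflation": model.y_deflation,
        }
        self.path("pls_model.json").write_text(
            json.dumps(_to_jsonable(payload), sort_keys=True, indent=1)
        )
        pd.DataFrame(
            {"feature": x_feats, "loading_mode1": model.x_loadings[:, 0]}
        ).to_csv(self.path("loadings_brain.csv"), index=False)
        pd.DataFrame(
            {"feature": y_feats, "loading_mode1": model.y_loadings[:, 0]}
        ).to_csv(self.path("loadings_cognition.csv"), index=False)

    def _read_model(self):
        p = self.path("pls_model.json")
        if not p.exists():
            raise ConfigurationError(f"missing model sidecar {p}; run the fit stage first")
        d = json.loads(p.read_text())
        model = PLSModel(
            n_modes=d["n_modes"],
            x_weights=np.array(d["x_weights"]),
            y_weights=np.array(d["y_weights"]),
            x_scores=np.empty((0, d["n_modes"])),
            y_scores=np.empty((0, d["n_modes"])),
            x_loadings=np.array(d["x_loadings"]),
            y_loadings=np.array(d["y_loadings"]),
            mode_cov=np.array(d["mode_cov"]),
            sign_flipped=np.array(d["sign_flipped"], dtype=bool),
            x_deflation=np.array(d["x_deflation"]),
            y_deflation=np.array(d["y_deflation"]),
        )
        return model, d["x_features"], d["y_features"]


def run_pipeline(config_path) -> Path:
    """Run all configured stages in order; returns the output directory."""
    config = load_config(config_path)
    stages = config.get("stages", list(STAGES))
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ConfigurationError(f"unknown stages {unknown}; valid: {list(STAGES)}")
    pipe = Pipeline(config, config_path)
    for stage in stages:
        getattr(pipe, stage)()
    pipe.flush_log()
    return pipe.outdir


def run_stage(config_path, stage: str) -> Path:
    """Run one stage standalone on saved intermediates."""
    if stage not in STAGES:
        raise ConfigurationError(f"unknown stage {stage!r}; valid: {list(STAGES)}")
    config = load_config(config_path)
    pipe = Pipeline(config, config_path)
    getattr(pipe, stage)()
    pipe.flush_log()
    return pipe.outdir


def load_config(config_path) -> dict:
    path = Path(config_path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    config = yaml.safe_load(path.read_text())
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a YAML mapping")
    return config
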