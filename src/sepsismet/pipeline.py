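"""End-to-end orchestration: synthesize/load -> QC -> stats -> fits -> ROC -> ORA -> overlap.

Every stage derives its own seed from the master seed keyed by the stage
name, so a stage rerun in isolation consumes exactly the randomness it
would inside the full run, and the whole pipeline is byte-reproducible:
the same config and seed yield identical manifest and result files.
"""
from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import compare_groups, comparison_table
from .evaluate import linear_score, roc_with_ci
from .lasso import LassoFit
from .ora import ora_test, read_gmt, select_features
from .overlap import coefficient_table, sign_partition, support_overlap
from .preprocess import PreprocessConfig, preprocess
from .published import reference_fits  # noqa: F401  (re-exported for reports)
from .synthetic import Cohort, CohortSpec, make_cohort, plant_missingness
from .tuning import bootstrap_median_lambda, final_fit

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "stage_seed"]

RESPONSES = ("survival30", "pecam", "stm")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: master seed keyed by the stage name."""
    return int(
        np.random.SeedSequence([master_seed, zlib.crc32(stage.encode())])
        .generate_state(1)[0]
        % (2**31)
    )


@dataclass
class PipelineConfig:
    seed: int
    output_dir: str = "sepsismet_out"
    metabolites_path: str | None = None
    clinical_path: str | None = None
    cohort: dict = field(default_factory=dict)
    preprocess: dict = field(default_factory=dict)
    responses: list[str] = field(default_factory=lambda: list(RESPONSES))
    clinical_covariates: list[str] = field(default_factory=list)
    tuning: dict = field(
        default_factory=lambda: {"B": 25, "k": 5, "n_grid": 40, "grid_ratio": 0.001}
    )
    ora: dict = field(
        default_factory=lambda: {"gmt": None, "rule": "nonzero", "top_k": None, "min_size": 2}
    )
    write_plots: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a master seed is mandatory")
        have_paths = self.metabolites_path is not None or self.clinical_path is not None
        if have_paths and self.cohort:
            raise ValueError("give either input paths or a synthetic cohort spec, not both")
        if have_paths and (self.metabolites_path is None or self.clinical_path is None):
            raise ValueError("both metabolites_path and clinical_path are required")
        unknown = set(self.responses) - set(RESPONSES)
        if unknown:
            raise ValueError(f"unknown responses: {sorted(unknown)}")

    @property
    def synthetic(self) -> bool:
        return self.metabolites_path is None


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _apply_profile(cfg: PipelineConfig, profile: str | None) -> PipelineConfig:
    if profile == "paper":
        cfg.tuning = {**cfg.tuning, "B": 500, "n_grid": 100}
    elif profile not in (None, "test"):
        raise ValueError(f"unknown profile {profile!r}")
    return cfg


def default_gmt_path() -> Path:
    """Bundled synthetic pathway collection matching the synthetic cohort names."""
    return Path(resources.files("sepsismet").joinpath("data/synthetic_pathways.gmt"))


def _get_cohort(cfg: PipelineConfig, log: list[str]) -> Cohort:
    if cfg.synthetic:
        spec_kwargs = dict(cfg.cohort)
        spec_kwargs.setdefault("seed", stage_seed(cfg.seed, "simulate"))
        spec = CohortSpec(**spec_kwargs)
        cohort = make_cohort(spec)
        if spec.missing_rate > 0 or spec.n_high_missing_features > 0:
            cohort = plant_missingness(cohort, spec)
        log.append(f"simulated cohort: {spec.n_patients} patients x {spec.n_metabolites} metabolites")
        return cohort
    met = pd.read_csv(cfg.metabolites_path, index_col=0, float_precision="round_trip")
    clin = pd.read_csv(cfg.clinical_path, index_col=0, float_precision="round_trip")
    log.append(f"loaded cohort from {cfg.metabolites_path} / {cfg.clinical_path}")
    return Cohort(metabolites=met, clinical=clin)


def _validate_inputs(cfg: PipelineConfig, cohort: Cohort) -> None:
    missing = [r for r in cfg.responses if r not in cohort.clinical.columns]
    if missing:
        raise ValueError(f"missing outcome column(s): {missing}")
    y = cohort.clinical["survival30"]
    if not set(np.unique(y.dropna())) <= {0, 1}:
        raise ValueError("survival30 outcome must be binary 0/1")
    unknown = [c for c in cfg.clinical_covariates if c not in cohort.clinical.columns]
    if unknown:
        raise ValueError(f"unknown clinical covariate(s): {unknown}")


def _design_for(cfg: PipelineConfig, scaled: pd.DataFrame, clinical: pd.DataFrame,
                response: str) -> tuple[np.ndarray, np.ndarray, list[str]]:
    covs = [c for c in cfg.clinical_covariates if c != response]
    X = scaled.to_numpy()
    names = list(scaled.columns)
    if covs:
        X = np.column_stack([X, clinical.loc[scaled.index, covs].to_numpy(float)])
        names += covs
    y = clinical.loc[scaled.index, response].to_numpy(float)
    return X, y, names


def _fitted_scores(X: np.ndarray, y: np.ndarray, fit: LassoFit) -> np.ndarray:
    """In-sample predictions of a standardized-scale fit on its training data."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    scale = np.where(sd > 0, sd, 1.0)
    return fit.intercept + ((X - mean) / scale) @ fit.w


def run_pipeline(cfg: PipelineConfig, profile: str | None = None) -> dict:
    """Execute every stage and write all artifacts under ``cfg.output_dir``.

    Returns the manifest (also written as ``manifest.json``).
    """
    cfg = _apply_profile(cfg, profile)
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    cohort = _get_cohort(cfg, log)
    _validate_inputs(cfg, cohort)
    cohort.write(outdir / "cohort")

    # --- preprocessing ------------------------------------------------
    pp_kwargs = dict(cfg.preprocess)
    pp_kwargs.setdefault("imputation_seed", stage_seed(cfg.seed, "impute"))
    pp_cfg = PreprocessConfig(**pp_kwargs)
    scaled, report = preprocess(cohort.metabolites, pp_cfg)
    scaled.to_csv(outdir / "metabolites_scaled.csv", float_format="%.17g")
    report.to_json(outdir / "preprocess_report.json")
    for feat, reason in report.removed_features:
        log.append(f"removed feature {feat}: {reason}")
    for pat in report.removed_patients:
        log.append(f"removed patient {pat}: missingness")
    clinical = cohort.clinical.loc[scaled.index]

    # --- cohort statistics -------------------------------------------
    stat_cols = [c for c in clinical.columns]
    rows = compare_groups(clinical[stat_cols], "survival30")
    stats_df = comparison_table(rows)
    stats_df.to_csv(outdir / "cohort_stats.csv", index=False)

    # --- per-response tuning + final fits ----------------------------
    fits: dict[str, LassoFit] = {}
    searches = {}
    for response in cfg.responses:
        X, y, names = _design_for(cfg, scaled, clinical, response)
        seed = stage_seed(cfg.seed, f"tune:{response}")
        search = bootstrap_median_lambda(
            X, y,
            B=int(cfg.tuning.get("B", 25)),
            k=int(cfg.tuning.get("k", 5)),
            seed=seed,
            n_grid=int(cfg.tuning.get("n_grid", 40)),
            grid_ratio=float(cfg.tuning.get("grid_ratio", 0.001)),
            feature_names=names,
        )
        fit = final_fit(X, y, search.median_lambda, feature_names=names)
        fits[response] = fit
        searches[response] = search
        (outdir / f"lambda_search_{response}.json").write_text(
            json.dumps(search.to_dict(), indent=1)
        )
        (outdir / f"fit_{response}.json").write_text(
            json.dumps(fit.to_dict(), indent=1)
        )
        log.append(
            f"{response}: median lambda {search.median_lambda:.5g}, "
            f"support {len(fit.support)}"
        )

    # --- ROC model comparison ----------------------------------------
    surv = clinical["survival30"].to_numpy(int)
    roc_seed = stage_seed(cfg.seed, "roc")
    candidates: dict[str, np.ndarray] = {
        "septic_shock": linear_score(clinical["septic_shock"].to_numpy(float), surv),
        "sofa": linear_score(clinical["sofa"].to_numpy(float), surv),
        "pecam_stm": linear_score(
            clinical[["pecam", "stm"]].to_numpy(float), surv
        ),
    }
    if "survival30" in fits:
        X, y, _ = _design_for(cfg, scaled, clinical, "survival30")
        candidates["metabolite_model"] = _fitted_scores(X, y, fits["survival30"])
        order = np.argsort(-np.abs(fits["survival30"].w))[:2]
        for j in order:
            if fits["survival30"].w[j] == 0:
                continue
            name = fits["survival30"].feature_names[j]
            if name in scaled.columns:
                candidates[f"single_{name}"] = scaled[name].to_numpy()
    curves = {}
    for name, scores in candidates.items():
        curves[name] = roc_with_ci(scores, surv, method="delong", seed=roc_seed)
    (outdir / "roc.json").write_text(
        json.dumps({k: c.to_dict() for k, c in curves.items()}, indent=1)
    )

    # --- over-representation analysis --------------------------------
    gmt_path = cfg.ora.get("gmt") or default_gmt_path()
    collection = read_gmt(gmt_path)
    measured = {c.strip().lower() for c in scaled.columns}
    universe = frozenset(measured & set(collection.universe))
    ora_tables = {}
    for response, fit in fits.items():
        selected = select_features(
            fit, rule=cfg.ora.get("rule", "nonzero"), top_k=cfg.ora.get("top_k")
        )
        dropped = selected - universe
        if dropped:
            log.append(f"{response}: {len(dropped)} selected features not annotatable")
        table = ora_test(
            selected & universe, collection, universe,
            min_size=int(cfg.ora.get("min_size", 2)),
        )
        table.to_csv(outdir / f"ora_{response}.csv", index=False)
        ora_tables[response] = table

    # --- cross-model overlap report ----------------------------------
    supports = [sign_partition(fit, model=name) for name, fit in fits.items()]
    regions = support_overlap(supports)
    overlap_json = {
        sign: {"+".join(k): sorted(v) for k, v in reg.items() if v}
        for sign, reg in regions.items()
    }
    (outdir / "overlap.json").write_text(json.dumps(overlap_json, indent=1))
    coefficient_table(fits).to_csv(outdir / "coefficients.csv", index=False)

    if cfg.write_plots:
        _write_plots(outdir, searches, curves, ora_tables)

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(
                {k: v for k, v in asdict(cfg).items() if k != "output_dir"},
                sort_keys=True, default=str,
            ).encode()
        ).hexdigest(),
        "stage_seeds": {
            s: stage_seed(cfg.seed, s)
            for s in ["simulate", "impute", "roc"]
            + [f"tune:{r}" for r in cfg.responses]
        },
        "log": log,
        "files": sorted(
            str(p.relative_to(outdir))
            for p in outdir.rglob("*")
            if p.is_file() and p.suffix in (".csv", ".json")
        ),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def _write_plots(outdir: Path, searches, curves, ora_tables) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for response, search in searches.items():
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.hist(np.log10(search.per_bootstrap_lambda), bins=20, color="steelblue")
        ax.axvline(np.log10(search.median_lambda), color="crimson", ls="--",
                   label=f"median = {search.median_lambda:.4g}")
        ax.set_xlabel("log10 lambda")
        ax.set_ylabel("bootstrap count")
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(outdir / f"lambda_hist_{response}.png", dpi=120)
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, c in curves.items():
        ax.plot(1 - c.specificity, c.sensitivity, label=f"{name} (AUC {c.auc:.2f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(outdir / "roc_overlay.png", dpi=120)
    plt.close(fig)

    rows = []
    for response, table in ora_tables.items():
        for _, r in table.iterrows():
            rows.append((response, r["pathway"], r["ora_score"], r["adjusted_p"]))
    if rows:
        df = pd.DataFrame(rows, columns=["response", "pathway", "score", "adj_p"])
        fig, ax = plt.subplots(figsize=(6, 0.4 * df["pathway"].nunique() + 2))
        paths = sorted(df["pathway"].unique())
        for resp in df["response"].unique():
            sub = df[df["response"] == resp]
            ax.scatter(
                -np.log10(np.maximum(sub["adj_p"], 1e-16)),
                [paths.index(p) for p in sub["pathway"]],
                s=20 * np.clip(sub["score"], 0.2, 10),
                label=resp, alpha=0.7,
            )
        ax.set_yticks(range(len(paths)), paths, fontsize=7)
        ax.set_xlabel("-log10 adjusted p")
        ax.legend(frameon=False, fontsize=7)
        fig.tight_layout()
        fig.savefig(outdir / "ora_dotplot.png", dpi=120)
        plt.close(fig)
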