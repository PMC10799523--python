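"""Filtering, imputation and scaling of the metabolite matrix.

The chain runs in a fixed order: feature missingness filter (> threshold of
patients missing), patient missingness filter, removal of features with
non-positive observed values (quantification failures; the log transform is
undefined there), imputation of the remaining gaps, then natural log and
Pareto scaling. Pareto scaling centres each log feature and divides by the
square root of its sample standard deviation, damping — without fully
equalising — the dominance of high-variance metabolites.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.impute import KNNImputer, SimpleImputer

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "filter_features_by_missingness",
    "filter_patients_by_missingness",
    "remove_nonpositive_features",
    "impute",
    "log_pareto_scale",
    "unscale",
    "preprocess",
]


@dataclass
class PreprocessConfig:
    feature_missing_threshold: float = 0.10
    patient_missing_threshold: float = 0.10
    imputation_method: str = "chained_forest"  # chained_forest | knn | median
    imputation_seed: int = 0
    max_imputation_iterations: int = 10
    knn_k: int = 5
    n_trees: int = 50
    pmm_donors: int = 3

    def __post_init__(self) -> None:
        for t in (self.feature_missing_threshold, self.patient_missing_threshold):
            if not 0 < t < 1:
                raise ValueError("missingness thresholds must lie in (0, 1)")
        if self.knn_k < 1:
            raise ValueError("knn_k must be at least 1")
        if self.imputation_method not in ("chained_forest", "knn", "median"):
            raise ValueError(f"unknown imputation method {self.imputation_method!r}")


@dataclass
class PreprocessReport:
    removed_features: list[tuple[str, str]] = field(default_factory=list)
    removed_patients: list = field(default_factory=list)
    feature_missing_fraction: dict[str, float] = field(default_factory=dict)
    n_imputed_cells: int = 0
    log_base: str = "natural"
    scaling_params: pd.DataFrame | None = None

    def to_json(self, path: str | Path) -> None:
        d = {
            "removed_features": [list(t) for t in self.removed_features],
            "removed_patients": [str(x) for x in self.removed_patients],
            "feature_missing_fraction": self.feature_missing_fraction,
            "n_imputed_cells": self.n_imputed_cells,
            "log_base": self.log_base,
            "scaling_params": (
                None
                if self.scaling_params is None
                else self.scaling_params.to_dict(orient="index")
            ),
        }
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))


def filter_features_by_missingness(
    matrix: pd.DataFrame, threshold: float = 0.10
) -> tuple[pd.DataFrame, list[str]]:
    """Drop features missing in strictly more than ``threshold`` of patients."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    frac = matrix.isna().mean(axis=0)
    removed = list(matrix.columns[frac > threshold])
    kept = matrix.drop(columns=removed)
    if kept.shape[1] == 0:
        raise ValueError("missingness filter removed every feature")
    return kept, removed


def filter_patients_by_missingness(
    matrix: pd.DataFrame, threshold: float = 0.10
) -> tuple[pd.DataFrame, list]:
    """Drop patients missing strictly more than ``threshold`` of features."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    frac = matrix.isna().mean(axis=1)
    removed = list(matrix.index[frac > threshold])
    kept = matrix.drop(index=removed)
    if kept.shape[0] == 0:
        raise ValueError("missingness filter removed every patient")
    return kept, removed


def remove_nonpositive_features(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop any feature with an observed value <= 0 (log-transform undefined)."""
    bad = [c for c in matrix.columns if (matrix[c].dropna() <= 0).any()]
    return matrix.drop(columns=bad), bad


def _chained_forest_impute(
    matrix: pd.DataFrame, config: PreprocessConfig
) -> pd.DataFrame:
    """Iterative chained random-forest imputation with predictive mean matching.

    Each incomplete feature is regressed on all others with a random forest;
    missing cells receive the observed value of a donor whose out-of-bag
    prediction is nearest the cell's prediction (one of ``pmm_donors``
    candidates, chosen at random), so imputed values are always actually
    observed ones. Iterates until the mean out-of-bag error stops improving
    or ``max_imputation_iterations`` is reached.
    """
    rng = np.random.default_rng(config.imputation_seed)
    vals = matrix.to_numpy(dtype=float).copy()
    miss = np.isnan(vals)
    col_order = np.argsort(miss.sum(axis=0))  # least-missing first
    # start from per-feature medians
    med = np.nanmedian(vals, axis=0)
    filled = np.where(miss, med, vals)
    prev_err = np.inf
    best = filled.copy()
    for _ in range(config.max_imputation_iterations):
        errs = []
        for j in col_order:
            mj = miss[:, j]
            if not mj.any():
                continue
            others = np.delete(filled, j, axis=1)
            rf = RandomForestRegressor(
                n_estimators=config.n_trees,
                oob_score=True,
                bootstrap=True,
                random_state=int(rng.integers(2**31)),
                n_jobs=1,
            )
            rf.fit(others[~mj], vals[~mj, j])
            errs.append(float(np.mean((rf.oob_prediction_ - vals[~mj, j]) ** 2)))
            pred_mis = rf.predict(others[mj])
            donors_pred = rf.oob_prediction_
            donors_val = vals[~mj, j]
            k = min(config.pmm_donors, donors_val.size)
            order = np.abs(donors_pred[None, :] - pred_mis[:, None]).argsort(axis=1)
            pick = order[np.arange(pred_mis.size), rng.integers(0, k, pred_mis.size)]
            filled[mj, j] = donors_val[pick]
        err = float(np.mean(errs)) if errs else 0.0
        if err >= prev_err:
            filled = best  # keep the iteration that scored best out-of-bag
            break
        prev_err = err
        best = filled.copy()
    out = matrix.copy()
    out.iloc[:, :] = np.where(miss, filled, vals)
    return out


def impute(matrix: pd.DataFrame, config: PreprocessConfig) -> pd.DataFrame:
    """Fill missing cells; observed cells are passed through bit-identically."""
    if not matrix.isna().any().any():
        return matrix.copy()
    if matrix.isna().all(axis=0).any():
        empty = list(matrix.columns[matrix.isna().all(axis=0)])
        raise ValueError(f"features with no observed values: {empty}")
    if config.imputation_method == "chained_forest":
        out = _chained_forest_impute(matrix, config)
    else:
        if config.imputation_method == "knn":
            imp = KNNImputer(n_neighbors=config.knn_k)
        else:
            imp = SimpleImputer(strategy="median")
        out = pd.DataFrame(
            imp.fit_transform(matrix), index=matrix.index, columns=matrix.columns
        )
    # contract: observed cells bit-identical to the input
    mask = matrix.notna().to_numpy()
    arr = out.to_numpy()
    arr[mask] = matrix.to_numpy()[mask]
    out.iloc[:, :] = arr
    return out


def log_pareto_scale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Natural log, then Pareto scale: (ln x - mean) / sqrt(sd), sd with n-1.

    Returns the scaled matrix and a per-feature table of the log-scale mean
    and standard deviation needed to invert the transform.
    """
    if (matrix <= 0).any().any() or matrix.isna().any().any():
        raise ValueError("log/Pareto scaling requires complete, positive data")
    logged = np.log(matrix)
    mean = logged.mean(axis=0)
    sd = logged.std(axis=0, ddof=1)
    constant = sd[sd == 0]
    if len(constant):
        raise ValueError(
            f"constant feature(s) cannot be Pareto scaled: {list(constant.index)}"
        )
    scaled = (logged - mean) / np.sqrt(sd)
    params = pd.DataFrame({"log_mean": mean, "log_sd": sd})
    return scaled, params


def unscale(scaled: pd.DataFrame, params: pd.DataFrame) -> pd.DataFrame:
    """Invert :func:`log_pareto_scale` back to raw concentrations."""
    logged = scaled * np.sqrt(params["log_sd"]) + params["log_mean"]
    return np.exp(logged)


def preprocess(
    matrix: pd.DataFrame, config: PreprocessConfig | None = None
) -> tuple[pd.DataFrame, PreprocessReport]:
    """Run the full chain and return the scaled matrix plus a report."""
    config = config or PreprocessConfig()
    report = PreprocessReport()
    report.feature_missing_fraction = {
        c: float(f) for c, f in matrix.isna().mean(axis=0).items()
    }
    matrix, rm = filter_features_by_missingness(
        matrix, config.feature_missing_threshold
    )
    report.removed_features += [(c, "missingness") for c in rm]
    matrix, report.removed_patients = filter_patients_by_missingness(
        matrix, config.patient_missing_threshold
    )
    matrix, rm = remove_nonpositive_features(matrix)
    report.removed_features += [(c, "nonpositive") for c in rm]
    n_missing = int(matrix.isna().sum().sum())
    matrix = impute(matrix, config)
    report.n_imputed_cells = n_missing
    scaled, params = log_pareto_scale(matrix)
    report.scaling_params = params
    return scaled, report
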