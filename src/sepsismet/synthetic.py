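"""Seeded synthetic sepsis cohorts with planted sparse metabolite effects.

The generator emulates the structure of a small ICU metabolomics study:
52 patients, 63 quantified plasma metabolites, 19 deaths within 30 days,
two continuous endothelial-damage markers (PECAM and soluble
thrombomodulin) driven by sparse linear combinations of log-concentrations,
and a metabolite matrix in which a subset of features carries more than 10%
missing values. Ground-truth coefficient vectors travel with the cohort so
recovery can be scored downstream.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

__all__ = ["CohortSpec", "Cohort", "GenerationError", "make_cohort", "plant_missingness"]


class GenerationError(RuntimeError):
    """Raised when a cohort with the requested event count cannot be drawn."""


def _default_beta(p: int, entries: dict[int, float]) -> np.ndarray:
    beta = np.zeros(p)
    for j, b in entries.items():
        beta[j] = b
    return beta


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults mirror the study shape.

    Coefficient vectors act on the (unit-variance) log-concentration scale.
    The default planted effects share three features across all three
    responses — two positive, one negative — echoing the overlap pattern
    biomarker analyses look for, plus response-specific features.
    """

    n_patients: int = 52
    n_metabolites: int = 63
    n_deaths: int = 19
    true_beta_mortality: np.ndarray | None = None
    true_beta_pecam: np.ndarray | None = None
    true_beta_stm: np.ndarray | None = None
    noise_sd_markers: float = 0.5
    missing_rate: float = 0.02
    n_high_missing_features: int = 13
    seed: int = 0
    rho: float = 0.2
    mortality_link: str = "logistic"  # or "linear"
    missing_mechanism: str = "mcar"  # or "mar_low"
    pecam_baseline: float = 12.0
    stm_baseline: float = 16.0
    max_event_retries: int = 1000

    def __post_init__(self) -> None:
        if not 0 < self.n_deaths < self.n_patients:
            raise ValueError("need 0 < n_deaths < n_patients")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd_markers <= 0:
            raise ValueError("noise_sd_markers must be positive")
        if self.mortality_link not in ("logistic", "linear"):
            raise ValueError("mortality_link must be 'logistic' or 'linear'")
        if self.missing_mechanism not in ("mcar", "mar_low"):
            raise ValueError("missing_mechanism must be 'mcar' or 'mar_low'")
        p = self.n_metabolites
        if self.true_beta_mortality is None:
            self.true_beta_mortality = _default_beta(
                p, {0: 1.0, 1: 0.6, 2: -1.0, 3: 0.8, 4: -0.7}
            )
        if self.true_beta_stm is None:
            self.true_beta_stm = _default_beta(
                p, {0: 1.3, 1: 0.5, 2: -1.7, 5: 1.0, 6: -0.9}
            )
        if self.true_beta_pecam is None:
            self.true_beta_pecam = _default_beta(
                p, {0: 1.9, 1: 1.8, 2: -0.9, 7: 1.2, 8: -1.1}
            )
        for name in ("true_beta_mortality", "true_beta_pecam", "true_beta_stm"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (p,):
                raise ValueError(f"{name} must have length n_metabolites")
            setattr(self, name, vec)

    def to_dict(self) -> dict:
        d = {
            k: v for k, v in self.__dict__.items() if not k.startswith("true_beta")
        }
        for name in ("true_beta_mortality", "true_beta_pecam", "true_beta_stm"):
            d[name] = [float(x) for x in getattr(self, name)]
        return d


@dataclass
class Cohort:
    """Patient x metabolite concentrations (NaN = missing) plus clinical table.

    ``clinical.survival30`` is the 30-day mortality event indicator used as
    the regression response: 1 = death within 30 days of ICU admission,
    0 = survived. Exactly ``spec.n_deaths`` patients carry a 1.
    """

    metabolites: pd.DataFrame
    clinical: pd.DataFrame
    truth: CohortSpec | None = None

    def __post_init__(self) -> None:
        if self.metabolites.shape[0] != self.clinical.shape[0]:
            raise ValueError("metabolite matrix and clinical table row counts differ")
        obs = self.metabolites.to_numpy()
        if np.any(obs[~np.isnan(obs)] <= 0):
            raise ValueError("observed concentrations must be positive")
        if "survival30" not in self.clinical.columns:
            raise ValueError("clinical table lacks the outcome column 'survival30'")
        if not set(np.unique(self.clinical["survival30"])) <= {0, 1}:
            raise ValueError("survival30 must be 0/1")

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        # %.17g round-trips float64 exactly, keeping file and memory in sync
        self.metabolites.to_csv(
            outdir / "metabolites.csv", index_label="patient_id", float_format="%.17g"
        )
        self.clinical.to_csv(
            outdir / "clinical.csv", index_label="patient_id", float_format="%.17g"
        )
        if self.truth is not None:
            (outdir / "truth.json").write_text(
                json.dumps(self.truth.to_dict(), indent=1, sort_keys=True)
            )

    @classmethod
    def read(cls, indir: str | Path) -> "Cohort":
        indir = Path(indir)
        met = pd.read_csv(
            indir / "metabolites.csv", index_col="patient_id",
            float_precision="round_trip",
        )
        clin = pd.read_csv(
            indir / "clinical.csv", index_col="patient_id",
            float_precision="round_trip",
        )
        truth = None
        tpath = indir / "truth.json"
        if tpath.exists():
            d = json.loads(tpath.read_text())
            for key in ("true_beta_mortality", "true_beta_pecam", "true_beta_stm"):
                d[key] = np.asarray(d[key], dtype=float)
            truth = CohortSpec(**d)
        return cls(metabolites=met, clinical=clin, truth=truth)


def _calibrated_probs(lp: np.ndarray, rate: float, link: str) -> np.ndarray:
    """Shift the linear predictor so mean event probability equals ``rate``."""
    if link == "logistic":
        def gap(c):
            return expit(c + lp).mean() - rate
    else:
        def gap(c):
            return np.clip(c + lp, 0.0, 1.0).mean() - rate
    try:
        c = brentq(gap, -50.0, 50.0, xtol=1e-12)
    except ValueError as exc:  # saturated predictor: rate unreachable
        raise GenerationError(
            "cannot calibrate mortality probabilities to the requested event rate"
        ) from exc
    probs = expit(c + lp) if link == "logistic" else np.clip(c + lp, 0.0, 1.0)
    return probs


def make_cohort(spec: CohortSpec) -> Cohort:
    """Draw a complete cohort (no missingness) from ``spec``, deterministically.

    Log-concentrations are multivariate normal with exchangeable correlation
    ``spec.rho`` and unit variances; the endothelial markers are linear in
    the centred log-concentrations plus Gaussian noise; mortality events are
    Bernoulli draws from a calibrated logistic (default) or clipped-linear
    probability, redrawn until exactly ``n_deaths`` events occur.
    """
    n, p = spec.n_patients, spec.n_metabolites
    rng = np.random.default_rng(spec.seed)
    names = [f"met_{j:03d}" for j in range(p)]

    mu = rng.uniform(0.5, 4.0, size=p)  # per-metabolite log-abundance level
    L = np.linalg.cholesky(spec.rho * np.ones((p, p)) + (1 - spec.rho) * np.eye(p))
    Z = mu + rng.standard_normal((n, p)) @ L.T
    Zc = Z - Z.mean(axis=0)

    pecam = (
        spec.pecam_baseline
        + Zc @ spec.true_beta_pecam
        + rng.normal(0.0, spec.noise_sd_markers, size=n)
    )
    stm = (
        spec.stm_baseline
        + Zc @ spec.true_beta_stm
        + rng.normal(0.0, spec.noise_sd_markers, size=n)
    )
    if np.any(pecam <= 0) or np.any(stm <= 0):
        warnings.warn("marker values clipped at 0.05 ng/mL to stay positive")
        pecam = np.maximum(pecam, 0.05)
        stm = np.maximum(stm, 0.05)

    lp = Zc @ spec.true_beta_mortality
    probs = _calibrated_probs(lp, spec.n_deaths / n, spec.mortality_link)
    if probs.sum() == 0 or (1 - probs).sum() == 0:
        raise GenerationError("requested event count has probability zero")
    for _ in range(spec.max_event_retries):
        events = rng.binomial(1, probs)
        if events.sum() == spec.n_deaths:
            break
    else:
        raise GenerationError(
            f"could not draw exactly {spec.n_deaths} events in "
            f"{spec.max_event_retries} attempts"
        )

    risk = (lp - lp.mean()) / (lp.std() or 1.0)
    sofa = np.clip(np.rint(8 + 2.5 * risk + rng.normal(0, 2, size=n)), 0, 24)
    clinical = pd.DataFrame(
        {
            "survival30": events,
            "pecam": pecam,
            "stm": stm,
            "sofa": sofa.astype(int),
            "septic_shock": rng.binomial(1, 28 / 52, size=n),
            "age": np.clip(np.rint(rng.normal(71, 9, size=n)), 18, 100).astype(int),
            "sex": rng.binomial(1, 25 / 52, size=n),
            "bmi": np.round(np.clip(rng.normal(27.5, 5.0, size=n), 15, 55), 3),
        },
        index=pd.RangeIndex(n, name="patient_id"),
    )
    metabolites = pd.DataFrame(np.exp(Z), columns=names, index=clinical.index)
    return Cohort(metabolites=metabolites, clinical=clinical, truth=spec)


def plant_missingness(cohort: Cohort, spec: CohortSpec) -> Cohort:
    """Mask cells of a complete cohort: MCAR base rate + high-missing features.

    After the base mask at ``spec.missing_rate``, ``n_high_missing_features``
    randomly chosen features receive additional masking so each strictly
    exceeds 10% missingness. With ``missing_mechanism='mar_low'`` the base
    mask preferentially hits low concentrations instead of being uniform.
    """
    mat = cohort.metabolites.to_numpy().copy()
    if np.isnan(mat).any():
        raise ValueError("cohort already contains missing values")
    n, p = mat.shape
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, 0xA55)))
    if spec.missing_mechanism == "mcar":
        mask = rng.random((n, p)) < spec.missing_rate
    else:
        ranks = np.argsort(np.argsort(mat, axis=0), axis=0) / max(n - 1, 1)
        cell_p = spec.missing_rate * 2 * (1 - ranks)  # low values twice as exposed
        mask = rng.random((n, p)) < np.clip(cell_p, 0, 1)

    thr = int(np.floor(0.10 * n)) + 1  # smallest count strictly above 10%
    if spec.n_high_missing_features > 0:
        if spec.n_high_missing_features > p:
            raise ValueError("more high-missing features than features")
        chosen = rng.choice(p, size=spec.n_high_missing_features, replace=False)
        hi = min(max(thr, int(np.ceil(0.2 * n))), n - 1)
        for j in chosen:
            target = int(rng.integers(thr, hi + 1))
            have = int(mask[:, j].sum())
            if have < target:
                avail = np.flatnonzero(~mask[:, j])
                extra = rng.choice(avail, size=target - have, replace=False)
                mask[extra, j] = True

    if np.any(mask.all(axis=1)):
        raise ValueError("missingness would mask an entire patient row")
    mat[mask] = np.nan
    met = pd.DataFrame(
        mat, columns=cohort.metabolites.columns, index=cohort.metabolites.index
    )
    return Cohort(metabolites=met, clinical=cohort.clinical.copy(), truth=cohort.truth)
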