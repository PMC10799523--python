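"""Reference results from the original 52-patient ICU sepsis cohort.

These are the reported numbers of the cohort analysis this package
re-implements (the raw patient data are not redistributable): the sparse
regression coefficient blocks for the 30-day mortality, soluble
thrombomodulin (sTM) and PECAM models, and the survivor vs non-survivor
contingency tables for sex and septic-shock status. They serve as worked-
example inputs for the reporting and statistics layers — e.g. recomputing
support sizes, sign partitions, cross-model overlaps and the exact-test
p-values from first principles.
"""
from __future__ import annotations

import numpy as np

from .lasso import LassoFit

__all__ = [
    "MORTALITY_COEFFICIENTS",
    "STM_COEFFICIENTS",
    "PECAM_COEFFICIENTS",
    "SEX_TABLE",
    "SEPTIC_SHOCK_TABLE",
    "reference_fit",
    "reference_fits",
]

#: Sparse model for death within 30 days of ICU admission (standardised scale).
MORTALITY_COEFFICIENTS: dict[str, float] = {
    "Glycine": -0.011,
    "Isoleucine": -0.124,
    "Asparagine": 0.035,
    "Glutamate": -0.012,
    "Tyrosine": 0.090,
    "Pyruvate": -0.065,
    "Fumarate": 0.083,
    "Oxoproline": 0.101,
    "Butyrylcarnitine": 0.028,
    "Docosahexanoate": -0.036,
    "Glutamine": 0.029,
    "Histidine": 0.111,
    "Myristoylcarnitine": 0.055,
    "Sphingosine 1 phosphate": -0.049,
    "Urate": 0.004,
}

#: Sparse model for plasma soluble thrombomodulin concentration.
STM_COEFFICIENTS: dict[str, float] = {
    "Glutamate": -1.327,
    "Ornithine": 1.064,
    "Tryptophan": -0.650,
    "Cystine": -0.278,
    "Fumarate": 1.221,
    "Acetylcarnitine": 0.845,
    "Eicosapentanoate": -0.102,
    "Histidine": 1.296,
    "Linoleate": -0.896,
    "Kynurenine": 0.865,
    "Myristoylcarnitine": 0.606,
    "Octanylcarnitine": 1.409,
    "Sphingosine 1 phosphate": -1.729,
    "Trimethyl N oxide": 0.144,
    "Urate": 0.548,
}

#: Sparse model for plasma PECAM concentration.
PECAM_COEFFICIENTS: dict[str, float] = {
    "Glycine": -1.728,
    "Valine": -1.222,
    "Isoleucine": -1.083,
    "Threonine": 3.463,
    "Glutamate": 0.978,
    "Phenylalanine": -0.104,
    "Tryptophan": -0.983,
    "Aspartate": 0.887,
    "Pyruvate": -0.435,
    "Succinate": -0.430,
    "Arachidonate": 0.671,
    "Arginine": 0.732,
    "Docosahexanoate": -0.897,
    "Gamma Linolenicate A": -0.605,
    "Glucose": -0.610,
    "Glutamine": 0.206,
    "Histidine": 1.869,
    "Linolenate": -0.212,
    "Myristoylcarnitine": -0.379,
    "Propionylcarnitine": 0.107,
    "Sphingosine 1 phosphate": -0.865,
    "Trimethyl N oxide": 0.363,
    "Urate": 1.832,
}

#: Survivors vs non-survivors by sex: rows (survivor, non-survivor),
#: columns (female, male).
SEX_TABLE = np.array([[17, 16], [10, 9]])

#: Survivors vs non-survivors by septic-shock status: rows as above,
#: columns (septic shock, sepsis without shock).
SEPTIC_SHOCK_TABLE = np.array([[16, 17], [12, 7]])


def reference_fit(coefficients: dict[str, float], model: str = "model") -> LassoFit:
    """Wrap a reported coefficient block as a LassoFit for the report layer."""
    names = list(coefficients)
    w = np.array([coefficients[n] for n in names], dtype=float)
    return LassoFit(
        w=w,
        intercept=0.0,
        lam=float("nan"),
        n_sweeps=0,
        converged=True,
        final_cost=float("nan"),
        feature_names=names,
    )


def reference_fits() -> dict[str, LassoFit]:
    """All three reported models keyed by response name."""
    return {
        "mortality": reference_fit(MORTALITY_COEFFICIENTS, "mortality"),
        "stm": reference_fit(STM_COEFFICIENTS, "stm"),
        "pecam": reference_fit(PECAM_COEFFICIENTS, "pecam"),
    }
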