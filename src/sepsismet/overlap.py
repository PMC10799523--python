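"""Cross-model reporting: signed supports, Venn overlaps, coefficient tables.

Feature names are normalised (case-folded, punctuation and whitespace
collapsed) before matching so spelling variants of the same metabolite line
up across models; an explicit synonym map can be supplied for aliases such
as abbreviations.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .lasso import LassoFit

__all__ = ["ModelSupport", "normalize_name", "sign_partition", "support_overlap", "coefficient_table"]

_PUNCT = re.compile(r"[\s\-_.,;:()\[\]/]+")


def normalize_name(name: str, synonyms: dict[str, str] | None = None) -> str:
    """Canonical feature key: lower-case, punctuation/whitespace collapsed."""
    key = _PUNCT.sub(" ", name.strip().lower()).strip()
    if synonyms:
        syn = {normalize_name(k): normalize_name(v) for k, v in synonyms.items()}
        key = syn.get(key, key)
    return key


@dataclass
class ModelSupport:
    """Signed support of one sparse model."""

    model: str
    positives: frozenset[str]
    negatives: frozenset[str]

    def __post_init__(self) -> None:
        if self.positives & self.negatives:
            raise ValueError("a feature cannot be both positive and negative")

    @property
    def support(self) -> frozenset[str]:
        return self.positives | self.negatives


def sign_partition(
    fit: LassoFit, model: str = "model", synonyms: dict[str, str] | None = None
) -> ModelSupport:
    """Split a fit's nonzero coefficients by sign (zeros excluded)."""
    pos, neg = set(), set()
    for name, w in zip(fit.feature_names, fit.w):
        if w > 0:
            pos.add(normalize_name(name, synonyms))
        elif w < 0:
            neg.add(normalize_name(name, synonyms))
    return ModelSupport(model=model, positives=frozenset(pos), negatives=frozenset(neg))


def support_overlap(supports: list[ModelSupport]) -> dict[str, dict[tuple[str, ...], frozenset[str]]]:
    """Exclusive Venn regions of the signed supports, per sign.

    For each sign, the region keyed by a tuple of model names holds the
    features present in exactly those models. Region sets partition the
    union of the supports.
    """
    if not supports:
        raise ValueError("need at least one model support")
    names = [s.model for s in supports]
    if len(set(names)) != len(names):
        raise ValueError("duplicate model names")
    out: dict[str, dict[tuple[str, ...], frozenset[str]]] = {}
    for sign in ("positive", "negative"):
        sets = {
            s.model: (s.positives if sign == "positive" else s.negatives)
            for s in supports
        }
        regions: dict[tuple[str, ...], frozenset[str]] = {}
        for r in range(1, len(names) + 1):
            for combo in combinations(sorted(names), r):
                inside = set.intersection(*(set(sets[m]) for m in combo))
                outside = set().union(*(sets[m] for m in names if m not in combo))
                regions[combo] = frozenset(inside - outside)
        out[sign] = regions
    return out


def intersect_all(supports: list[ModelSupport], sign: str) -> frozenset[str]:
    """Features carrying the given sign in every model."""
    sets = [s.positives if sign == "positive" else s.negatives for s in supports]
    return frozenset(set.intersection(*(set(x) for x in sets)))


def coefficient_table(
    fits: dict[str, LassoFit], synonyms: dict[str, str] | None = None
) -> pd.DataFrame:
    """Long-format (model, metabolite, coefficient) table of nonzero terms.

    Sorted by model then descending |coefficient|; coefficients survive a
    CSV round trip bit-equal (written at full precision).
    """
    rows = []
    for model, fit in fits.items():
        for name, w in zip(fit.feature_names, fit.w):
            if w != 0:
                rows.append(
                    {
                        "model": model,
                        "metabolite": normalize_name(name, synonyms),
                        "coefficient": float(w),
                    }
                )
    table = pd.DataFrame(rows, columns=["model", "metabolite", "coefficient"])
    if table.empty:
        return table
    table["absw"] = table["coefficient"].abs()
    table = (
        table.sort_values(["model", "absw"], ascending=[True, False], kind="stable")
        .drop(columns="absw")
        .reset_index(drop=True)
    )
    return table
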