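"""Pathway over-representation analysis of penalised-regression supports.

A selected metabolite set (the nonzero coefficients of a sparse fit, or the
top-k by magnitude) is tested against each pathway with the upper-tail
hypergeometric probability P(X >= overlap), with the measured-and-mappable
metabolite roster as the sampling universe. Scores are -log10 of the raw
p-value; Benjamini-Hochberg adjusted p-values are reported alongside.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .lasso import LassoFit

__all__ = ["PathwayCollection", "read_gmt", "select_features", "ora_test", "bh_adjust"]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _norm(name: str) -> str:
    return name.strip().lower()


@dataclass
class PathwayCollection:
    """Pathway id -> (display name, member set); universe = union of members."""

    pathways: dict[str, tuple[str, frozenset[str]]]

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for _, members in self.pathways.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.pathways)


def read_gmt(path: str | Path) -> PathwayCollection:
    """Parse a GMT file: tab-separated id, description, members (cols 3+).

    Members are trimmed, matched case-insensitively and deduplicated within
    a set. Blank lines are skipped; a data line with fewer than three
    columns is a parse error.
    """
    path = Path(path)
    pathways: dict[str, tuple[str, frozenset[str]]] = {}
    lines = path.read_text().splitlines()
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path.name}:{i}: GMT line has fewer than 3 columns")
        pid, desc = parts[0].strip(), parts[1].strip()
        members = frozenset(_norm(m) for m in parts[2:] if m.strip())
        if not members:
            raise ValueError(f"{path.name}:{i}: pathway {pid!r} has no members")
        pathways[pid] = (desc, members)
    if not pathways:
        raise ValueError(f"{path.name}: no pathways found")
    return PathwayCollection(pathways)


def select_features(
    fit: LassoFit, rule: str = "nonzero", top_k: int | None = None
) -> frozenset[str]:
    """Feature set a sparse fit selects: nonzero support or top-k by |coef|."""
    if rule == "nonzero":
        return frozenset(_norm(n) for n in fit.support)
    if rule == "top_k":
        if not top_k or top_k < 1:
            raise ValueError("top_k rule needs a positive top_k")
        order = np.argsort(-np.abs(fit.w), kind="stable")[:top_k]
        return frozenset(_norm(fit.feature_names[j]) for j in order if fit.w[j] != 0)
    raise ValueError(f"unknown selection rule {rule!r}")


def ora_test(
    selected: frozenset[str] | set[str],
    pathways: PathwayCollection,
    universe: frozenset[str] | set[str],
    min_size: int = 2,
) -> pd.DataFrame:
    """Hypergeometric over-representation table across a pathway collection.

    Population = |universe|, successes = pathway members in the universe,
    draws = |selected|; raw p = P(X >= overlap). Pathways with fewer than
    ``min_size`` members in the universe are not tested. An empty selection
    yields p = 1 everywhere.
    """
    if min_size < 1:
        raise ValueError("min_size must be at least 1")
    selected = frozenset(_norm(s) for s in selected)
    universe = frozenset(_norm(u) for u in universe)
    unmapped = selected - universe
    if unmapped:
        raise ValueError(f"selected identifiers outside the universe: {sorted(unmapped)}")
    rows = []
    M, n_draw = len(universe), len(selected)
    for pid, (desc, members) in pathways.pathways.items():
        in_universe = members & universe
        if len(in_universe) < min_size:
            continue
        overlap = len(in_universe & selected)
        if n_draw == 0:
            raw_p = 1.0
        else:
            raw_p = float(hypergeom.sf(overlap - 1, M, len(in_universe), n_draw))
        rows.append(
            {
                "pathway": pid,
                "name": desc,
                "overlap": overlap,
                "pathway_size": len(in_universe),
                "raw_p": min(raw_p, 1.0),
                "ora_score": -np.log10(min(raw_p, 1.0)) if raw_p > 0 else np.inf,
            }
        )
    table = pd.DataFrame(rows)
    if not table.empty:
        table["adjusted_p"] = bh_adjust(table["raw_p"])
        table = table.sort_values("raw_p", kind="stable").reset_index(drop=True)
    return table
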