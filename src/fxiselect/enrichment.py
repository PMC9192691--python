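"""Correlation-augmented over-representation analysis against GMT gene sets.

The query is the set of selected proteins plus any measured protein whose
absolute Spearman correlation with a selected protein exceeds 0.80 (strict).
Each gene set is intersected with the measured-protein background before a
one-sided hypergeometric (Fisher over-representation) test; raw p < 0.05
flags significance — no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)

SIGNIFICANCE_ALPHA = 0.05
RHO_THRESHOLD = 0.80


@dataclass
class GeneSetDB:
    """Named gene sets with uppercased symbols and a source label."""

    sets: dict[str, frozenset[str]]
    source: str = ""
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {
            name: frozenset(g.upper() for g in genes)
            for name, genes in self.sets.items()
        }

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path, source: str = "") -> GeneSetDB:
    """Read a GMT file (name, description, genes..., tab-separated)."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            logger.warning("skipping malformed GMT line: %r", line[:80])
            continue
        name, desc, genes = parts[0], parts[1], parts[2:]
        if name in sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        sets[name] = frozenset(g.upper() for g in genes if g)
        descriptions[name] = desc
    return GeneSetDB(sets=sets, source=source or str(path), descriptions=descriptions)


def write_gmt(db: GeneSetDB | dict, path: str | Path, description: str = "na") -> None:
    sets = db.sets if isinstance(db, GeneSetDB) else db
    lines = []
    for name in sorted(sets):
        genes = sorted(sets[name])
        desc = (
            db.descriptions.get(name, description)
            if isinstance(db, GeneSetDB)
            else description
        )
        lines.append("\t".join([name, desc] + genes))
    Path(path).write_text("\n".join(lines) + "\n")


def map_to_genes(ids, mapping: pd.DataFrame | None) -> list[str]:
    """Map protein ids to gene symbols via a two-column frame; identity if None.

    Unmapped proteins are dropped with a logged count.
    """
    if mapping is None:
        return [str(i).upper() for i in ids]
    lut = dict(zip(mapping.iloc[:, 0].astype(str), mapping.iloc[:, 1].astype(str)))
    mapped = [lut[str(i)].upper() for i in ids if str(i) in lut]
    n_dropped = len(list(ids)) - len(mapped)
    if n_dropped:
        logger.info("dropped %d unmapped proteins", n_dropped)
    return mapped


def augment_query(
    selected, matrix: pd.DataFrame, rho_threshold: float = RHO_THRESHOLD
) -> list[str]:
    """Selected proteins plus partners with |Spearman rho| strictly above threshold."""
    selected = list(selected)
    if not selected:
        return []
    missing = [s for s in selected if s not in matrix.columns]
    if missing:
        raise KeyError(f"selected proteins absent from matrix: {missing[:5]}")
    # Spearman = Pearson on ranks; one vectorized pass over all columns
    ranks = matrix.rank().to_numpy(dtype=float)
    std = ranks.std(axis=0)
    std[std == 0] = np.inf  # constant columns contribute zero correlation
    ranks = (ranks - ranks.mean(axis=0)) / std
    cols = {c: i for i, c in enumerate(matrix.columns)}
    sel_idx = [cols[s] for s in selected]
    rho = np.abs(ranks.T @ ranks[:, sel_idx]) / ranks.shape[0]
    best = rho.max(axis=1)
    partners = {
        c
        for c, i in cols.items()
        if c not in selected and best[i] > rho_threshold
    }
    return sorted(set(selected) | partners)


def hypergeom_test(overlap: int, query_n: int, set_n: int, background_n: int) -> float:
    """One-sided over-representation p-value: P(X >= overlap).

    X ~ Hypergeometric(background_n, set_n, query_n).
    """
    if not (
        0 <= overlap <= min(query_n, set_n)
        and max(query_n, set_n) <= background_n
    ):
        raise ValueError(
            f"inconsistent counts: overlap={overlap}, query={query_n}, "
            f"set={set_n}, background={background_n}"
        )
    return float(hypergeom.sf(overlap - 1, background_n, set_n, query_n))


def enrich(
    query,
    db: GeneSetDB,
    background,
    alpha: float = SIGNIFICANCE_ALPHA,
) -> pd.DataFrame:
    """Test each gene set against the query, restricted to the background.

    Returns a frame sorted by p-value (set-name tie-break) with columns
    ``set``, ``overlap``, ``query_n``, ``set_n``, ``background_n``, ``p``,
    ``significant``, plus overlapping genes.
    """
    background = {str(g).upper() for g in background}
    if not background:
        raise ValueError("empty background")
    query_in = {str(g).upper() for g in query} & background
    n_outside = len(set(query)) - len(query_in)
    if n_outside:
        logger.info("ignored %d query genes absent from background", n_outside)
    rows = []
    for name in sorted(db.sets):
        eff = db.sets[name] & background
        hits = sorted(eff & query_in)
        p = hypergeom_test(len(hits), len(query_in), len(eff), len(background))
        rows.append(
            {
                "set": name,
                "overlap": len(hits),
                "query_n": len(query_in),
                "set_n": len(eff),
                "background_n": len(background),
                "p": p,
                "significant": p < alpha,
                "genes": ",".join(hits),
            }
        )
    res = pd.DataFrame(rows)
    if len(res):
        res = res.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    return res


def compare_timepoints(res_a: pd.DataFrame, res_b: pd.DataFrame) -> dict:
    """Partition significant sets into shared / A-specific / B-specific."""
    sig_a = set(res_a.loc[res_a["significant"], "set"])
    sig_b = set(res_b.loc[res_b["significant"], "set"])
    return {
        "shared": sorted(sig_a & sig_b),
        "a_specific": sorted(sig_a - sig_b),
        "b_specific": sorted(sig_b - sig_a),
    }
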