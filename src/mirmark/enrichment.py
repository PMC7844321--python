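"""Over-representation analysis of target genes against named gene sets.

A generic hypergeometric/Fisher ORA: for a target list of size n drawn from
a universe of N genes, the overlap k with a gene set of size K is tested
against the upper tail P(X >= k) of Hypergeometric(N, K, n).  The ``ease``
mode applies the EASE-score convention (substitute k - 1 for k, floored at
0), a deliberately conservative variant.  BH adjustment is applied across
the collection; a "top terms" report keeps the ten smallest raw p below the
significance cut.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets with GMT semantics (name, description, members)."""

    sets: dict          # name -> frozenset of gene ids
    descriptions: dict  # name -> str

    def __post_init__(self) -> None:
        empty = [n for n, s in self.sets.items() if not s]
        if empty:
            raise ValueError(f"empty gene set(s): {empty[:5]}")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name, description, then tab-separated members."""
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT needs >= 3 fields")
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}: duplicate gene-set name {name!r}")
            sets[name] = frozenset(f for f in fields[2:] if f)
            descriptions[name] = fields[1]
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            members = "\t".join(sorted(collection.sets[name]))
            fh.write(f"{name}\t{collection.descriptions.get(name, '')}\t{members}\n")


def hypergeom_upper_tail(n_universe: int, n_set: int, n_targets: int, overlap: int) -> float:
    """P(X >= overlap) for X ~ Hypergeometric(N=n_universe, K=n_set, n=n_targets)."""
    return float(stats.hypergeom.sf(overlap - 1, n_universe, n_set, n_targets))


def ora_test(
    targets,
    collection: GeneSetCollection,
    universe,
    mode: str = "fisher",
) -> pd.DataFrame:
    """One-sided over-representation p per gene set, BH-adjusted.

    ``mode="fisher"`` tests the observed overlap; ``mode="ease"`` tests
    overlap - 1 (floored at 0).  Targets outside the universe are dropped
    with a logged count, and each set is intersected with the universe
    before testing.  Rows sorted by raw p.
    """
    if mode not in ("fisher", "ease"):
        raise ValueError(f"unknown ORA mode: {mode!r}")
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    if not len(collection):
        raise ValueError("empty gene-set collection")
    targets = set(targets)
    outside = targets - universe
    if outside:
        logger.info("%d target(s) outside the universe dropped", len(outside))
        targets &= universe

    n_univ, n_targ = len(universe), len(targets)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        if not members:
            continue
        hits = targets & members
        k = len(hits)
        k_eff = max(k - 1, 0) if mode == "ease" else k
        p = hypergeom_upper_tail(n_univ, len(members), n_targ, k_eff)
        rows.append(
            (name, len(members), k, p, ",".join(sorted(hits)))
        )
    df = pd.DataFrame(rows, columns=["set", "size", "overlap", "p_raw", "members_in_overlap"])
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy()) if len(df) else []
    df = df[["set", "size", "overlap", "p_raw", "p_adj", "members_in_overlap"]]
    return df.sort_values(["p_raw", "set"], kind="mergesort").reset_index(drop=True)


def top_terms(table: pd.DataFrame, alpha: float = 0.05, n: int = 10) -> pd.DataFrame:
    """The (up to) ``n`` most significant terms with raw p < ``alpha``."""
    return table[table["p_raw"] < alpha].head(n).reset_index(drop=True)


def write_enrichment(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
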