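"""Local over-representation analysis against GMT gene-set collections.

Replaces a web ORA service with an offline hypergeometric test: for a query
of n genes drawn from a universe of M, a term with K members and k overlap
gets the upper-tail probability P(X >= k) under the hypergeometric
distribution.  BH correction is applied within each (cell line, direction)
run; results are filtered to adjusted p < 0.05 with a non-zero overlap.
The display rule unions each cell line's top-20 terms per direction and
attaches the partner line's row for every included term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .modstats import bh_adjust

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "hypergeom_tail",
    "ora",
    "select_display",
]


@dataclass
class GeneSetCollection:
    """Named gene sets (uppercased symbols) with per-set source tags."""

    sets: dict[str, list[str]]
    sources: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            self.sets[name] = sorted(dict.fromkeys(g.upper() for g in members))
            self.sources.setdefault(name, name.split("_", 1)[0])

    def __len__(self) -> int:
        return len(self.sets)

    def restrict(self, universe: set[str]) -> "GeneSetCollection":
        universe = {g.upper() for g in universe}
        return GeneSetCollection(
            sets={n: [g for g in m if g in universe] for n, m in self.sets.items()},
            sources=dict(self.sources),
            descriptions=dict(self.descriptions),
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse the tab-separated GMT dialect: name, description, members..."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields "
                             "(need name, description and >=1 member)")
        name, desc, *members = fields
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = [m for m in members if m]
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeom_tail(M: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, n)."""
    if not 0 <= k <= min(K, n):
        if k > min(K, n):
            return 0.0
        raise ValueError("k must be >= 0")
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def ora(query: set[str] | list[str], collection: GeneSetCollection,
        universe: set[str] | list[str], alpha: float = 0.05,
        filter_results: bool = True) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list against every set.

    Query genes outside the universe are dropped (count recorded in
    ``DataFrame.attrs['dropped_query_genes']``).  BH correction runs across
    all terms of this call; callers testing several (cell line, direction)
    strata run one call per stratum.
    """
    universe = {g.upper() for g in universe}
    raw_query = {g.upper() for g in query}
    query_set = raw_query & universe
    if len(universe) < len(raw_query):
        raise ValueError("universe is smaller than the query list")
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    restricted = collection.restrict(universe)

    M, n = len(universe), len(query_set)
    rows = []
    for name, members in restricted.sets.items():
        K = len(members)
        k = len(query_set.intersection(members))
        p = hypergeom_tail(M, K, n, k) if K > 0 else 1.0
        rows.append({
            "term": name,
            "source": restricted.sources.get(name, ""),
            "overlap": k, "set_size": K, "query_size": n, "universe_size": M,
            "p": p,
            "genes": ",".join(sorted(query_set.intersection(members))),
        })
    out = pd.DataFrame(rows).set_index("term")
    out["fdr"] = bh_adjust(out["p"].to_numpy())
    out["neg_log10_fdr"] = -np.log10(np.maximum(out["fdr"], np.finfo(float).tiny))
    out.attrs["dropped_query_genes"] = len(raw_query) - len(query_set)
    if filter_results:
        out = out[(out["fdr"] < alpha) & (out["overlap"] > 0)]
    return out.sort_values(["fdr", "p"], kind="mergesort")


def select_display(results: dict[str, pd.DataFrame], top_n: int = 20) -> pd.DataFrame:
    """Union of each cell line's top-``top_n`` terms, partner rows attached.

    ``results`` maps cell line ('WT'/'AI') to an already filtered ORA table
    for one direction.  Terms present in only one line carry NaN in the
    other line's columns, flagged not-significant.
    """
    chosen: list[str] = []
    for line in sorted(results):
        table = results[line].sort_values(["fdr", "p"], kind="mergesort")
        for term in table.index[:top_n]:
            if term not in chosen:
                chosen.append(term)
    rows = []
    for term in chosen:
        row: dict = {"term": term}
        for line, table in results.items():
            if term in table.index:
                row[f"{line}_fdr"] = float(table.loc[term, "fdr"])
                row[f"{line}_neg_log10_fdr"] = float(table.loc[term, "neg_log10_fdr"])
                row[f"{line}_overlap"] = int(table.loc[term, "overlap"])
                row[f"{line}_significant"] = True
            else:
                row[f"{line}_fdr"] = np.nan
                row[f"{line}_neg_log10_fdr"] = np.nan
                row[f"{line}_overlap"] = 0
                row[f"{line}_significant"] = False
        rows.append(row)
    if not rows:
        cols = ["term"]
        return pd.DataFrame(columns=cols).set_index("term")
    return pd.DataFrame(rows).set_index("term")
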