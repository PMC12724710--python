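"""Protein-interaction graph assembly, node annotation and MCODE modules.

Edges come from a STRING-export TSV (``geneA``, ``geneB``,
``combined_score``); both the 0-1 and the 0-1000 score dialects are
auto-detected.  Edges at or above the confidence threshold (default 0.4)
are kept, the largest connected component is extracted, nodes are
annotated with the omics layer(s) backing them, and densely connected
modules are detected with MCODE:

1. vertex weighting -- for every node v of degree >= degree_cutoff, take
   the closed neighbourhood N[v], find its highest k-core, and set
   w(v) = k_max * density(k-core);
2. greedy seeded expansion -- seeds are unused nodes in decreasing weight
   order (ties by node id); from a seed of weight w_s > 0, breadth-first
   expansion adds unused neighbours with w >= (1 - node_score_cutoff)*w_s;
3. post-processing -- haircut trims to the k_core-core of the module
   subgraph (iteratively removing low-degree members); modules without a
   k_core-core are discarded.  Module score = density * size; modules are
   disjoint and ranked by score.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .glycan import glyco_gene
from .integrate import phospho_gene

__all__ = [
    "MCODEParams",
    "NetworkModule",
    "load_edges",
    "largest_component",
    "annotate_nodes",
    "vertex_weights",
    "mcode",
    "export_network",
    "import_network",
]


@dataclass
class MCODEParams:
    node_score_cutoff: float = 0.1
    degree_cutoff: int = 2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False

    def __post_init__(self) -> None:
        if self.node_score_cutoff < 0:
            raise ValueError("node_score_cutoff must be >= 0")
        if self.degree_cutoff < 0:
            raise ValueError("degree_cutoff must be >= 0")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")
        if self.fluff:
            raise NotImplementedError("fluff post-processing is not supported")


@dataclass
class NetworkModule:
    members: list[str]
    seed: str
    score: float
    rank: int

    def to_dict(self) -> dict:
        return {"rank": self.rank, "seed": self.seed, "score": self.score,
                "members": self.members}


# ----------------------------------------------------------------------
# graph assembly
# ----------------------------------------------------------------------

def load_edges(path: str | Path, threshold: float = 0.4) -> nx.Graph:
    """Read a STRING-style edge list; normalise scores; keep edges >= threshold."""
    df = pd.read_csv(path, sep="\t")
    required = ["geneA", "geneB", "combined_score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"edge list missing columns: {missing}")
    scores = pd.to_numeric(df["combined_score"], errors="raise").astype(float)
    if (scores > 1.0).any():        # 0-1000 STRING dialect
        scores = scores / 1000.0
    G = nx.Graph()
    for a, b, s in zip(df["geneA"].astype(str), df["geneB"].astype(str), scores):
        if a == b or s < threshold:
            continue
        if G.has_edge(a, b):
            G[a][b]["confidence"] = max(G[a][b]["confidence"], float(s))
        else:
            G.add_edge(a, b, confidence=float(s))
    return G


def largest_component(G: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest component; ties broken lexicographically."""
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = [sorted(c) for c in nx.connected_components(G)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return G.subgraph(comps[0]).copy()


def annotate_nodes(G: nx.Graph, glyco_de: pd.DataFrame | None,
                   phospho_de: pd.DataFrame | None) -> nx.Graph:
    """Attach layer, modification count and signed max-|log2FC| per gene.

    Both DE tables must already be restricted to significant features; the
    glycopeptide and phosphosite id grammars map features to genes.  Genes
    absent from the graph are counted but otherwise ignored.
    """
    per_gene: dict[str, dict] = {}

    def collect(de: pd.DataFrame | None, layer: str, gene_of) -> None:
        if de is None:
            return
        for fid, logfc in de["logFC"].items():
            gene = gene_of(fid)
            rec = per_gene.setdefault(gene, {"glyco": 0, "phospho": 0,
                                             "max_abs_logfc": 0.0,
                                             "signed_max_logfc": 0.0})
            rec[layer] += 1
            if abs(logfc) > rec["max_abs_logfc"]:
                rec["max_abs_logfc"] = abs(float(logfc))
                rec["signed_max_logfc"] = float(logfc)

    collect(glyco_de, "glyco", glyco_gene)
    collect(phospho_de, "phospho", phospho_gene)

    unmapped = 0
    for gene, rec in per_gene.items():
        if gene not in G:
            unmapped += 1
            continue
        layer = "dual" if rec["glyco"] and rec["phospho"] else (
            "glyco" if rec["glyco"] else "phospho")
        G.nodes[gene]["layer"] = layer
        G.nodes[gene]["modification_count"] = rec["glyco"] + rec["phospho"]
        G.nodes[gene]["max_logfc"] = rec["signed_max_logfc"]
    G.graph["unmapped_genes"] = unmapped
    return G


# ----------------------------------------------------------------------
# MCODE
# ----------------------------------------------------------------------

def _density(H: nx.Graph) -> float:
    n = H.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * H.number_of_edges() / (n * (n - 1))


def _highest_k_core(H: nx.Graph) -> tuple[int, nx.Graph]:
    """(k_max, subgraph) of the highest k-core; (0, empty) if H has no edges."""
    if H.number_of_edges() == 0:
        return 0, H.subgraph([])
    core_num = nx.core_number(H)
    k_max = max(core_num.values())
    nodes = [v for v, k in core_num.items() if k >= k_max]
    return k_max, H.subgraph(nodes)


def vertex_weights(G: nx.Graph, params: MCODEParams | None = None) -> dict[str, float]:
    """MCODE local vertex weights; nodes below the degree cutoff weigh 0."""
    params = params or MCODEParams()
    weights: dict[str, float] = {}
    for v in G.nodes:
        if G.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = list(G.neighbors(v)) + [v]
        k_max, core = _highest_k_core(G.subgraph(closed))
        weights[v] = float(k_max) * _density(core)
    return weights


def _haircut(members: set, G: nx.Graph, k: int) -> set:
    """Iteratively drop members with in-module degree < k (the k-core)."""
    sub = G.subgraph(members).copy()
    while True:
        low = [v for v in sub.nodes if sub.degree(v) < k]
        if not low:
            return set(sub.nodes)
        sub.remove_nodes_from(low)


def mcode(G: nx.Graph, params: MCODEParams | None = None) -> list[NetworkModule]:
    """Detect disjoint dense modules; ranked by score = density * size."""
    params = params or MCODEParams()
    weights = vertex_weights(G, params)
    seeds = sorted((v for v in G.nodes if weights[v] > 0),
                   key=lambda v: (-weights[v], str(v)))
    used: set = set()
    raw_modules: list[tuple[set, str]] = []
    for seed in seeds:
        if seed in used:
            continue
        threshold = (1.0 - params.node_score_cutoff) * weights[seed]
        members = {seed}
        queue = deque([seed])
        while queue:
            v = queue.popleft()
            for u in G.neighbors(v):
                if u in members or u in used:
                    continue
                if weights[u] >= threshold:
                    members.add(u)
                    queue.append(u)
        used |= members
        raw_modules.append((members, seed))

    modules: list[NetworkModule] = []
    for members, seed in raw_modules:
        core = _haircut(members, G, params.k_core)
        if not core:          # no k_core-core: discard
            continue
        final = core if params.haircut else members
        sub = G.subgraph(final)
        score = _density(sub) * sub.number_of_nodes()
        modules.append(NetworkModule(members=sorted(final),
                                     seed=seed, score=score, rank=0))
    modules.sort(key=lambda m: (-m.score, m.members))
    for i, m in enumerate(modules, start=1):
        m.rank = i
    return modules


# ----------------------------------------------------------------------
# export
# ----------------------------------------------------------------------

def export_network(G: nx.Graph, modules: list[NetworkModule],
                   out_dir: str | Path, prefix: str = "network") -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    module_of = {}
    for m in modules:
        for v in m.members:
            module_of.setdefault(v, m.rank)

    gml = out_dir / f"{prefix}.graphml"
    H = G.copy()
    H.graph.pop("unmapped_genes", None)
    for v in H.nodes:
        H.nodes[v].setdefault("layer", "")
        H.nodes[v].setdefault("modification_count", 0)
        H.nodes[v].setdefault("max_logfc", 0.0)
        H.nodes[v]["module"] = module_of.get(v, 0)
    nx.write_graphml(H, gml)
    paths["graphml"] = gml

    node_rows = [{"gene": v, **H.nodes[v]} for v in sorted(H.nodes)]
    nodes_path = out_dir / f"{prefix}_nodes.tsv"
    pd.DataFrame(node_rows).to_csv(nodes_path, sep="\t", index=False)
    paths["nodes"] = nodes_path

    edge_rows = [{"geneA": min(a, b), "geneB": max(a, b),
                  "confidence": d["confidence"]}
                 for a, b, d in H.edges(data=True)]
    edge_rows.sort(key=lambda r: (r["geneA"], r["geneB"]))
    edges_path = out_dir / f"{prefix}_edges.tsv"
    pd.DataFrame(edge_rows, columns=["geneA", "geneB", "confidence"]).to_csv(
        edges_path, sep="\t", index=False)
    paths["edges"] = edges_path

    modules_path = out_dir / f"{prefix}_modules.json"
    modules_path.write_text(json.dumps([m.to_dict() for m in modules], indent=2))
    paths["modules"] = modules_path
    return paths


def import_network(graphml_path: str | Path) -> nx.Graph:
    return nx.read_graphml(graphml_path)
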