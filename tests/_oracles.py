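"""Independent reference implementations used only to check the package.

Each oracle takes a deliberately different computational route from the code
under test: explicit normal equations for least squares, log-gamma tail
enumeration for the hypergeometric test, and subset-enumeration /
fixpoint-expansion for MCODE.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def ols_reference(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """(beta, s2) via explicit matrix inversion of the normal equations."""
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    d = X.shape[0] - X.shape[1]
    return beta, float(resid @ resid / d)


def quadratic_form_reference(beta: np.ndarray, C: np.ndarray,
                             xtx_inv: np.ndarray, s2: float) -> float:
    """Moderated-F numerator via brute-force quadratic form."""
    k = C.shape[0]
    mid = np.linalg.inv(C @ xtx_inv @ C.T)
    cb = C @ beta
    return float(cb @ mid @ cb / (k * s2))


def bh_reference(p: list[float]) -> list[float]:
    """Direct enumeration of the step-up formula adj_(i) = min_{j>=i} p_(j) m/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    for rank_i, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(rank_i, m + 1)]
        adj[idx] = min(1.0, min(candidates))
    return adj


def hypergeom_tail_reference(M: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by log-gamma enumeration of the upper tail."""
    def log_comb(a, b):
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    total = 0.0
    for i in range(k, min(K, n) + 1):
        if n - i > M - K:
            continue
        total += math.exp(log_comb(K, i) + log_comb(M - K, n - i) - log_comb(M, n))
    return min(total, 1.0)


# ----------------------------------------------------------------------
# MCODE reference (subset enumeration; fixpoint expansion)
# ----------------------------------------------------------------------

def _bf_highest_kcore(H: nx.Graph) -> tuple[int, set]:
    """Highest k-core by enumerating every vertex subset (graphs <= ~12 nodes)."""
    nodes = list(H.nodes)
    best_k, best = 0, set()
    for k in range(1, len(nodes)):
        union: set = set()
        for r in range(k + 1, len(nodes) + 1):
            for sub in itertools.combinations(nodes, r):
                S = H.subgraph(sub)
                if min(dict(S.degree).values(), default=-1) >= k:
                    union |= set(sub)
        if union:
            best_k, best = k, union
        else:
            break
    return best_k, best


def _density(H: nx.Graph) -> float:
    n = H.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * H.number_of_edges() / (n * (n - 1))


def _bf_weights(G: nx.Graph, degree_cutoff: int) -> dict:
    w = {}
    for v in G.nodes:
        if G.degree(v) < degree_cutoff:
            w[v] = 0.0
            continue
        closed = set(G.neighbors(v)) | {v}
        k, core = _bf_highest_kcore(G.subgraph(closed))
        w[v] = k * _density(G.subgraph(core))
    return w


def _bf_haircut(members: set, G: nx.Graph, k: int) -> set:
    members = set(members)
    while True:
        degs = {v: sum(1 for u in G.neighbors(v) if u in members) for v in members}
        low = {v for v, d in degs.items() if d < k}
        if not low:
            return members
        members -= low


def mcode_reference(G: nx.Graph, node_score_cutoff: float = 0.1,
                    degree_cutoff: int = 2, k_core: int = 2) -> list[dict]:
    """Seed-by-seed fixpoint expansion; returns ranked module dicts."""
    w = _bf_weights(G, degree_cutoff)
    seeds = sorted((v for v in G.nodes if w[v] > 0), key=lambda v: (-w[v], str(v)))
    used: set = set()
    raw = []
    for seed in seeds:
        if seed in used:
            continue
        threshold = (1.0 - node_score_cutoff) * w[seed]
        allowed = {v for v in G.nodes if v not in used and w[v] >= threshold}
        members = {seed}
        changed = True
        while changed:
            changed = False
            for v in sorted(allowed - members, key=str):
                if any(u in members for u in G.neighbors(v)):
                    members.add(v)
                    changed = True
        used |= members
        raw.append((members, seed))
    modules = []
    for members, seed in raw:
        core = _bf_haircut(members, G, k_core)
        if not core:
            continue
        sub = G.subgraph(core)
        modules.append({"members": sorted(core), "seed": seed,
                        "score": _density(sub) * sub.number_of_nodes()})
    modules.sort(key=lambda m: (-m["score"], m["members"]))
    return modules
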