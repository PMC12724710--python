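"""Cross-layer feature selection, clustered heatmap blocks, response catalog.

Integration selects the top-``k`` features per layer by omnibus moderated F
(FDR-filtered), assembles row-z-scored heatmap blocks with deterministic
Euclidean/complete-linkage clustering, and categorises serum-response
phosphosites into WT*-only / AI*-only / Both / NS with an any-site collapse
to proteins.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import IntensityMatrix

__all__ = [
    "IntegrationConfig",
    "HeatmapBlock",
    "select_features",
    "build_block",
    "pathway_heatmap",
    "categorize_response",
    "collapse_to_proteins",
    "phospho_gene",
    "cut_samples",
]

CATEGORIES = ("WT*", "AI*", "Both", "NS")


@dataclass
class IntegrationConfig:
    top_k: int = 500
    fdr_cutoff: float = 0.05
    completeness: float = 0.70
    # distance/linkage fixed to the study's choices; kept visible for the manifest
    distance: str = "euclidean"
    linkage: str = "complete"

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness must lie in (0,1]")


@dataclass
class HeatmapBlock:
    """Row-z-scored matrix with deterministic row/column dendrogram orders."""

    layer: str
    values: pd.DataFrame          # z-scored, original row/col order
    row_order: list[str]
    col_order: list[str]
    row_linkage: np.ndarray | None = None
    col_linkage: np.ndarray | None = None
    dropped_rows: list[str] = field(default_factory=list)
    row_groups: dict[str, list[str]] | None = None   # pathway -> ordered rows

    def ordered(self) -> pd.DataFrame:
        return self.values.loc[self.row_order, self.col_order]

    def write(self, prefix: str | Path) -> list[Path]:
        prefix = Path(prefix)
        values_path = prefix.with_suffix(".tsv")
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(values_path, sep="\t")
        meta_path = prefix.with_suffix(".json")
        meta = {
            "layer": self.layer,
            "row_order": self.row_order,
            "col_order": self.col_order,
            "dropped_rows": self.dropped_rows,
            "row_groups": self.row_groups,
        }
        meta_path.write_text(json.dumps(meta, indent=2))
        return [values_path, meta_path]


def select_features(f_table: pd.DataFrame, cfg: IntegrationConfig) -> list[str]:
    """FDR-filter then rank by F descending, tie-broken by feature id."""
    passing = f_table[f_table["fdr"] < cfg.fdr_cutoff]
    ranked = passing.sort_index(kind="mergesort").sort_values(
        "F", ascending=False, kind="mergesort")
    return list(ranked.index[:cfg.top_k])


def _zscore_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    constant = sd <= 0
    dropped = list(values.index[constant])
    z = values.loc[~constant].sub(mean[~constant], axis=0).div(sd[~constant], axis=0)
    return z, dropped


def _cluster_order(values: np.ndarray, labels: list[str], cfg: IntegrationConfig
                   ) -> tuple[list[str], np.ndarray]:
    if len(labels) < 2:
        return list(labels), None
    dist = pdist(values, metric=cfg.distance)
    Z = hierarchy.linkage(dist, method=cfg.linkage)
    order = hierarchy.leaves_list(Z)
    return [labels[i] for i in order], Z


def build_block(matrix: IntensityMatrix, features: list[str],
                cfg: IntegrationConfig | None = None,
                samples: list[str] | None = None) -> HeatmapBlock:
    """Completeness-filter, z-score and bicluster the selected features.

    ``matrix`` should be the imputed log2 matrix (its ``detected`` mask is
    the pre-imputation detection record used for the completeness filter).
    """
    cfg = cfg or IntegrationConfig()
    features = [f for f in features if f in matrix.feature_ids]
    samples = list(samples) if samples is not None else list(matrix.sample_ids)
    needed = int(np.ceil(cfg.completeness * len(samples) - 1e-9))
    detected = matrix.detected.loc[features, samples]
    keep = detected.sum(axis=1) >= needed
    vals = matrix.values.loc[keep[keep].index, samples]
    z, dropped = _zscore_rows(vals)
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("fewer than 2 features or samples survive filtering")
    row_order, row_Z = _cluster_order(z.to_numpy(), list(z.index), cfg)
    col_order, col_Z = _cluster_order(z.to_numpy().T, list(z.columns), cfg)
    return HeatmapBlock(layer=matrix.layer, values=z, row_order=row_order,
                        col_order=col_order, row_linkage=row_Z,
                        col_linkage=col_Z, dropped_rows=dropped)


def pathway_heatmap(matrix: IntensityMatrix, pathway_sites: dict[str, list[str]],
                    cfg: IntegrationConfig | None = None,
                    samples: list[str] | None = None) -> HeatmapBlock:
    """Supervised pathway grouping with unsupervised clustering within groups.

    Row order never crosses pathway boundaries; pathways appear in sorted
    label order; a pathway with <2 sites is emitted unclustered.
    """
    cfg = cfg or IntegrationConfig()
    samples = list(samples) if samples is not None else list(matrix.sample_ids)
    all_sites: list[str] = []
    for sites in pathway_sites.values():
        all_sites.extend(s for s in sites if s in matrix.feature_ids)
    all_sites = list(dict.fromkeys(all_sites))
    vals = matrix.values.loc[all_sites, samples]
    z, dropped = _zscore_rows(vals)

    row_order: list[str] = []
    row_groups: dict[str, list[str]] = {}
    for pathway in sorted(pathway_sites):
        sites = [s for s in pathway_sites[pathway] if s in z.index]
        if len(sites) >= 2:
            order, _ = _cluster_order(z.loc[sites].to_numpy(), sites, cfg)
        else:
            order = list(sites)
        row_groups[pathway] = order
        row_order.extend(order)
    col_order, col_Z = _cluster_order(z.loc[row_order].to_numpy().T,
                                      list(z.columns), cfg) \
        if len(row_order) >= 1 else (samples, None)
    return HeatmapBlock(layer=matrix.layer, values=z.loc[row_order],
                        row_order=row_order, col_order=col_order,
                        col_linkage=col_Z, dropped_rows=dropped,
                        row_groups=row_groups)


def cut_samples(block: HeatmapBlock, n_clusters: int = 2) -> pd.Series:
    """Flat sample clusters from the column dendrogram (for cluster-recovery checks)."""
    if block.col_linkage is None:
        raise ValueError("block has no column dendrogram")
    labels = hierarchy.fcluster(block.col_linkage, t=n_clusters, criterion="maxclust")
    return pd.Series(labels, index=block.values.columns, name="cluster")


# ----------------------------------------------------------------------
# serum-response categorisation
# ----------------------------------------------------------------------

def categorize_response(de_wt: pd.DataFrame, de_ai: pd.DataFrame) -> pd.DataFrame:
    """Classify each feature as WT*-only, AI*-only, Both or NS significant.

    The universe is the union of both tables; a feature absent from one
    table is treated as not significant there.
    """
    universe = de_wt.index.union(de_ai.index)
    wt_sig = de_wt["significant"].reindex(universe, fill_value=False).astype(bool)
    ai_sig = de_ai["significant"].reindex(universe, fill_value=False).astype(bool)
    category = np.select(
        [wt_sig & ai_sig, wt_sig & ~ai_sig, ~wt_sig & ai_sig],
        ["Both", "WT*", "AI*"], default="NS")
    return pd.DataFrame({"wt_sig": wt_sig, "ai_sig": ai_sig,
                         "category": category}, index=universe)


def phospho_gene(site_id: str) -> str:
    """GENE from a GENE_S123 phosphosite id; raises on malformed ids."""
    gene, _, site = site_id.rpartition("_")
    if not gene or len(site) < 2 or site[0] not in "STY" or not site[1:].isdigit():
        raise ValueError(f"phosphosite id {site_id!r} does not match GENE_S123")
    return gene


def collapse_to_proteins(catalog: pd.DataFrame,
                         site_to_gene: dict[str, str] | None = None,
                         ) -> pd.DataFrame:
    """Any-site collapse: a protein is significant in a line iff any site is."""
    genes = {}
    skipped = []
    for site in catalog.index:
        if site_to_gene is not None:
            gene = site_to_gene.get(site)
            if gene is None:
                skipped.append(site)
                continue
        else:
            try:
                gene = phospho_gene(site)
            except ValueError:
                skipped.append(site)
                continue
        genes[site] = gene
    cat = catalog.loc[list(genes)].copy()
    cat["gene"] = [genes[s] for s in cat.index]
    agg = cat.groupby("gene")[["wt_sig", "ai_sig"]].any()
    category = np.select(
        [agg["wt_sig"] & agg["ai_sig"], agg["wt_sig"] & ~agg["ai_sig"],
         ~agg["wt_sig"] & agg["ai_sig"]],
        ["Both", "WT*", "AI*"], default="NS")
    out = agg.copy()
    out["category"] = category
    out.attrs["skipped_sites"] = skipped
    out.attrs["collapse_rule"] = "any-site"
    return out
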