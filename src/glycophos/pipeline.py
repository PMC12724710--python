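"""Config-driven orchestration of the full analysis with a run manifest.

``run_all`` executes, in order: (1) data acquisition (synthetic generation
or loading the three TSV matrices + design), (2) per-layer preprocessing,
(3) differential statistics (baseline AI-vs-WT on starved samples;
within-line treated-vs-untreated; 2x2 factorial omnibus F), (4) glycan
class summaries, (5) cross-layer integration and the serum-response
catalog, (6) over-representation analysis, (7) network assembly + MCODE.
Every output file is recorded (with its SHA-256) in ``manifest.json``;
identical config + seed give byte-identical output directories.

One global seed fans out to per-stage seeds by hashing the stage name, so
a stage re-run in isolation reproduces the full-run behaviour.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .containers import IntensityMatrix, design_subset, read_design
from .enrich import GeneSetCollection, ora, read_gmt, select_display, write_gmt
from .glycan import (class_flags_table, class_logfc_summary, class_ratios,
                     glyco_gene, target_splot)
from .integrate import (IntegrationConfig, categorize_response,
                        collapse_to_proteins, phospho_gene, build_block,
                        select_features)
from .modstats import SignifConfig, factorial_F, pairwise_de
from .network import (MCODEParams, annotate_nodes, export_network,
                      largest_component, load_edges, mcode)
from .preprocess import preprocess_layer
from .simulate import (SimulationConfig, generate_dataset, generate_gene_sets,
                       generate_interactions, write_dataset)

logger = logging.getLogger("glycophos")

__all__ = ["RunConfig", "run_all", "stage_seed", "load_config"]

_LAYERS = ("global", "glyco", "phospho")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed (< 2^31) from the global seed and stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31 - 1)


@dataclass
class RunConfig:
    """Everything a run needs; exactly one of synthetic/file mode."""

    out_dir: str = "glycophos_out"
    seed: int = 0
    # file mode: paths to the three raw matrices + design table
    matrix_paths: dict | None = None        # {"global": ..., "glyco": ..., "phospho": ...}
    design_path: str | None = None
    gmt_path: str | None = None             # optional in synthetic mode
    edges_path: str | None = None           # optional in synthetic mode
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    signif: SignifConfig = field(default_factory=SignifConfig)
    integration: IntegrationConfig = field(default_factory=IntegrationConfig)
    mcode_params: MCODEParams = field(default_factory=MCODEParams)
    min_detection_rate: float = 0.70
    edge_threshold: float = 0.4

    @property
    def synthetic_mode(self) -> bool:
        return self.matrix_paths is None

    def validate(self) -> None:
        if (self.matrix_paths is None) != (self.design_path is None):
            raise ValueError("file mode needs both matrix_paths and design_path")
        if self.matrix_paths is not None:
            missing_keys = [l for l in _LAYERS if l not in self.matrix_paths]
            if missing_keys:
                raise ValueError(f"matrix_paths missing layers: {missing_keys}")
            for layer, path in self.matrix_paths.items():
                if not Path(path).is_file():
                    raise ValueError(f"matrix file for {layer!r} not found: {path}")
            if not Path(self.design_path).is_file():
                raise ValueError(f"design file not found: {self.design_path}")
            for name, p in (("gmt_path", self.gmt_path), ("edges_path", self.edges_path)):
                if p is not None and not Path(p).is_file():
                    raise ValueError(f"{name} not found: {p}")


def load_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML/JSON mapping of overrides."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
    nested = {
        "simulation": SimulationConfig,
        "signif": SignifConfig,
        "integration": IntegrationConfig,
        "mcode_params": MCODEParams,
    }
    kwargs = {}
    for key, value in raw.items():
        if key in nested:
            kwargs[key] = nested[key](**value)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


# ----------------------------------------------------------------------

class _Manifest:
    def __init__(self, out_dir: Path, config: RunConfig):
        self.out_dir = out_dir
        self.stages: list[dict] = []
        self.config = config

    def record(self, stage: str, outputs: list[Path]) -> None:
        entries = []
        for p in sorted(set(map(Path, outputs))):
            entries.append({
                "path": str(p.relative_to(self.out_dir)),
                "sha256": hashlib.sha256(p.read_bytes()).hexdigest(),
            })
        self.stages.append({"stage": stage, "outputs": entries})

    def write(self) -> Path:
        cfg = asdict(self.config)
        cfg.pop("out_dir", None)    # extrinsic: runs are reproducible across locations
        payload = {
            "version": __version__,
            "parameters": cfg,
            "stages": self.stages,
        }
        path = self.out_dir / "manifest.json"
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path


def _write_de(de: pd.DataFrame, path: Path) -> Path:
    out = de.copy()
    out.index.name = "feature_id"
    out.to_csv(path, sep="\t")
    return path


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out_dir, config)
    t_run = time.monotonic()

    def _stage(name):
        logger.info("stage %s starting", name)
        return time.monotonic()

    # ---------------- stage 1: data ----------------
    t0 = _stage("data")
    if config.synthetic_mode:
        sim = SimulationConfig(**{**asdict(config.simulation),
                                  "seed": stage_seed(config.seed, "simulate")})
        dataset = generate_dataset(sim)
        data_dir = out_dir / "data"
        paths = write_dataset(dataset, data_dir)
        matrices = dataset["matrices"]
        design = dataset["design"]
        manifest.record("simulate", list(paths.values()))
    else:
        matrices = {layer: IntensityMatrix.read_tsv(config.matrix_paths[layer],
                                                    scale="raw", layer=layer)
                    for layer in _LAYERS}
        design = read_design(config.design_path)
        manifest.record("load", [])
    logger.info("stage data done in %.1fs", time.monotonic() - t0)

    # ---------------- stage 2: preprocess ----------------
    t0 = _stage("preprocess")
    pre_dir = out_dir / "preprocess"
    pre_dir.mkdir(exist_ok=True)
    pre: dict[str, dict] = {}
    outputs = []
    for layer in _LAYERS:
        res = preprocess_layer(matrices[layer], design,
                               seed=stage_seed(config.seed, f"impute:{layer}"),
                               min_rate=config.min_detection_rate)
        pre[layer] = res
        p = pre_dir / f"{layer}_imputed.tsv"
        res["imputed"].to_tsv(p, mask_path=pre_dir / f"{layer}_detected.tsv")
        outputs += [p, pre_dir / f"{layer}_detected.tsv"]
        qc_path = pre_dir / f"{layer}_qc.json"
        res["qc"].to_json(qc_path)
        outputs.append(qc_path)
    manifest.record("preprocess", outputs)
    logger.info("stage preprocess done in %.1fs", time.monotonic() - t0)

    # ---------------- stage 3: differential statistics ----------------
    t0 = _stage("modstats")
    de_dir = out_dir / "de"
    de_dir.mkdir(exist_ok=True)
    outputs = []
    starved = design_subset(design, condition="untreated")
    baseline: dict[str, pd.DataFrame] = {}
    ftables: dict[str, pd.DataFrame] = {}
    serum: dict[tuple[str, str], pd.DataFrame] = {}
    for layer in _LAYERS:
        imputed = pre[layer]["imputed"]
        baseline[layer] = pairwise_de(imputed, starved, "cell_line", "AI", "WT",
                                      config.signif)
        outputs.append(_write_de(baseline[layer], de_dir / f"{layer}_baseline_AIvsWT.tsv"))
        ftables[layer] = factorial_F(imputed, design, config.signif)
        outputs.append(_write_de(ftables[layer], de_dir / f"{layer}_factorial_F.tsv"))
    for layer in ("glyco", "phospho"):
        for line in ("WT", "AI"):
            sub = design_subset(design, cell_line=line)
            de = pairwise_de(pre[layer]["imputed"], sub, "condition",
                             "treated", "untreated", config.signif)
            serum[(layer, line)] = de
            outputs.append(_write_de(de, de_dir / f"{layer}_serum_{line}.tsv"))
    manifest.record("modstats", outputs)
    logger.info("stage modstats done in %.1fs", time.monotonic() - t0)

    # ---------------- stage 4: glycan summaries ----------------
    t0 = _stage("glycan")
    gly_dir = out_dir / "glycan"
    gly_dir.mkdir(exist_ok=True)
    outputs = []
    flags = class_flags_table(pre["glyco"]["raw_filtered"].feature_ids)
    p = gly_dir / "class_flags.tsv"
    flags.to_csv(p, sep="\t")
    outputs.append(p)
    ratios = class_ratios(pre["glyco"]["raw_filtered"], flags, starved)
    for name, table in ratios.items():
        p = gly_dir / f"class_{name}.tsv"
        table.to_csv(p, sep="\t")
        outputs.append(p)
    flags_all = class_flags_table(baseline["glyco"].index)
    summary = class_logfc_summary(baseline["glyco"], flags_all)
    p = gly_dir / "class_logfc_summary.tsv"
    summary.to_csv(p, sep="\t")
    outputs.append(p)
    for which in ("target_complex", "target_hybrid"):
        splot = target_splot(baseline["glyco"], flags_all, which)
        p = gly_dir / f"splot_{which}.tsv"
        _write_de(splot, p)
        outputs.append(p)
    manifest.record("glycan", outputs)
    logger.info("stage glycan done in %.1fs", time.monotonic() - t0)

    # ---------------- stage 5: integration ----------------
    t0 = _stage("integrate")
    int_dir = out_dir / "integrate"
    int_dir.mkdir(exist_ok=True)
    outputs = []
    for layer in _LAYERS:
        features = select_features(ftables[layer], config.integration)
        if len(features) >= 2:
            block = build_block(pre[layer]["imputed"], features, config.integration)
            outputs += block.write(int_dir / f"block_{layer}")
    catalog = categorize_response(serum[("phospho", "WT")], serum[("phospho", "AI")])
    p = int_dir / "response_catalog_sites.tsv"
    catalog.to_csv(p, sep="\t", index_label="site_id")
    outputs.append(p)
    protein_catalog = collapse_to_proteins(catalog)
    p = int_dir / "response_catalog_proteins.tsv"
    protein_catalog.to_csv(p, sep="\t", index_label="gene")
    outputs.append(p)
    manifest.record("integrate", outputs)
    logger.info("stage integrate done in %.1fs", time.monotonic() - t0)

    # ---------------- stage 6: enrichment ----------------
    t0 = _stage("enrich")
    enr_dir = out_dir / "enrich"
    enr_dir.mkdir(exist_ok=True)
    outputs = []
    phospho_genes = sorted({phospho_gene(s)
                            for s in pre["phospho"]["imputed"].feature_ids})
    if config.gmt_path is not None:
        collection = read_gmt(config.gmt_path)
    else:
        sets = generate_gene_sets(phospho_genes,
                                  seed=stage_seed(config.seed, "gene_sets"))
        collection = GeneSetCollection(sets=sets)
        p = enr_dir / "synthetic_gene_sets.gmt"
        write_gmt(collection, p)
        outputs.append(p)
    ora_results: dict[str, dict[str, pd.DataFrame]] = {"up": {}, "down": {}}
    for line in ("WT", "AI"):
        de = serum[("phospho", line)]
        sig = de[de["significant"]]
        for direction, mask in (("up", sig["logFC"] > 0), ("down", sig["logFC"] < 0)):
            genes = {phospho_gene(s) for s in sig.index[mask]}
            table = ora(genes, collection, phospho_genes, alpha=config.signif.alpha)
            ora_results[direction][line] = table
            p = enr_dir / f"ora_{line}_{direction}.tsv"
            table.to_csv(p, sep="\t")
            outputs.append(p)
    for direction in ("up", "down"):
        display = select_display(ora_results[direction])
        p = enr_dir / f"display_{direction}.tsv"
        display.to_csv(p, sep="\t")
        outputs.append(p)
    manifest.record("enrich", outputs)
    logger.info("stage enrich done in %.1fs", time.monotonic() - t0)

    # ---------------- stage 7: network ----------------
    t0 = _stage("network")
    net_dir = out_dir / "network"
    net_dir.mkdir(exist_ok=True)
    outputs = []
    glyco_sig = baseline["glyco"][baseline["glyco"]["significant"]]
    module_counts = {}
    for line in ("WT", "AI"):
        phospho_sig = serum[("phospho", line)]
        phospho_sig = phospho_sig[phospho_sig["significant"]]
        genes = sorted({glyco_gene(f) for f in glyco_sig.index}
                       | {phospho_gene(s) for s in phospho_sig.index})
        if config.edges_path is not None:
            edges_path = Path(config.edges_path)
        else:
            edges = generate_interactions(genes,
                                          seed=stage_seed(config.seed, f"edges:{line}"))
            edges_path = net_dir / f"synthetic_edges_{line}.tsv"
            edges.to_csv(edges_path, sep="\t", index=False)
            outputs.append(edges_path)
        G = load_edges(edges_path, threshold=config.edge_threshold)
        G = G.subgraph([g for g in genes if g in G]).copy()
        if G.number_of_nodes() == 0:
            logger.warning("no %s network nodes above threshold; skipping", line)
            module_counts[line] = 0
            continue
        G = largest_component(G)
        G = annotate_nodes(G, glyco_sig, phospho_sig)
        modules = mcode(G, config.mcode_params)
        module_counts[line] = len(modules)
        paths = export_network(G, modules, net_dir, prefix=f"{line}")
        outputs += list(paths.values())
    manifest.record("network", outputs)
    logger.info("stage network done in %.1fs", time.monotonic() - t0)

    manifest_path = manifest.write()
    logger.info("run complete in %.1fs; manifest at %s",
                time.monotonic() - t_run, manifest_path)
    result = json.loads(manifest_path.read_text())
    result["module_counts"] = module_counts
    return result
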