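"""Synthetic three-layer multi-omics generator with planted ground truth.

Emulates the statistical structure of a 2x2x3 glycoengineering + serum
stimulation study: two cell lines (WT and the glycoengineered AI line), two
conditions (serum-starved/untreated vs 30-min serum-stimulated/treated),
three biological replicates each.  Three layers are emitted on the raw
(un-logged) intensity scale so the preprocessing stage is exercised:

* ``global``  - protein abundances; a fraction carries cell-line shifts.
* ``glyco``   - intact glycopeptides whose ids embed a glycan composition
  drawn from a fixed catalogue; class-driven AI-vs-WT shifts are planted
  (fucosylated down, sialylated up, branched down, engineered targets up).
* ``phospho`` - phosphosites (``GENE_S123`` ids); a fraction responds to
  serum with amplitude ``serum_amplitude_log2`` in WT, blunted by
  ``ai_blunting_factor`` in AI.

Latent intensities are log2-normal; missingness is MNAR-dominated (logistic
in the standardized latent log2 intensity) with an additional MCAR layer.
Every draw flows from the config seed, so identical configs give identical
outputs.  A ground-truth table (one row per feature) records the planted
log2 fold-changes for parameter-recovery tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import IntensityMatrix, make_design, write_design
from .glycan import classify, parse_glycoform

__all__ = [
    "SimulationConfig",
    "generate_dataset",
    "generate_toy_glycan_table",
    "generate_gene_sets",
    "generate_interactions",
    "write_dataset",
    "GLYCOFORM_CATALOGUE",
]

# ~20 compositions spanning high-mannose, fucosylated, sialylated, branched
# and both engineered target forms.
GLYCOFORM_CATALOGUE = (
    # high-mannose / immature
    "N2H5F0S0G0", "N2H6F0S0G0", "N2H7F0S0G0", "N2H8F0S0G0", "N2H9F0S0G0",
    # neutral complex / hybrid
    "N4H5F0S0G0", "N4H4F0S0G0", "N3H4F0S0G0", "N3H5F0S0G0",
    # fucosylated only
    "N4H5F1S0G0", "N4H4F1S0G0", "N2H3F1S0G0", "N4H5F2S0G0",
    # sialylated only (includes both engineered targets)
    "N4H5F0S2G0", "N3H6F0S1G0", "N4H5F0S1G0",
    # sialylated + fucosylated
    "N4H5F1S1G0", "N4H5F1S2G0",
    # branched (N > 4)
    "N5H6F0S0G0", "N5H6F0S3G0", "N5H6F1S2G0", "N6H7F1S3G0",
    # GalNAc-containing
    "N4H4F0S1G1",
)

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """All knobs of the generator; the seed fully determines the output."""

    n_global: int = 1000
    n_glyco: int = 800
    n_phospho: int = 1500
    n_replicates: int = 3
    baseline_log2_mean: float = 20.0
    baseline_log2_sd: float = 2.0
    noise_log2_sd: float = 0.5
    sample_shift_sd: float = 0.2
    # fraction of features carrying each planted contrast
    effect_fraction: dict = field(default_factory=lambda: {
        "cell_line": 0.1,   # global + phospho baseline AI-vs-WT effects
        "serum": 0.1,       # phospho serum-responsive fraction
        "glyco_class": 1.0,  # fraction of glyco class members carrying the class shift
    })
    glyco_shift_log2: dict = field(default_factory=lambda: {
        "fucosylated": -1.5,
        "sialylated": 1.5,
        "branched": -1.5,
        "target": 2.0,
    })
    global_shift_log2: float = 1.0
    serum_amplitude_log2: float = 1.5
    ai_blunting_factor: float = 0.3
    mnar_strength: float = 1.0
    mcar_rate: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_global", "n_glyco", "n_phospho"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2 (variance estimation)")
        for name in ("baseline_log2_mean", "baseline_log2_sd", "noise_log2_sd",
                     "sample_shift_sd", "global_shift_log2",
                     "serum_amplitude_log2"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        for key, val in self.effect_fraction.items():
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"effect_fraction[{key!r}] must lie in [0,1]")
        if not 0.0 <= self.ai_blunting_factor <= 1.0:
            raise ValueError("ai_blunting_factor must lie in [0,1]")
        if self.mnar_strength < 0:
            raise ValueError("mnar_strength must be >= 0")
        if not 0.0 <= self.mcar_rate <= 1.0:
            raise ValueError("mcar_rate must lie in [0,1]")
        for key, val in self.glyco_shift_log2.items():
            if not np.isfinite(val):
                raise ValueError(f"glyco_shift_log2[{key!r}] must be finite")


# ----------------------------------------------------------------------
# feature id factories
# ----------------------------------------------------------------------

def _gene_symbols(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def _random_peptide(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _glyco_feature_ids(rng: np.random.Generator, n: int) -> tuple[list[str], list[str]]:
    """ids of form GENE|PEPTIDE|N<pos>|composition; returns (ids, compositions)."""
    genes = _gene_symbols("GLYG", max(1, n // 3))
    ids, comps = [], []
    for i in range(n):
        gene = genes[int(rng.integers(len(genes)))]
        pep = _random_peptide(rng, int(rng.integers(8, 16)))
        pos = int(rng.integers(20, 900))
        comp = GLYCOFORM_CATALOGUE[int(rng.integers(len(GLYCOFORM_CATALOGUE)))]
        ids.append(f"{gene}|{pep}|N{pos}|{comp}")
        comps.append(comp)
    return ids, comps


def _phospho_feature_ids(rng: np.random.Generator, n: int) -> list[str]:
    genes = _gene_symbols("PHOG", max(1, n // 4))
    residues = "STY"
    ids = set()
    out = []
    while len(out) < n:
        gene = genes[int(rng.integers(len(genes)))]
        res = residues[int(rng.integers(3))]
        pos = int(rng.integers(2, 2000))
        fid = f"{gene}_{res}{pos}"
        if fid not in ids:
            ids.add(fid)
            out.append(fid)
    return out


# ----------------------------------------------------------------------
# main generator
# ----------------------------------------------------------------------

def generate_dataset(config: SimulationConfig) -> dict:
    """Generate the three raw intensity layers, the design and ground truth.

    Returns a dict with keys ``matrices`` (layer -> IntensityMatrix, raw
    scale), ``design`` (DataFrame) and ``truth`` (DataFrame with the planted
    log2 fold-changes per contrast and affected flags).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    design = make_design(n_replicates=config.n_replicates)
    is_ai = (design["cell_line"] == "AI").to_numpy()
    is_treated = (design["condition"] == "treated").to_numpy()
    n_samples = len(design)

    sample_offsets = rng.normal(0.0, config.sample_shift_sd, size=n_samples)

    matrices: dict[str, IntensityMatrix] = {}
    truth_rows: list[dict] = []

    for layer in ("global", "glyco", "phospho"):
        if layer == "global":
            n_feat = config.n_global
            ids = _gene_symbols("GENE", n_feat)
            comps = None
        elif layer == "glyco":
            n_feat = config.n_glyco
            ids, comps = _glyco_feature_ids(rng, n_feat)
        else:
            n_feat = config.n_phospho
            ids = _phospho_feature_ids(rng, n_feat)
            comps = None

        base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n_feat)
        beta_cl = np.zeros(n_feat)       # AI - WT shift
        beta_serum_wt = np.zeros(n_feat)  # treated - untreated in WT
        beta_serum_ai = np.zeros(n_feat)

        if layer == "glyco":
            gate = rng.random(n_feat) < config.effect_fraction["glyco_class"]
            shifts = config.glyco_shift_log2
            for i, comp_text in enumerate(comps):
                if not gate[i]:
                    continue
                flags = classify(parse_glycoform(comp_text))
                if flags["target_any"]:
                    beta_cl[i] = shifts["target"]
                    continue
                shift = 0.0
                if flags["fucosylated"]:
                    shift += shifts["fucosylated"]
                if flags["sialylated"]:
                    shift += shifts["sialylated"]
                if flags["branched"]:
                    shift += shifts["branched"]
                beta_cl[i] = shift
        else:
            affected = rng.random(n_feat) < config.effect_fraction["cell_line"]
            signs = rng.choice([-1.0, 1.0], size=n_feat)
            beta_cl = np.where(affected, signs * config.global_shift_log2, 0.0)

        if layer == "phospho":
            responsive = rng.random(n_feat) < config.effect_fraction["serum"]
            beta_serum_wt = np.where(responsive, config.serum_amplitude_log2, 0.0)
            beta_serum_ai = beta_serum_wt * config.ai_blunting_factor
        else:
            responsive = np.zeros(n_feat, dtype=bool)

        serum_beta = np.where(is_ai[None, :], beta_serum_ai[:, None],
                              beta_serum_wt[:, None])
        latent = (base[:, None]
                  + sample_offsets[None, :]
                  + beta_cl[:, None] * is_ai[None, :]
                  + serum_beta * is_treated[None, :]
                  + rng.normal(0.0, config.noise_log2_sd, size=(n_feat, n_samples)))

        # MNAR: logistic missingness in standardized latent log2 intensity.
        missing = np.zeros_like(latent, dtype=bool)
        if config.mnar_strength > 0:
            z = (latent - latent.mean()) / latent.std()
            p_mnar = 1.0 / (1.0 + np.exp(config.mnar_strength * z + 2.0))
            missing |= rng.random(latent.shape) < p_mnar
        if config.mcar_rate > 0:
            missing |= rng.random(latent.shape) < config.mcar_rate

        raw = np.exp2(latent)
        raw[missing] = np.nan
        values = pd.DataFrame(raw, index=pd.Index(ids, name="feature_id"),
                              columns=design["sample_id"].to_list())
        matrices[layer] = IntensityMatrix.from_values(values, scale="raw", layer=layer)

        for i, fid in enumerate(ids):
            truth_rows.append({
                "feature_id": fid,
                "layer": layer,
                "true_log2fc_cell_line": beta_cl[i],
                "true_log2fc_serum_wt": beta_serum_wt[i],
                "true_log2fc_serum_ai": beta_serum_ai[i],
                "affected_cell_line": bool(beta_cl[i] != 0.0),
                "affected_serum": bool(responsive[i]),
            })

    truth = pd.DataFrame(truth_rows)
    return {"matrices": matrices, "design": design, "truth": truth}


# ----------------------------------------------------------------------
# auxiliary generators
# ----------------------------------------------------------------------

def generate_toy_glycan_table() -> pd.DataFrame:
    """Deterministic <=10-row glycopeptide table covering every class predicate."""
    rows = [
        # (gene, peptide, site, composition, intensity)
        ("GLYG0001", "LNCSVNATK", "N34", "N4H5F0S2G0", 900.0),   # target complex
        ("GLYG0002", "TVNHSLLR", "N120", "N3H6F0S1G0", 700.0),   # target hybrid
        ("GLYG0003", "AENGTSWK", "N77", "N4H5F0S1G0", 500.0),    # sialylated only
        ("GLYG0004", "VLNWSDFK", "N210", "N4H5F1S0G0", 400.0),   # fucosylated only
        ("GLYG0005", "GINETMIR", "N58", "N4H5F1S2G0", 300.0),    # both
        ("GLYG0006", "SDNFTQLK", "N91", "N2H8F0S0G0", 800.0),    # high-mannose, neither
        ("GLYG0007", "QPNLTGVR", "N150", "N5H6F0S0G0", 250.0),   # branched neutral
        ("GLYG0008", "FRNVSEPK", "N42", "N6H7F1S3G0", 150.0),    # branched + both
    ]
    records = []
    for gene, pep, site, comp_text, intensity in rows:
        comp = parse_glycoform(comp_text)
        rec = {
            "feature_id": f"{gene}|{pep}|{site}|{comp_text}",
            "composition": comp_text,
            "intensity": intensity,
        }
        rec.update(classify(comp))
        records.append(rec)
    return pd.DataFrame(records).set_index("feature_id")


def generate_gene_sets(genes: list[str], seed: int, n_sets: int = 30,
                       min_size: int = 10, max_size: int = 40,
                       sources: tuple[str, ...] = ("KEGGSYN", "REACTSYN"),
                       ) -> dict[str, list[str]]:
    """Synthetic GMT-style gene-set collection over the supplied gene universe."""
    rng = np.random.default_rng(seed)
    genes = sorted(set(genes))
    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        source = sources[i % len(sources)]
        size = int(rng.integers(min_size, max_size + 1))
        size = min(size, len(genes))
        members = sorted(rng.choice(genes, size=size, replace=False))
        sets[f"{source}_PATHWAY_{i + 1:02d}"] = [str(m) for m in members]
    return sets


def generate_interactions(genes: list[str], seed: int, n_modules: int = 5,
                          module_size: int = 8, p_within: float = 0.9,
                          p_background: float = 0.004,
                          score_scale: str = "unit") -> pd.DataFrame:
    """STRING-export-style edge list with planted dense modules.

    ``score_scale``: ``unit`` emits combined scores in [0,1]; ``string``
    emits the 0-1000 integer dialect.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(set(genes))
    edges: dict[tuple[str, str], float] = {}

    def add_edge(a: str, b: str, lo: float, hi: float) -> None:
        if a == b:
            return
        key = (a, b) if a < b else (b, a)
        score = float(rng.uniform(lo, hi))
        edges[key] = max(edges.get(key, 0.0), score)

    # planted dense modules: high-confidence near-cliques
    pool = list(genes)
    rng.shuffle(pool)
    idx = 0
    for _ in range(n_modules):
        members = pool[idx:idx + module_size]
        idx += module_size
        if len(members) < 3:
            break
        for a, b in itertools.combinations(members, 2):
            if rng.random() < p_within:
                add_edge(a, b, 0.7, 0.999)
    # sparse background
    n_bg = int(p_background * len(genes) * (len(genes) - 1) / 2)
    for _ in range(n_bg):
        a, b = rng.choice(genes, size=2, replace=False)
        add_edge(str(a), str(b), 0.15, 0.95)

    rows = [{"geneA": a, "geneB": b, "combined_score": s}
            for (a, b), s in sorted(edges.items())]
    df = pd.DataFrame(rows, columns=["geneA", "geneB", "combined_score"])
    if score_scale == "string":
        df["combined_score"] = (df["combined_score"] * 1000).round().astype(int)
    elif score_scale != "unit":
        raise ValueError("score_scale must be 'unit' or 'string'")
    return df


# ----------------------------------------------------------------------
# on-disk dataset
# ----------------------------------------------------------------------

def write_dataset(dataset: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write matrices/design/ground-truth TSVs; returns the emitted paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for layer, matrix in dataset["matrices"].items():
        p = out_dir / f"{layer}_raw.tsv"
        matrix.to_tsv(p)
        paths[f"{layer}_raw"] = p
    p = out_dir / "design.tsv"
    write_design(dataset["design"], p)
    paths["design"] = p
    p = out_dir / "ground_truth.tsv"
    dataset["truth"].to_csv(p, sep="\t", index=False)
    paths["ground_truth"] = p
    return paths
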