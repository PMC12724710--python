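"""Glycoform composition parsing, glycan-class predicates and class summaries.

Intact glycopeptides are quantified with their attached glycan, written in
the monosaccharide-count shorthand ``N#H#F#S#G#``: GlcNAc (N), hexose
(mannose/galactose, H), fucose (F), Neu5Ac sialic acid (S) and GalNAc (G).
Class membership is purely compositional:

* sialylated: S > 0
* fucosylated: F > 0
* branched: N > 4 (tri-/tetra-antennary and higher)
* starred (mutually exclusive) variants: sialylated* = S>0 and F=0,
  fucosylated* = F>0 and S=0
* engineered targets: the bi-antennary complex glycan N4H5F0S2G0 and the
  hybrid glycan N3H6F0S1G0 (non-fucosylated, sialylated, unbranched).

Glycopeptide feature ids follow the convention
``GENE|PEPTIDE|SITE|N#H#F#S#G#``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GlycoformComposition",
    "parse_glycoform",
    "format_glycoform",
    "classify",
    "class_flags_table",
    "parse_glyco_feature_id",
    "glyco_gene",
    "class_ratios",
    "class_logfc_summary",
    "target_splot",
    "TARGET_COMPLEX",
    "TARGET_HYBRID",
    "CLASS_COLUMNS",
]

_COMP_RE = re.compile(r"^N(\d+)H(\d+)F(\d+)S(\d+)G(\d+)$")


@dataclass(frozen=True, order=True)
class GlycoformComposition:
    """Monosaccharide counts of an N-glycan in N/H/F/S/G shorthand."""

    n: int
    h: int
    f: int
    s: int
    g: int

    def __post_init__(self) -> None:
        for name in ("n", "h", "f", "s", "g"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"monosaccharide count {name!r} must be a non-negative "
                                 f"integer, got {v!r}")

    def __str__(self) -> str:
        return f"N{self.n}H{self.h}F{self.f}S{self.s}G{self.g}"


TARGET_COMPLEX = GlycoformComposition(4, 5, 0, 2, 0)
TARGET_HYBRID = GlycoformComposition(3, 6, 0, 1, 0)

CLASS_COLUMNS = (
    "sialylated", "fucosylated", "branched",
    "sialylated_excl", "fucosylated_excl",
    "target_complex", "target_hybrid", "target_any",
)


def parse_glycoform(text: str) -> GlycoformComposition:
    """Parse ``N4H5F0S2G0``-style shorthand; counts may be multi-digit."""
    m = _COMP_RE.match(text.strip())
    if m is None:
        raise ValueError(f"malformed glycoform shorthand: {text!r} "
                         "(expected N<int>H<int>F<int>S<int>G<int>)")
    n, h, f, s, g = (int(x) for x in m.groups())
    return GlycoformComposition(n, h, f, s, g)


def format_glycoform(comp: GlycoformComposition) -> str:
    return str(comp)


def classify(comp: GlycoformComposition) -> dict[str, bool]:
    """Evaluate every glycan-class predicate on one composition."""
    sial = comp.s > 0
    fuc = comp.f > 0
    flags = {
        "sialylated": sial,
        "fucosylated": fuc,
        "branched": comp.n > 4,
        "sialylated_excl": sial and not fuc,
        "fucosylated_excl": fuc and not sial,
        "target_complex": comp == TARGET_COMPLEX,
        "target_hybrid": comp == TARGET_HYBRID,
    }
    flags["target_any"] = flags["target_complex"] or flags["target_hybrid"]
    return flags


def parse_glyco_feature_id(feature_id: str) -> tuple[str, str, str, GlycoformComposition]:
    """Split ``GENE|PEPTIDE|SITE|N#H#F#S#G#`` into its four parts."""
    parts = feature_id.split("|")
    if len(parts) != 4:
        raise ValueError(f"glycopeptide id {feature_id!r} does not match "
                         "GENE|PEPTIDE|SITE|composition")
    gene, peptide, site, comp_text = parts
    return gene, peptide, site, parse_glycoform(comp_text)


def glyco_gene(feature_id: str) -> str:
    return feature_id.split("|", 1)[0]


def class_flags_table(feature_ids) -> pd.DataFrame:
    """Boolean class membership per glycopeptide feature id."""
    rows = []
    for fid in feature_ids:
        _, _, _, comp = parse_glyco_feature_id(fid)
        flags = classify(comp)
        flags["composition"] = str(comp)
        rows.append(flags)
    out = pd.DataFrame(rows, index=pd.Index(feature_ids, name="feature_id"))
    return out[["composition", *CLASS_COLUMNS]]


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def class_ratios(raw_matrix, flags: pd.DataFrame, design: pd.DataFrame,
                 classes: tuple[str, ...] = ("sialylated", "fucosylated", "branched"),
                 ) -> dict[str, pd.DataFrame]:
    """Per-sample class abundance ratios on the raw scale, with WT-vs-AI Welch t.

    Ratio = (total intensity of class members) / (total intensity of all
    glycopeptides) per sample; undetected cells contribute zero.  The design
    passed in determines which samples are compared (pass the starved subset
    to reproduce the baseline comparison).
    """
    if raw_matrix.scale != "raw":
        raise ValueError("class ratios are defined on raw-scale intensities")
    samples = [s for s in design["sample_id"] if s in raw_matrix.sample_ids]
    vals = raw_matrix.values[samples].fillna(0.0)
    totals = vals.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total glycopeptide intensity: {bad}")
    flags = flags.loc[raw_matrix.feature_ids]

    ratio_rows = {}
    for cls in classes:
        member = flags[cls].to_numpy(bool)
        ratio_rows[cls] = vals.loc[member].sum(axis=0) / totals
    ratios = pd.DataFrame(ratio_rows).T  # classes x samples
    ratios.index.name = "glycan_class"

    line_of = design.set_index("sample_id")["cell_line"]
    summary_rows = []
    for cls in classes:
        r = ratios.loc[cls]
        wt = r[[s for s in samples if line_of[s] == "WT"]].to_numpy(float)
        ai = r[[s for s in samples if line_of[s] == "AI"]].to_numpy(float)
        t, p = stats.ttest_ind(ai, wt, equal_var=False)
        summary_rows.append({
            "glycan_class": cls,
            "wt_mean": wt.mean(), "wt_sem": stats.sem(wt),
            "ai_mean": ai.mean(), "ai_sem": stats.sem(ai),
            "t": float(t), "p": float(p), "stars": _stars(float(p)),
        })
    summary = pd.DataFrame(summary_rows).set_index("glycan_class")
    return {"ratios": ratios, "summary": summary}


def class_logfc_summary(de: pd.DataFrame, flags: pd.DataFrame,
                        classes: tuple[str, ...] = ("sialylated_excl",
                                                    "fucosylated_excl",
                                                    "target_any"),
                        ) -> pd.DataFrame:
    """log2FC distribution summaries per glycan class among significant features.

    ``de`` must carry ``logFC`` and ``significant`` columns indexed by
    feature id.  Empty classes report NaN medians.
    """
    sig = de[de["significant"]]
    flags = flags.reindex(sig.index)
    rows = []
    for cls in classes:
        fcs = sig.loc[flags[cls].fillna(False).to_numpy(bool), "logFC"]
        rows.append({
            "glycan_class": cls,
            "n": int(len(fcs)),
            "median_logFC": float(fcs.median()) if len(fcs) else np.nan,
            "mean_logFC": float(fcs.mean()) if len(fcs) else np.nan,
            "q25": float(fcs.quantile(0.25)) if len(fcs) else np.nan,
            "q75": float(fcs.quantile(0.75)) if len(fcs) else np.nan,
        })
    return pd.DataFrame(rows).set_index("glycan_class")


def target_splot(de: pd.DataFrame, flags: pd.DataFrame,
                 which: str = "target_complex") -> pd.DataFrame:
    """Ranked (s-plot style) table of features carrying one target glycoform."""
    if which not in ("target_complex", "target_hybrid"):
        raise ValueError("which must be 'target_complex' or 'target_hybrid'")
    flags = flags.reindex(de.index)
    sub = de.loc[flags[which].fillna(False).to_numpy(bool)].copy()
    labels = []
    for fid in sub.index:
        gene, peptide, site, _ = parse_glyco_feature_id(fid)
        labels.append(f"{peptide} ({gene} {site})")
    sub["label"] = labels
    # stable two-key sort: logFC ascending, feature id breaking ties
    sub = sub.sort_index(kind="mergesort").sort_values("logFC", kind="mergesort")
    cols = ["label", "logFC", "fdr", "significant"]
    return sub[[c for c in cols if c in sub.columns]]
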