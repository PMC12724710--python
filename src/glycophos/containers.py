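"""Core data containers shared by every pipeline stage.

The central object is :class:`IntensityMatrix`: a features x samples table of
MS abundances with an explicit detection mask, a scale tag (``raw`` or
``log2``) and a layer tag (``global``, ``glyco`` or ``phospho``).  Matrices
round-trip losslessly through TSV (first column ``feature_id``, remaining
columns sample ids; the detection mask travels as a parallel TSV).

A sample design is an ordinary :class:`pandas.DataFrame` with columns
``sample_id``, ``cell_line`` (WT/AI), ``condition`` (untreated/treated) and
``replicate``; :func:`validate_design` enforces the invariants every
downstream model relies on (unique ids, >=2 replicates per design cell).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

LAYERS = ("global", "glyco", "phospho")
SCALES = ("raw", "log2")
CELL_LINES = ("WT", "AI")
CONDITIONS = ("untreated", "treated")

DESIGN_COLUMNS = ["sample_id", "cell_line", "condition", "replicate"]


@dataclass
class IntensityMatrix:
    """Features x samples abundance matrix with a congruent detection mask.

    ``values`` holds floats with NaN at undetected cells until imputation
    fills them; ``detected`` records which cells were actually observed and
    is never modified by imputation (it is the provenance mask).
    """

    values: pd.DataFrame
    detected: pd.DataFrame
    scale: str
    layer: str
    is_imputed: bool = False

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}, got {self.scale!r}")
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.values.shape != self.detected.shape:
            raise ValueError("values and detected mask differ in shape")
        if not self.values.index.equals(self.detected.index) or not self.values.columns.equals(
            self.detected.columns
        ):
            raise ValueError("values and detected mask differ in axes")
        if not self.detected.dtypes.map(lambda d: d == bool).all():
            self.detected = self.detected.astype(bool)

    # ------------------------------------------------------------------
    @classmethod
    def from_values(cls, values: pd.DataFrame, scale: str, layer: str) -> "IntensityMatrix":
        """Build a matrix from a plain table; NaN/inf cells become undetected."""
        vals = values.astype(float)
        detected = np.isfinite(vals.to_numpy())
        vals = vals.where(pd.DataFrame(detected, index=vals.index, columns=vals.columns))
        return cls(values=vals, detected=pd.DataFrame(detected, index=vals.index,
                                                      columns=vals.columns),
                   scale=scale, layer=layer)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def detection_rate(self) -> pd.Series:
        """Fraction of samples in which each feature was observed."""
        return self.detected.mean(axis=1)

    def copy(self) -> "IntensityMatrix":
        return replace(self, values=self.values.copy(), detected=self.detected.copy())

    # ------------------------------------------------------------------
    def to_tsv(self, path: str | Path, mask_path: str | Path | None = None) -> None:
        out = self.values.copy()
        out.index.name = "feature_id"
        out.to_csv(path, sep="\t")
        if mask_path is not None:
            mask = self.detected.astype(int)
            mask.index.name = "feature_id"
            mask.to_csv(mask_path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path, scale: str, layer: str,
                 mask_path: str | Path | None = None) -> "IntensityMatrix":
        vals = pd.read_csv(path, sep="\t", index_col="feature_id").astype(float)
        if mask_path is not None:
            detected = pd.read_csv(mask_path, sep="\t", index_col="feature_id").astype(bool)
            detected = detected.loc[vals.index, vals.columns]
            return cls(values=vals.where(detected), detected=detected, scale=scale, layer=layer)
        return cls.from_values(vals, scale=scale, layer=layer)


# ----------------------------------------------------------------------
# Sample design helpers
# ----------------------------------------------------------------------

def make_design(n_replicates: int = 3,
                cell_lines: tuple[str, ...] = CELL_LINES,
                conditions: tuple[str, ...] = CONDITIONS) -> pd.DataFrame:
    """Full-factorial design table (default 2 lines x 2 conditions x 3 reps)."""
    rows = []
    for cl in cell_lines:
        for cond in conditions:
            for rep in range(1, n_replicates + 1):
                rows.append({
                    "sample_id": f"{cl}_{cond}_r{rep}",
                    "cell_line": cl,
                    "condition": cond,
                    "replicate": rep,
                })
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)
    validate_design(design)
    return design


def validate_design(design: pd.DataFrame) -> None:
    missing = [c for c in DESIGN_COLUMNS if c not in design.columns]
    if missing:
        raise ValueError(f"design table missing columns: {missing}")
    if design["sample_id"].duplicated().any():
        raise ValueError("sample_ids must be unique")
    bad_cl = set(design["cell_line"]) - set(CELL_LINES)
    if bad_cl:
        raise ValueError(f"unknown cell_line values: {sorted(bad_cl)}")
    bad_cond = set(design["condition"]) - set(CONDITIONS)
    if bad_cond:
        raise ValueError(f"unknown condition values: {sorted(bad_cond)}")
    if (design["replicate"] < 1).any():
        raise ValueError("replicate numbers must be positive")
    counts = design.groupby(["cell_line", "condition"]).size()
    if (counts < 2).any():
        raise ValueError("every (cell_line, condition) cell needs >=2 replicates")


def replicate_groups(design: pd.DataFrame) -> dict[tuple[str, str], list[str]]:
    """Map (cell_line, condition) -> ordered sample ids."""
    groups: dict[tuple[str, str], list[str]] = {}
    for (cl, cond), sub in design.groupby(["cell_line", "condition"], sort=True):
        groups[(cl, cond)] = list(sub["sample_id"])
    return groups


def design_subset(design: pd.DataFrame, cell_line: str | None = None,
                  condition: str | None = None) -> pd.DataFrame:
    sub = design
    if cell_line is not None:
        sub = sub[sub["cell_line"] == cell_line]
    if condition is not None:
        sub = sub[sub["condition"] == condition]
    return sub.reset_index(drop=True)


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    validate_design(design)
    return design


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)
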