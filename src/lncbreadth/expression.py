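"""FPKM matrices, background-based detection thresholds, expression width.

The detection threshold separates genuinely transcribed features from the
near-zero FPKM noise observed over untranscribed genomic regions. A candidate
threshold t incurs FP(t) = #{background values >= t} false positives and
FN(t) = #{transcribed values < t} false negatives; the chosen threshold
minimizes FP + FN over the candidate grid, balancing the two error kinds.
Thresholds are estimated separately per biotype because lncRNAs are much more
lowly expressed than protein-coding genes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Features x tissues FPKM table.

    ``values``: DataFrame indexed by feature id with tissue columns.
    ``level``: 'transcript' or 'gene'.
    """

    values: pd.DataFrame
    level: str = "transcript"

    def __post_init__(self) -> None:
        if self.level not in ("transcript", "gene"):
            raise ValueError(f"bad level {self.level!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative FPKM values")
        if self.values.index.duplicated().any():
            raise ValueError("duplicated feature ids")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicated tissue ids")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def read_tsv(cls, path: str | Path, level: str = "transcript") -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0), level=level)

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class DetectionThreshold:
    biotype: str
    threshold: float
    fp_count: int
    fn_count: int
    grid: str

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def read_sample_map(path: str | Path) -> pd.Series:
    """TSV with columns (sample, tissue) -> Series sample -> tissue."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index(df.columns[0])[df.columns[1]]


def aggregate_to_tissues(
    sample_matrix: pd.DataFrame, sample_to_tissue: pd.Series | dict, level: str = "transcript"
) -> ExpressionMatrix:
    """Collapse sample columns to tissues, taking the per-tissue maximum.

    For tissues with multiple samples the highest FPKM among the tissue's
    samples represents the tissue.
    """
    mapping = pd.Series(sample_to_tissue)
    unmapped = [s for s in sample_matrix.columns if s not in mapping.index]
    if unmapped:
        raise KeyError(f"samples missing from the tissue map: {unmapped}")
    grouped = sample_matrix.T.groupby(mapping.reindex(sample_matrix.columns)).max().T
    grouped = grouped.sort_index(axis=1)
    return ExpressionMatrix(grouped, level=level)


def estimate_detection_threshold(
    transcribed_values,
    untranscribed_values,
    biotype: str = "lncRNA",
) -> DetectionThreshold:
    """Threshold balancing false positives against false negatives.

    Candidates are the sorted unique positive values pooled from both samples;
    the smallest candidate minimizing FP + FN wins (ties break toward the more
    sensitive, smaller threshold).
    """
    sig = np.sort(np.asarray(transcribed_values, dtype=float))
    bg = np.sort(np.asarray(untranscribed_values, dtype=float))
    if sig.size == 0 or bg.size == 0:
        raise ValueError("both transcribed and untranscribed samples must be non-empty")

    if not (bg > 0).any():
        warnings.warn(
            "all-zero background; falling back to the smallest positive transcribed value",
            stacklevel=2,
        )
        positive = sig[sig > 0]
        if positive.size == 0:
            raise ValueError("no positive transcribed values to fall back on")
        t = float(positive[0])
        return DetectionThreshold(biotype, t, 0, int((sig < t).sum()), "fallback: min positive signal")

    candidates = np.unique(np.concatenate([sig, bg]))
    candidates = candidates[candidates > 0]
    # FP(t) = #{bg >= t}; FN(t) = #{sig < t}
    fp = bg.size - np.searchsorted(bg, candidates, side="left")
    fn = np.searchsorted(sig, candidates, side="left")
    cost = fp + fn
    best = int(np.argmin(cost))  # argmin returns the first (smallest) minimizer
    return DetectionThreshold(
        biotype=biotype,
        threshold=float(candidates[best]),
        fp_count=int(fp[best]),
        fn_count=int(fn[best]),
        grid=f"{candidates.size} unique pooled positive values",
    )


def expression_width(feature_row, threshold: float) -> int:
    """Number of tissues where FPKM >= threshold (inclusive)."""
    return int((np.asarray(feature_row, dtype=float) >= threshold).sum())
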