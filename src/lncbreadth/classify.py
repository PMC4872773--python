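"""UE / TS / other classification of transcripts and genes.

A transcript is ubiquitously expressed (UE) when it exceeds its biotype's
detection threshold in every tissue and the coefficient of variation of its
FPKM across tissues is below ``cv_max`` (default 1). It is tissue-specific
(TS) when it is expressed in exactly one tissue and its Jensen-Shannon
specificity score (Cabili-style) exceeds ``ts_min`` (default 0.4). A gene
inherits a UE/TS label as soon as one of its transcripts qualifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, expression_width


@dataclass(frozen=True)
class SpecificityScore:
    score: float
    argmax_tissue: str


@dataclass
class ClassificationResult:
    feature_id: str
    level: str
    label: str  # UE | TS | other
    cv: float
    specificity: SpecificityScore | None
    expression_width: int
    ts_tissue: str | None = None
    conflict: bool = False


def coefficient_of_variation(values) -> float:
    """Sample standard deviation (n-1) over the mean; infinity when mean <= 0."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean <= 0:
        return math.inf
    return float(v.std(ddof=1) / mean)


def _entropy_term(x: np.ndarray) -> np.ndarray:
    """-x log2 x with the 0 log 0 = 0 convention."""
    out = np.zeros_like(x)
    pos = x > 0
    out[pos] = -x[pos] * np.log2(x[pos])
    return out


def js_specificity(profile, tissue_ids: Sequence[str] | None = None) -> SpecificityScore:
    """Jensen-Shannon tissue-specificity score of an expression profile.

    The profile is normalized to a probability vector p. Against the point
    distribution e_t concentrated on tissue t,
    ``JSD(p, e_t) = H((p + e_t)/2) - (H(p) + H(e_t))/2`` with base-2 entropy;
    the per-tissue score is ``1 - sqrt(JSD)`` and the maximum over tissues is
    returned together with its tissue. The score is scale-invariant and equals
    1 exactly for a single-tissue point profile.
    """
    v = np.asarray(profile, dtype=float)
    if (v < 0).any():
        raise ValueError("negative expression values")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero profile has no specificity score")
    p = v / total

    half = _entropy_term(p / 2.0)
    s = half.sum()
    h_p = _entropy_term(p).sum()
    # H((p+e_t)/2) = sum_{i != t} h(p_i/2) + h((p_t+1)/2); H(e_t) = 0
    h_mix = s - half + _entropy_term((p + 1.0) / 2.0)
    jsd = np.maximum(h_mix - h_p / 2.0, 0.0)
    scores = 1.0 - np.sqrt(jsd)
    best = int(np.argmax(scores))
    name = tissue_ids[best] if tissue_ids is not None else str(best)
    return SpecificityScore(float(scores[best]), name)


def classify_transcript(
    expr_row,
    threshold: float,
    tissue_ids: Sequence[str] | None = None,
    cv_max: float = 1.0,
    ts_min: float = 0.4,
    feature_id: str = "",
    level: str = "transcript",
) -> ClassificationResult:
    v = np.asarray(expr_row, dtype=float)
    if tissue_ids is None:
        tissue_ids = [str(i) for i in range(v.size)]
    width = expression_width(v, threshold)
    cv = coefficient_of_variation(v)
    spec = js_specificity(v, tissue_ids) if v.sum() > 0 else None

    label, ts_tissue = "other", None
    if width == v.size and cv < cv_max:
        label = "UE"
    elif width == 1 and spec is not None and spec.score > ts_min:
        label = "TS"
        ts_tissue = tissue_ids[int(np.argmax(v >= threshold))]
    return ClassificationResult(feature_id, level, label, cv, spec, width, ts_tissue)


def classify_gene(transcript_results: Sequence[ClassificationResult], gene_id: str) -> ClassificationResult:
    """Gene label from its transcripts: UE/TS if any transcript qualifies.

    When both a UE and a TS transcript occur (possible under the per-transcript
    rules), the gene is labeled UE with a conflict flag: ubiquitous
    transcription of any isoform contradicts whole-gene tissue restriction.
    """
    if not transcript_results:
        raise ValueError(f"gene {gene_id} has no transcript results")
    ue = [r for r in transcript_results if r.label == "UE"]
    ts = [r for r in transcript_results if r.label == "TS"]
    if ue:
        rep = min(ue, key=lambda r: r.cv)
        label, conflict = "UE", bool(ts)
    elif ts:
        rep = max(ts, key=lambda r: r.specificity.score)
        label, conflict = "TS", False
    else:
        rep = max(transcript_results, key=lambda r: r.expression_width)
        label, conflict = "other", False
    return ClassificationResult(
        gene_id, "gene", label, rep.cv, rep.specificity, rep.expression_width,
        rep.ts_tissue if label == "TS" else None, conflict,
    )


def classify_matrix(
    matrix: ExpressionMatrix,
    thresholds: Mapping[str, float],
    feature_biotype: Mapping[str, str],
    feature_gene: Mapping[str, str] | None = None,
    cv_max: float = 1.0,
    ts_min: float = 0.4,
) -> tuple[list[ClassificationResult], list[ClassificationResult]]:
    """Classify every transcript row, then roll results up to genes.

    ``thresholds`` maps biotype -> detection threshold; ``feature_biotype``
    maps feature id -> biotype; ``feature_gene`` maps transcript -> gene id
    (omit when the matrix is already gene-level).
    """
    tissue_ids = matrix.tissue_ids
    tx_results = []
    for fid, row in matrix.values.iterrows():
        biotype = feature_biotype.get(fid)
        if biotype is None or biotype not in thresholds:
            raise KeyError(f"no detection threshold for feature {fid!r} (biotype {biotype!r})")
        tx_results.append(
            classify_transcript(
                row.to_numpy(), thresholds[biotype], tissue_ids,
                cv_max=cv_max, ts_min=ts_min, feature_id=fid, level=matrix.level,
            )
        )
    gene_results: list[ClassificationResult] = []
    if feature_gene is not None:
        by_gene: dict[str, list[ClassificationResult]] = {}
        for r in tx_results:
            by_gene.setdefault(feature_gene[r.feature_id], []).append(r)
        gene_results = [classify_gene(rs, gid) for gid, rs in by_gene.items()]
    return tx_results, gene_results


def results_to_frame(results: Iterable[ClassificationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "feature_id": r.feature_id,
                "level": r.level,
                "label": r.label,
                "cv": r.cv,
                "specificity": r.specificity.score if r.specificity else np.nan,
                "width": r.expression_width,
                "ts_tissue": r.ts_tissue or "",
                "conflict_flag": int(r.conflict),
            }
        )
    return pd.DataFrame(rows)


def write_results_tsv(results: Iterable[ClassificationResult], path: str | Path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False, float_format="%.6g")
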