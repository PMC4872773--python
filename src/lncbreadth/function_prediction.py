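"""Guilt-by-association function prediction for UE and TS lncRNAs.

UE lncRNAs are functionally annotated from the protein-coding genes they
co-localize and co-express with: neighbors within distance windows, Pearson
co-expression, a pseudo-neighbor randomization test, and hypergeometric GO
enrichment with Benjamini-Hochberg correction. TS lncRNAs, whose neighbors
are rarely tissue-restricted, are instead grouped with TS protein-coding
genes of the same tissue by hierarchical clustering of active histone-mark
promoter profiles; each lncRNA inherits the GO terms enriched among the
protein-coding members of its cluster.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .annotation import GeneModel
from .intervals import GenomicInterval, IntervalIndex
from .stats import bh_adjust, hypergeom_upper_tail

log = logging.getLogger(__name__)

DEFAULT_WINDOWS = (5_000, 10_000, 25_000, 50_000, 100_000)
ACTIVE_MARKS = ("H3K4me1", "H3K27ac", "H3K4me2", "H3K4me3", "H3K9ac", "H3K36me3")


@dataclass
class EnrichmentResult:
    term_id: str
    overlap_count: int
    set_size: int
    term_size: int
    universe_size: int
    p_raw: float
    p_adjusted: float
    contributing_genes: tuple[str, ...]
    term_name: str = ""


@dataclass
class NeighborAssignment:
    lncRNA_id: str
    neighbors: dict[int, list[str]]  # window -> pc gene ids
    nearest_gene_id: str | None
    nearest_distance: float
    correlations: dict[str, float] = field(default_factory=dict)


@dataclass
class CoModificationCluster:
    tissue: str
    cluster_id: int
    member_ids: tuple[str, ...]
    centroid: np.ndarray
    enriched_terms: list[EnrichmentResult]


def neighbors_within(
    lnc_loci: Mapping[str, GenomicInterval],
    pc_loci: Mapping[str, GenomicInterval],
    windows: Sequence[int] = DEFAULT_WINDOWS,
    same_tissue: Mapping[str, str] | None = None,
    lnc_tissue: Mapping[str, str] | None = None,
) -> list[NeighborAssignment]:
    """Protein-coding neighbors of each lncRNA at every distance window.

    Distances are locus-to-locus gaps. With ``same_tissue`` (pc gene -> TS
    tissue) and ``lnc_tissue`` (lncRNA -> TS tissue), neighbors are restricted
    to pc genes tissue-specific in the lncRNA's own tissue.
    """
    windows = sorted(windows)
    index = IntervalIndex((iv, pid) for pid, iv in pc_loci.items())
    out = []
    for lid, locus in lnc_loci.items():
        hits = index.within(locus, windows[-1])
        if same_tissue is not None:
            want = None if lnc_tissue is None else lnc_tissue.get(lid)
            hits = [h for h in hits if same_tissue.get(h[1]) == want and want is not None]
        per_window = {w: sorted(pid for _iv, pid, d in hits if d <= w) for w in windows}
        if hits:
            _iv, nearest, ndist = min(hits, key=lambda h: (h[2], h[1]))
        else:
            nearest, ndist = None, float("inf")
        out.append(NeighborAssignment(lid, per_window, nearest, ndist))
    return out


def neighbor_fraction(assignments: Sequence[NeighborAssignment], window: int) -> float:
    """Fraction of lncRNAs with at least one neighbor at the given window."""
    if not assignments:
        raise ValueError("no neighbor assignments")
    return float(np.mean([bool(a.neighbors.get(window)) for a in assignments]))


def _log_rows(rows: np.ndarray, log_transform: bool) -> np.ndarray:
    return np.log2(rows + 1.0) if log_transform else rows.astype(float)


def coexpression(
    lnc_row,
    gene_rows: pd.DataFrame,
    method: str = "pearson",
    log_transform: bool = True,
) -> pd.Series:
    """Correlation of one lncRNA profile with each gene row over matched tissues.

    Default Pearson on log2(FPKM+1); Spearman available. Zero-variance vectors
    yield NaN.
    """
    x = _log_rows(np.asarray(lnc_row, dtype=float), log_transform)
    mat = _log_rows(gene_rows.to_numpy(dtype=float), log_transform)
    if method == "spearman":
        x = pd.Series(x).rank().to_numpy()
        mat = pd.DataFrame(mat).rank(axis=1).to_numpy()
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    xc = x - x.mean()
    mc = mat - mat.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum()) * np.sqrt((mc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, mc @ xc / denom, np.nan)
    return pd.Series(r, index=gene_rows.index, name="correlation")


def _paired_correlations(lnc_mat: np.ndarray, pc_mat: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between two equally shaped matrices."""
    a = lnc_mat - lnc_mat.mean(axis=1, keepdims=True)
    b = pc_mat - pc_mat.mean(axis=1, keepdims=True)
    denom = np.sqrt((a**2).sum(axis=1) * (b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (a * b).sum(axis=1) / denom, np.nan)


def randomization_test(
    observed_correlations,
    lnc_rows: pd.DataFrame,
    background_pc_rows: pd.DataFrame,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    log_transform: bool = True,
) -> tuple[float, np.ndarray]:
    """Pseudo-neighbor permutation test for lncRNA/neighbor co-expression.

    Each permutation draws, for every observed (lncRNA, neighbor) pair, a
    random protein-coding gene from the background (true neighbors excluded by
    the caller) and recomputes the paired correlations; the null statistic is
    their mean. Returns the plus-one empirical p-value
    ``(1 + #{null >= observed}) / (1 + n_perm)`` and the full null
    distribution.
    """
    obs = np.asarray(observed_correlations, dtype=float)
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    if len(lnc_rows) != obs.size:
        raise ValueError("one lncRNA row per observed correlation is required")
    if len(background_pc_rows) < obs.size:
        raise ValueError("background smaller than the neighbor count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    lnc_mat = _log_rows(lnc_rows.to_numpy(dtype=float), log_transform)
    bg_mat = _log_rows(background_pc_rows.to_numpy(dtype=float), log_transform)
    observed_mean = float(np.nanmean(obs))
    null = np.empty(n_perm)
    for i in range(n_perm):
        pick = rng.choice(bg_mat.shape[0], size=obs.size, replace=False)
        null[i] = np.nanmean(_paired_correlations(lnc_mat, bg_mat[pick]))
    p = (1 + int((null >= observed_mean).sum())) / (1 + n_perm)
    return float(p), null


def go_enrichment(
    gene_set: Sequence[str],
    go_annotation: pd.DataFrame,
    universe: Sequence[str],
    p_max: float = 0.1,
    min_overlap: int = 2,
) -> list[EnrichmentResult]:
    """Hypergeometric GO-term enrichment with BH correction.

    ``go_annotation`` columns: gene_id, term_id, optional term_name. Terms are
    tested against all annotated genes restricted to the universe; results are
    kept when the adjusted p-value is below ``p_max`` and at least
    ``min_overlap`` query genes carry the term.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    genes = set(gene_set)
    if not genes <= universe_set:
        raise ValueError("gene_set must be a subset of the universe")
    ann = go_annotation[go_annotation["gene_id"].isin(universe_set)]
    names = (
        ann.drop_duplicates("term_id").set_index("term_id")["term_name"].to_dict()
        if "term_name" in ann.columns
        else {}
    )
    results = []
    for term_id, grp in ann.groupby("term_id", sort=True):
        term_genes = set(grp["gene_id"])
        hit = tuple(sorted(genes & term_genes))
        p = hypergeom_upper_tail(len(hit), len(universe_set), len(term_genes), len(genes))
        results.append(
            EnrichmentResult(
                term_id=term_id,
                overlap_count=len(hit),
                set_size=len(genes),
                term_size=len(term_genes),
                universe_size=len(universe_set),
                p_raw=p,
                p_adjusted=np.nan,
                contributing_genes=hit,
                term_name=names.get(term_id, ""),
            )
        )
    adjusted = bh_adjust([r.p_raw for r in results])
    for r, q in zip(results, adjusted):
        r.p_adjusted = float(q)
    kept = [r for r in results if r.p_adjusted < p_max and r.overlap_count >= min_overlap]
    kept.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term_id))
    return kept


def band_enrichment(
    category_genes: Sequence[str],
    gene_bands: Mapping[str, str | None],
    gene_chroms: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-band and per-chromosome hypergeometric enrichment of a gene category.

    The universe is every gene with a location; significance is the raw upper
    tail p <= alpha (no multiplicity correction, matching how chromosome maps
    are usually starred).
    """
    universe = list(gene_chroms)
    cat = set(category_genes)
    rows = []
    for scope, labels in (("chromosome", gene_chroms), ("band", gene_bands)):
        groups: dict[str, set[str]] = {}
        for gid in universe:
            lab = labels.get(gid)
            if lab is not None:
                groups.setdefault(lab, set()).add(gid)
        for lab, members in sorted(groups.items()):
            k = len(cat & members)
            p = hypergeom_upper_tail(k, len(universe), len(members), len(cat))
            rows.append(
                {
                    "scope": scope,
                    "label": lab,
                    "category_in_group": k,
                    "group_size": len(members),
                    "p_raw": p,
                    "significant": p <= alpha,
                }
            )
    return pd.DataFrame(rows)


def comodification_features(
    profiles: Mapping[str, Mapping[str, np.ndarray]],
    marks: Sequence[str] = ACTIVE_MARKS,
    summary: str = "mean",
) -> pd.DataFrame:
    """Per-gene feature vector from promoter profiles of the active marks.

    Default: one value per mark (mean over the 40 promoter bins), z-scored per
    mark across genes. ``summary='bins'`` concatenates all bins instead.
    """
    rows = {}
    for gid, per_mark in profiles.items():
        vecs = []
        for m in marks:
            bins = np.asarray(per_mark[m], dtype=float)
            vecs.append(bins.mean(keepdims=True) if summary == "mean" else bins)
        rows[gid] = np.concatenate(vecs)
    df = pd.DataFrame.from_dict(rows, orient="index")
    std = df.std(axis=0, ddof=0).replace(0, 1.0)
    return (df - df.mean(axis=0)) / std


def _pearson_distance(mat: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(mat)
    corr = np.nan_to_num(corr, nan=0.0)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def predict_ts_function(
    tissue: str,
    ts_lnc_ids: Sequence[str],
    ts_pc_ids: Sequence[str],
    promoter_profiles: Mapping[str, Mapping[str, np.ndarray]],
    go_annotation: pd.DataFrame,
    universe: Sequence[str],
    marks: Sequence[str] = ACTIVE_MARKS,
    k: int | None = None,
    max_k: int = 15,
    p_max: float = 0.1,
    min_overlap: int = 2,
) -> list[CoModificationCluster]:
    """Co-modification clustering of TS genes of one tissue.

    TS lncRNAs and TS protein-coding genes are embedded by their active-mark
    promoter signals, clustered by average-linkage agglomeration on
    1 - Pearson correlation, and the tree is cut at the k (2..min(max_k, n-1))
    maximizing the mean silhouette unless ``k`` is fixed. GO enrichment runs on
    each cluster's protein-coding members only; clusters without them predict
    nothing. Deterministic: no randomness is involved.
    """
    members = [g for g in list(ts_lnc_ids) + list(ts_pc_ids) if g in promoter_profiles]
    members = sorted(set(members))
    if len(members) < 3:
        warnings.warn(f"tissue {tissue}: fewer than 3 profiled TS genes; no clustering")
        return []
    feats = comodification_features({g: promoter_profiles[g] for g in members}, marks=marks)
    feats = feats.loc[members]
    dist = _pearson_distance(feats.to_numpy())
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")

    if k is None:
        best_k, best_score = 2, -np.inf
        for kk in range(2, min(max_k, len(members) - 1) + 1):
            labels = fcluster(tree, kk, criterion="maxclust")
            if len(np.unique(labels)) < 2:
                continue
            score = silhouette_score(dist, labels, metric="precomputed")
            if score > best_score + 1e-12:
                best_k, best_score = kk, score
        k = best_k
    labels = fcluster(tree, k, criterion="maxclust")

    pc_set = set(ts_pc_ids)
    clusters = []
    for cid in sorted(np.unique(labels)):
        ids = tuple(m for m, lab in zip(members, labels) if lab == cid)
        pc_members = [g for g in ids if g in pc_set]
        terms: list[EnrichmentResult] = []
        if pc_members:
            terms = go_enrichment(pc_members, go_annotation, universe, p_max=p_max, min_overlap=min_overlap)
        clusters.append(
            CoModificationCluster(
                tissue=tissue,
                cluster_id=int(cid),
                member_ids=ids,
                centroid=feats.loc[list(ids)].mean(axis=0).to_numpy(),
                enriched_terms=terms,
            )
        )
    return clusters


def predictions_frame(clusters: Sequence[CoModificationCluster], lnc_ids: Sequence[str]) -> pd.DataFrame:
    """One row per (lncRNA, inherited term): evidence = comodification."""
    lnc_set = set(lnc_ids)
    rows = []
    for c in clusters:
        for gid in c.member_ids:
            if gid not in lnc_set:
                continue
            for t in c.enriched_terms:
                rows.append(
                    {
                        "lncRNA_id": gid,
                        "term_id": t.term_id,
                        "term_name": t.term_name,
                        "p_adjusted": t.p_adjusted,
                        "cluster_id": c.cluster_id,
                        "tissue": c.tissue,
                        "evidence": "comodification",
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["lncRNA_id", "term_id", "term_name", "p_adjusted", "cluster_id", "tissue", "evidence"],
    )
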