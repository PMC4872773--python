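"""Structural, conservation, CpG and regulator characterization of gene sets."""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .intervals import GenomicInterval, IntervalIndex
from .stats import wilcoxon_rank_sum


class GenomeTrack:
    """Per-nucleotide scores stored as sorted segments per chromosome.

    Segments are kept as (starts, ends, values) arrays; a per-nucleotide
    window is materialized only on ``slice``, so chromosome size never
    matters. ``fill`` is the value of positions absent from the source file:
    NaN for sparse score tracks such as conservation (missing positions are
    excluded from averages), 0.0 for read-coverage tracks (no reads means
    zero depth).
    """

    def __init__(
        self,
        segments: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        fill: float = math.nan,
        chrom_sizes: Mapping[str, int] | None = None,
    ):
        self.segments = {}
        for chrom, (starts, ends, vals) in segments.items():
            order = np.argsort(starts, kind="stable")
            self.segments[chrom] = (
                np.asarray(starts)[order],
                np.asarray(ends)[order],
                np.asarray(vals, dtype=float)[order],
            )
        self.fill = fill
        self.chrom_sizes = dict(chrom_sizes or {})

    @classmethod
    def from_arrays(cls, arrays: Mapping[str, np.ndarray], fill: float = math.nan) -> "GenomeTrack":
        """Build from dense per-chromosome arrays (convenient for small tests)."""
        segs = {}
        sizes = {}
        for chrom, arr in arrays.items():
            arr = np.asarray(arr, dtype=float)
            starts = np.arange(arr.size)
            segs[chrom] = (starts, starts + 1, arr)
            sizes[chrom] = arr.size
        return cls(segs, fill=fill, chrom_sizes=sizes)

    @classmethod
    def from_bedgraph(
        cls,
        path: str | Path,
        chrom_sizes: Mapping[str, int] | None = None,
        fill: float = math.nan,
    ) -> "GenomeTrack":
        """Load a 4-column bedGraph (chrom, start, end, value; 0-based half-open)."""
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        df = df[~df["chrom"].str.startswith(("track", "browser"))]
        segs = {
            chrom: (
                grp["start"].to_numpy(np.int64),
                grp["end"].to_numpy(np.int64),
                grp["value"].to_numpy(float),
            )
            for chrom, grp in df.groupby("chrom", sort=False)
        }
        return cls(segs, fill=fill, chrom_sizes=chrom_sizes)

    def chrom_size(self, chrom: str) -> int | None:
        if chrom in self.chrom_sizes:
            return self.chrom_sizes[chrom]
        seg = self.segments.get(chrom)
        return int(seg[1].max()) if seg is not None else None

    def slice(self, region: GenomicInterval) -> np.ndarray:
        """Per-nucleotide values over a region (length == region.length);
        positions not covered by any segment carry ``fill``. Later segments
        overwrite earlier ones where they overlap."""
        out = np.full(region.length, self.fill)
        seg = self.segments.get(region.chrom)
        if seg is None:
            return out
        starts, ends, vals = seg
        lo = int(np.searchsorted(starts, region.start - (ends - starts).max(), side="left")) if starts.size else 0
        for i in range(lo, starts.size):
            s, e = int(starts[i]), int(ends[i])
            if s >= region.end:
                break
            if e <= region.start:
                continue
            out[max(s, region.start) - region.start: min(e, region.end) - region.start] = vals[i]
        return out


def mean_conservation(region: GenomicInterval, track: GenomeTrack) -> float:
    """Mean per-nucleotide score over a region; missing positions are excluded
    from the denominator. NaN when the region is entirely uncovered."""
    vals = track.slice(region)
    covered = ~np.isnan(vals)
    if not covered.any():
        return math.nan
    return float(vals[covered].mean())


def mean_conservation_regions(regions: Sequence[GenomicInterval], track: GenomeTrack) -> float:
    """Length-weighted mean over several disjoint regions (e.g. union exons)."""
    vals = np.concatenate([track.slice(r) for r in regions]) if regions else np.array([])
    covered = ~np.isnan(vals)
    if not covered.any():
        return math.nan
    return float(vals[covered].mean())


# ---------------------------------------------------------------------------
# gene structure

def structure_stats(genes: Iterable[GeneModel]) -> pd.DataFrame:
    """Per-gene structural statistics.

    Gene-level lengths use the locus span and the union of exons across
    transcripts; exon_count is the maximum over transcripts.
    """
    rows = []
    for g in genes:
        exonic = sum(e.length for e in g.union_exons())
        rows.append(
            {
                "gene_id": g.gene_id,
                "genomic_length": g.locus.length,
                "exonic_length": exonic,
                "intronic_length": g.locus.length - exonic,
                "exon_count": max(t.exon_count for t in g.transcripts),
                "transcript_count": len(g.transcripts),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


def compare_structure(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    columns: Sequence[str] = ("intronic_length", "genomic_length", "exon_count", "transcript_count"),
) -> pd.DataFrame:
    """Group medians and Wilcoxon rank-sum p-values per structural column."""
    rows = []
    for col in columns:
        rows.append(
            {
                "stat": col,
                "median_a": float(table_a[col].median()),
                "median_b": float(table_b[col].median()),
                "wilcoxon_p": wilcoxon_rank_sum(table_a[col], table_b[col]),
            }
        )
    return pd.DataFrame(rows).set_index("stat")


# ---------------------------------------------------------------------------
# regulators

def read_regulator_table(path: str | Path) -> pd.DataFrame:
    """TSV with columns regulator_id, target_id, regulator_type in {TF, miRNA}."""
    df = pd.read_csv(path, sep="\t")
    bad = set(df["regulator_type"]) - {"TF", "miRNA"}
    if bad:
        raise ValueError(f"unknown regulator types: {sorted(bad)}")
    return df.drop_duplicates()


def count_regulators(feature_id: str, table: pd.DataFrame) -> tuple[int, int]:
    """Distinct (TF, miRNA) regulator counts targeting one feature."""
    sub = table[table["target_id"] == feature_id]
    tf = sub.loc[sub["regulator_type"] == "TF", "regulator_id"].nunique()
    mi = sub.loc[sub["regulator_type"] == "miRNA", "regulator_id"].nunique()
    return int(tf), int(mi)


def count_regulators_all(feature_ids: Sequence[str], table: pd.DataFrame) -> pd.DataFrame:
    dedup = table.drop_duplicates(["regulator_id", "target_id", "regulator_type"])
    counts = (
        dedup.groupby(["target_id", "regulator_type"])["regulator_id"].nunique().unstack(fill_value=0)
    )
    out = pd.DataFrame(index=pd.Index(feature_ids, name="feature_id"))
    out["tf_count"] = counts.get("TF", pd.Series(dtype=int)).reindex(out.index).fillna(0).astype(int)
    out["mirna_count"] = counts.get("miRNA", pd.Series(dtype=int)).reindex(out.index).fillna(0).astype(int)
    return out


def tf_edges_from_binding_sites(
    sites: pd.DataFrame,
    genes: Iterable[GeneModel],
    upstream: int = 5000,
    downstream: int = 1000,
) -> pd.DataFrame:
    """Derive TF->gene edges from binding-site coordinates.

    A site counts when it overlaps the strand-aware window from ``upstream``
    bases 5' of the TSS to ``downstream`` bases 3' of it. ``sites`` columns:
    tf_id, chrom, start, end.
    """
    index = IntervalIndex(
        (GenomicInterval(str(r.chrom), int(r.start), int(r.end)), r.tf_id)
        for r in sites.itertuples()
    )
    edges = []
    for g in genes:
        pos, strand = g.tss, g.locus.strand
        if strand == "-":
            win = GenomicInterval(g.locus.chrom, max(0, pos - downstream), pos + upstream)
        else:
            win = GenomicInterval(g.locus.chrom, max(0, pos - upstream), pos + downstream)
        for _iv, tf_id in index.overlapping(win):
            edges.append({"regulator_id": tf_id, "target_id": g.gene_id, "regulator_type": "TF"})
    return pd.DataFrame(edges, columns=["regulator_id", "target_id", "regulator_type"]).drop_duplicates()


# ---------------------------------------------------------------------------
# CpG islands and promoter CpG class

def read_bed_intervals(path: str | Path) -> list[GenomicInterval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2])))
    return out


def cgi_overlap(promoter: GenomicInterval, cgi_index: IntervalIndex) -> bool:
    """True when the promoter intersects at least one CpG island."""
    return bool(cgi_index.overlapping(promoter))


@dataclass(frozen=True)
class CpGClassParams:
    """Sliding-window high/intermediate/low CpG promoter scheme."""

    window: int = 500
    high_gc: float = 0.55
    high_oe: float = 0.6
    low_oe: float = 0.4


def categorize_promoter_cpg(
    sequence: str,
    cgi_index: IntervalIndex | None = None,
    promoter: GenomicInterval | None = None,
    params: CpGClassParams = CpGClassParams(),
) -> dict:
    """CGI overlap plus high/intermediate/low CpG-content class of a promoter.

    high: some window has GC >= high_gc and CpG observed/expected >= high_oe;
    low: no window reaches CpG o/e >= low_oe; intermediate otherwise.
    CpG o/e per window = #CpG * window / (#C * #G); N bases count as non-GC.
    """
    seq = sequence.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError(f"non-ACGTN symbols in sequence: {sorted(set(seq) - set('ACGTN'))}")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    cpg = ((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(np.int64)

    w = min(params.window, arr.size)
    if w < 2:
        raise ValueError("sequence too short for CpG classification")

    def windowed(x: np.ndarray, width: int) -> np.ndarray:
        c = np.concatenate([[0], np.cumsum(x)])
        return c[width:] - c[:-width]

    n_c = windowed(is_c, w).astype(float)
    n_g = windowed(is_g, w).astype(float)
    n_cpg = windowed(cpg, w - 1).astype(float)  # CpG dinucleotides fully inside the window
    gc_frac = (n_c + n_g) / w
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(n_c * n_g > 0, n_cpg * w / (n_c * n_g), 0.0)

    if ((gc_frac >= params.high_gc) & (oe >= params.high_oe)).any():
        cls = "high"
    elif not (oe >= params.low_oe).any():
        cls = "low"
    else:
        cls = "intermediate"

    overlap = False
    if cgi_index is not None and promoter is not None:
        overlap = cgi_overlap(promoter, cgi_index)
    return {"CGI_overlap": overlap, "cpg_class": cls}
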