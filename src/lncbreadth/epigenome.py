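"""Promoter histone-mark metaprofiles, enhancer ubiquity, and proximity.

The promoter of each gene (4,000 nt around the TSS) is divided into 40 bins
of 100 nt; each bin carries the mean per-nucleotide read depth. Bins are
oriented 5'->3' along the gene's strand so that "upstream" bins are
comparable between strands. Enhancers are labeled ubiquitous (UE) when
detected in more than two cell lines (configurable to "at least two"),
tissue-specific (TS) otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .features import GenomeTrack
from .intervals import GenomicInterval, IntervalIndex


@dataclass
class PromoterProfile:
    feature_id: str
    mark: str
    cell_line: str
    bins: np.ndarray  # mean depth per bin, 5'->3'
    bin_sums: np.ndarray  # integer depth totals per bin (exact bookkeeping)
    clipped: bool = False

    def __post_init__(self) -> None:
        if len(self.bins) != len(self.bin_sums):
            raise ValueError("bins and bin_sums disagree")
        if (np.asarray(self.bins) < 0).any():
            raise ValueError("negative bin values")


def bin_promoter_signal(
    promoter: GenomicInterval,
    coverage: GenomeTrack,
    nbins: int = 40,
    feature_id: str = "",
    mark: str = "",
    cell_line: str = "",
) -> PromoterProfile:
    """Mean coverage per bin over a promoter window.

    The promoter length must divide evenly into ``nbins``; windows clipped at
    chromosome ends are zero-padded and flagged. On the minus strand the bin
    order is reversed so bin 0 is the 5'-most (upstream) bin.
    """
    if promoter.length % nbins != 0:
        raise ValueError(f"promoter length {promoter.length} not divisible by {nbins} bins")
    width = promoter.length // nbins
    vals = np.nan_to_num(coverage.slice(promoter), nan=0.0)
    size = coverage.chrom_size(promoter.chrom)
    clipped = promoter.start == 0 or (size is not None and promoter.end > size)
    sums = vals.reshape(nbins, width).sum(axis=1)
    if promoter.strand == "-":
        sums = sums[::-1]
    bin_sums = np.rint(sums).astype(np.int64)
    exact = np.allclose(sums, bin_sums)
    return PromoterProfile(
        feature_id=feature_id,
        mark=mark,
        cell_line=cell_line,
        bins=sums / width,
        bin_sums=bin_sums if exact else np.floor(sums).astype(np.int64),
        clipped=clipped,
    )


def aggregate_profiles(profiles: Sequence[PromoterProfile]) -> np.ndarray:
    """Element-wise mean profile over a gene category."""
    if not profiles:
        raise ValueError("no profiles to aggregate")
    return np.mean([p.bins for p in profiles], axis=0)


@dataclass
class Enhancer:
    interval: GenomicInterval
    cell_lines_present: frozenset[str]
    strength: str | None = None  # strong | weak
    ubiquity_label: str | None = None  # UE | TS

    def __post_init__(self) -> None:
        if not self.cell_lines_present:
            raise ValueError("enhancer with no cell lines")


def read_enhancer_bed(path: str | Path) -> list[Enhancer]:
    """BED with a comma-separated cell-line column 4 and optional state column 5."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            cells = frozenset(x for x in f[3].split(",") if x)
            strength = f[4] if len(f) > 4 and f[4] in ("strong", "weak") else None
            out.append(Enhancer(GenomicInterval(f[0], int(f[1]), int(f[2])), cells, strength))
    return out


def classify_enhancers(enhancers: Iterable[Enhancer], rule: str = ">2") -> list[Enhancer]:
    """Label enhancers UE/TS from their cell-line presence count.

    ``rule='>2'``: UE iff present in more than two cell lines (default).
    ``rule='>=2'``: UE iff present in at least two.
    """
    if rule not in (">2", ">=2"):
        raise ValueError(f"unknown enhancer ubiquity rule {rule!r}")
    cut = 2 if rule == ">2" else 1
    out = list(enhancers)
    for e in out:
        e.ubiquity_label = "UE" if len(e.cell_lines_present) > cut else "TS"
    return out


def proximity_fraction(
    feature_loci: dict[str, GenomicInterval],
    target_intervals: Sequence[GenomicInterval],
    window: int,
) -> tuple[float, pd.Series]:
    """Fraction of features with at least one target within ``window`` bases.

    Distance is the gap between intervals (0 when overlapping, infinite across
    chromosomes). Also returns the per-feature boolean table.
    """
    if not feature_loci:
        raise ValueError("empty feature set")
    if window < 0:
        raise ValueError("window must be >= 0")
    index = IntervalIndex((iv, None) for iv in target_intervals)
    flags = {
        fid: bool(index.within(locus, window))
        for fid, locus in feature_loci.items()
    }
    series = pd.Series(flags, name=f"within_{window}")
    return float(series.mean()), series
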