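"""Gene models, GTF loading, and the non-redundant lncRNA set.

Gene annotations for lncRNAs commonly come from several catalogs (GENCODE,
Ensembl, assembled catalogs such as Cabili et al.'s lincRNAs) that describe
the same loci with different identifiers. The non-redundant set collapses
cross-source duplicates: whenever two loci from different sources overlap by
more than a fraction cutoff (default 0.8), only the model from the
higher-priority source is kept.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

from .intervals import GenomicInterval, IntervalIndex, overlap_fraction, tss

log = logging.getLogger(__name__)

DEFAULT_PRIORITY = ("GENCODE", "Ensembl", "Cabili")

BIOTYPE_KEYS = ("gene_biotype", "gene_type", "biotype")
LNCRNA_BIOTYPES = {"lncRNA", "lincRNA", "antisense", "processed_transcript"}


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in {self.transcript_id}")
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"transcript {self.transcript_id} spans chromosomes/strands")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def genomic_length(self) -> int:
        return self.span.length

    @property
    def intronic_length(self) -> int:
        return self.genomic_length - self.exonic_length

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def tss(self) -> int:
        return tss(self.span)


@dataclass
class GeneModel:
    gene_id: str
    biotype: str
    source: str
    transcripts: list[TranscriptModel]
    band: str | None = None

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")

    @property
    def locus(self) -> GenomicInterval:
        """Union span over all transcripts."""
        spans = [t.span for t in self.transcripts]
        return GenomicInterval(
            spans[0].chrom,
            min(s.start for s in spans),
            max(s.end for s in spans),
            spans[0].strand,
        )

    @property
    def tss(self) -> int:
        """5'-most TSS over transcripts on the gene's strand."""
        positions = [t.tss for t in self.transcripts]
        return max(positions) if self.locus.strand == "-" else min(positions)

    def union_exons(self) -> list[GenomicInterval]:
        """Merged exon intervals across all transcripts."""
        exons = sorted((e for t in self.transcripts for e in t.exons), key=lambda e: e.start)
        merged: list[GenomicInterval] = []
        for e in exons:
            if merged and e.start <= merged[-1].end:
                last = merged[-1]
                if e.end > last.end:
                    merged[-1] = GenomicInterval(last.chrom, last.start, e.end, last.strand)
            else:
                merged.append(e)
        return merged


class GTFParseError(ValueError):
    pass


def _biotype_of(attrs, default: str | None) -> str | None:
    for key in BIOTYPE_KEYS:
        if key in attrs:
            return attrs[key][0]
    return default


def load_gene_models(
    path: str | Path,
    biotype_filter: str | Sequence[str] | None = None,
    default_biotype: str | None = None,
) -> list[GeneModel]:
    """Parse a GTF into gene models with exon structure.

    Coordinates are converted from GTF's 1-based closed to internal 0-based
    half-open. The GTF ``source`` column (field 2) is taken as the annotation
    source for redundancy resolution. Transcripts without exon records are
    dropped with a warning. ``biotype_filter`` keeps only matching biotypes
    (a lone string means exactly that biotype; ``"lncRNA"`` also accepts the
    common long-non-coding sub-biotypes).
    """
    path = Path(path)
    with open(path) as fh:
        if not any(line.strip() and not line.startswith("#") for line in fh):
            return []
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils raises heterogeneous errors
        raise GTFParseError(f"failed to parse GTF {path}: {exc}") from exc

    gene_meta: dict[str, tuple[str | None, str | None]] = {}
    for g in db.features_of_type("gene"):
        gene_meta[g.attributes["gene_id"][0]] = (_biotype_of(g.attributes, None), g.source)

    exons_by_tx: dict[str, list[GenomicInterval]] = {}
    tx_gene: dict[str, str] = {}
    tx_meta: dict[str, tuple[str | None, str | None]] = {}
    for ex in db.features_of_type("exon"):
        try:
            txid = ex.attributes["transcript_id"][0]
            gid = ex.attributes["gene_id"][0]
        except KeyError as exc:
            raise GTFParseError(f"exon without {exc} attribute at {ex.seqid}:{ex.start}") from exc
        exons_by_tx.setdefault(txid, []).append(
            GenomicInterval(ex.seqid, ex.start - 1, ex.end, ex.strand or ".")
        )
        tx_gene[txid] = gid
        tx_meta.setdefault(txid, (_biotype_of(ex.attributes, None), ex.source))

    # transcript features without any exon record are rejected with a warning
    for t in db.features_of_type("transcript"):
        txid = t.attributes["transcript_id"][0]
        if txid not in exons_by_tx:
            warnings.warn(f"transcript {txid} has no exons; skipped", stacklevel=2)

    genes: dict[str, GeneModel] = {}
    for txid, exons in exons_by_tx.items():
        gid = tx_gene[txid]
        tm = TranscriptModel(txid, gid, exons)
        if gid in genes:
            genes[gid].transcripts.append(tm)
        else:
            biotype, source = gene_meta.get(gid, tx_meta[txid])
            genes[gid] = GeneModel(
                gene_id=gid,
                biotype=biotype or default_biotype or "unknown",
                source=source or "unknown",
                transcripts=[tm],
            )

    models = list(genes.values())
    if biotype_filter is not None:
        if isinstance(biotype_filter, str):
            accepted = LNCRNA_BIOTYPES if biotype_filter == "lncRNA" else {biotype_filter}
        else:
            accepted = set(biotype_filter)
        models = [m for m in models if m.biotype in accepted]
    return models


def build_nonredundant_set(
    models: Iterable[GeneModel],
    priority: Sequence[str] = DEFAULT_PRIORITY,
    min_overlap: float = 0.8,
    overlap_method: str = "min",
) -> tuple[list[GeneModel], pd.DataFrame]:
    """Collapse cross-source duplicate loci by source priority.

    A model is dropped when its locus overlaps a model from a higher-priority
    source by more than ``min_overlap``. Intra-source redundancy is left
    untouched. Returns the retained models plus a redundancy log
    (removed_id, kept_id, overlap_fraction).
    """
    models = list(models)
    rank = {src: i for i, src in enumerate(priority)}
    for m in models:
        if m.source not in rank:
            raise ValueError(f"gene {m.gene_id} has source {m.source!r} not in priority {priority}")

    # a model is redundant when ANY higher-priority model from another source
    # overlaps it above the cutoff, whether or not that model itself survives
    # (so a chain A > B > C with A~B and B~C keeps only A)
    index = IntervalIndex((m.locus, m) for m in models)
    kept: list[GeneModel] = []
    removed_rows = []
    for m in models:
        duplicate_of = None
        best = 0.0
        for _iv, other in index.overlapping(m.locus):
            if other.source == m.source or rank[other.source] >= rank[m.source]:
                continue
            frac = overlap_fraction(m.locus, other.locus, method=overlap_method)
            if frac > min_overlap and frac >= best:
                duplicate_of, best = other, frac
        if duplicate_of is None:
            kept.append(m)
        else:
            removed_rows.append(
                {"removed_id": m.gene_id, "kept_id": duplicate_of.gene_id, "overlap_fraction": best}
            )
    log.info("non-redundant set: kept %d of %d models", len(kept), len(models))
    redundancy = pd.DataFrame(removed_rows, columns=["removed_id", "kept_id", "overlap_fraction"])
    return kept, redundancy


def write_loci_bed(models: Iterable[GeneModel], path: str | Path) -> None:
    """BED6 of gene loci (0-based half-open, score column unused)."""
    with open(path, "w") as fh:
        for m in models:
            loc = m.locus
            fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\t{m.gene_id}\t0\t{loc.strand}\n")


def read_loci_bed(path: str | Path) -> dict[str, GenomicInterval]:
    out: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
            strand = fields[5] if len(fields) > 5 else "."
            out[name] = GenomicInterval(chrom, start, end, strand)
    return out


def assign_bands(models: Iterable[GeneModel], bands: pd.DataFrame) -> None:
    """Label each gene with the chromosome band containing its TSS.

    ``bands`` columns: chrom, start, end, band (0-based half-open, as in
    UCSC cytoBand after coordinate conversion).
    """
    index = IntervalIndex(
        (GenomicInterval(r.chrom, int(r.start), int(r.end)), r.band)
        for r in bands.itertuples()
    )
    for m in models:
        pos = m.tss
        point = GenomicInterval(m.locus.chrom, pos, pos + 1)
        hits = index.overlapping(point)
        m.band = hits[0][1] if hits else None
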