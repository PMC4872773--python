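"""Self-consistent synthetic dataset with planted ground truth.

The generator emulates the statistical structure the analysis assumes:

* a tissues x transcripts FPKM matrix with planted ubiquitously expressed
  genes (every tissue, low CV), planted tissue-specific genes (one tissue),
  and an exponential near-zero background from untranscribed regions;
* compact gene structures for UE genes (shorter genomic/intronic span, fewer
  exons and isoforms) versus TS genes;
* elevated conservation over UE exons and promoters;
* CpG islands at about one third of UE promoters;
* enhancers near lncRNAs with per-cell-line presence counts separating
  ubiquitous from cell-type-restricted enhancers;
* six active histone marks with two-block signatures at TS promoters, giving
  each tissue's TS genes a planted co-modification clustering;
* essential protein-coding genes placed within 50 kb of a configured fraction
  of UE (and TS) lncRNAs, and UE protein-coding neighbors within 100 kb.

Every file is a plain-text standard format (GTF, TSV, BED, bedGraph) and the
whole bundle is a deterministic function of the seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

MARKS = ("H3K4me1", "H3K27ac", "H3K4me2", "H3K4me3", "H3K9ac", "H3K36me3")


@dataclass
class GeneratorConfig:
    seed: int = 42
    n_tissues: int = 20
    n_lnc: int = 2000
    n_pc: int = 1000
    n_ue_lnc: int = 200
    n_ts_lnc: int = 300
    ue_pc_fraction: float = 0.243
    ts_pc_fraction: float = 0.123

    # expression model (FPKM scale)
    background_mean: float = 0.05  # untranscribed-region FPKM, exponential
    n_background: int = 5000
    leak_mean: float = 0.01  # FPKM leakage of silent gene/tissue cells
    ue_meanlog: float = 2.0
    ue_sdlog: float = 0.6
    ue_noise_sdlog: float = 0.2  # per-tissue noise -> CV ~ 0.2 for UE genes
    sig_meanlog: float = 1.5
    sig_sdlog: float = 0.8  # on-tissue expression of TS / intermediate genes
    max_samples_per_tissue: int = 3

    # gene structure (nt)
    ue_genomic_median: float = 5000.0
    ts_genomic_median: float = 10000.0
    genomic_sdlog: float = 0.4
    ue_max_exons: int = 3
    ts_max_exons: int = 6
    pc_genomic_median: float = 20000.0

    # conservation
    cons_ue: float = 0.6
    cons_ts: float = 0.2
    cons_other: float = 0.25
    cons_sd: float = 0.05
    cons_segment: int = 500

    # promoters / epigenome
    cgi_fraction_ue: float = 1 / 3
    cgi_fraction_other: float = 0.05
    n_cell_lines: int = 13
    enhancer_prob_ue: float = 0.8
    enhancer_prob_ts: float = 0.6
    enhancer_prob_other: float = 0.3
    mark_high: float = 10.0
    mark_low: float = 2.0
    mark_noise_frac: float = 0.1  # noise sd as a fraction of block separation
    n_clusters_per_tissue: int = 2

    # genomic layout
    territory: int = 300_000
    genes_per_chrom: int = 1000
    territories_per_band: int = 20
    n_redundant_duplicates: int = 20

    # planted proximity fractions
    neighbor_fraction_ue: float = 0.837  # UE pc gene within 100 kb of a UE lncRNA
    essential_fraction_ue: float = 0.345  # essential gene within 50 kb
    essential_fraction_ts: float = 0.121

    def validate(self) -> None:
        if self.n_ue_lnc + self.n_ts_lnc > self.n_lnc:
            raise ValueError("planted UE + TS exceed n_lnc")
        if self.ue_pc_fraction + self.ts_pc_fraction > 1:
            raise ValueError("pc fractions sum above 1")
        for name in (
            "ue_pc_fraction", "ts_pc_fraction", "cgi_fraction_ue", "cgi_fraction_other",
            "enhancer_prob_ue", "enhancer_prob_ts", "enhancer_prob_other",
            "neighbor_fraction_ue", "essential_fraction_ue", "essential_fraction_ts",
            "mark_noise_frac",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_tissues", "n_lnc", "n_pc", "n_background", "n_cell_lines"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class _GenePlan:
    gene_id: str
    biotype: str
    label: str  # UE | TS | other
    chrom: str
    start: int = 0
    strand: str = "+"
    ts_tissue: str | None = None
    cluster_id: int | None = None
    essential: bool = False
    neighbor_planted: bool = False
    essential_planted: bool = False
    cgi_planted: bool = False
    enhancer_label: str = ""
    transcripts: list = field(default_factory=list)  # (tx_id, [(exon_start, exon_end)])
    end: int = 0

    @property
    def tss(self) -> int:
        return self.end if self.strand == "-" else self.start


def _gene_structure(rng, gene_id, start, strand, median_len, sdlog, max_exons, n_tx_max):
    """Exon/intron layout plus isoforms for one gene."""
    genomic = int(median_len * math.exp(rng.normal(0.0, sdlog)))
    k = int(rng.integers(1, max_exons + 1))
    exon_lens = rng.integers(150, 400, size=k)
    exonic = int(exon_lens.sum())
    genomic = max(genomic, exonic + 50 * max(0, k - 1))
    intron_total = genomic - exonic
    if k > 1:
        cuts = np.sort(rng.uniform(0, 1, size=k - 2)) if k > 2 else np.array([])
        weights = np.diff(np.concatenate([[0.0], cuts, [1.0]]))
        introns = 50 + np.floor(weights * (intron_total - 50 * (k - 1))).astype(int)
    else:
        introns = np.array([], dtype=int)
    exons = []
    pos = start
    for i in range(k):
        exons.append((pos, pos + int(exon_lens[i])))
        pos = exons[-1][1] + (int(introns[i]) if i < k - 1 else 0)
    end = exons[-1][1]

    n_tx = int(rng.integers(1, n_tx_max + 1))
    transcripts = []
    for t in range(n_tx):
        if t == 0 or k <= 2:
            tx_exons = list(exons)
        else:  # drop one internal exon, keeping the span
            drop = int(rng.integers(1, k - 1))
            tx_exons = [e for i, e in enumerate(exons) if i != drop]
        transcripts.append((f"{gene_id}.t{t + 1}", tx_exons))
    return transcripts, end


def _tissue_profile(rng, cfg: GeneratorConfig, label: str, ts_index: int | None,
                    shared_log_noise: np.ndarray | None = None, pc: bool = False):
    """Planted tissue-level FPKM profile for one transcript."""
    n = cfg.n_tissues
    leak = rng.exponential(cfg.leak_mean, size=n)
    if label == "UE":
        base = math.exp(rng.normal(cfg.ue_meanlog + (0.5 if pc else 0.0), cfg.ue_sdlog))
        noise = rng.normal(0.0, cfg.ue_noise_sdlog, size=n)
        if shared_log_noise is not None:
            noise = 0.8 * shared_log_noise + rng.normal(0.0, 0.1, size=n)
        return base * np.exp(noise), noise
    if label == "TS":
        prof = leak
        prof[ts_index] = rng.lognormal(cfg.sig_meanlog, cfg.sig_sdlog)
        return prof, None
    # intermediate gene: expressed in 2..n-2 tissues
    width = int(rng.integers(2, max(3, n - 1)))
    active = rng.choice(n, size=min(width, n - 2), replace=False)
    prof = leak
    prof[active] = rng.lognormal(cfg.sig_meanlog, cfg.sig_sdlog, size=active.size)
    return prof, None


def _write_gtf(path: Path, plans: list[_GenePlan], sources: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for g in plans:
            src = sources.get(g.gene_id, "GENCODE")
            attrs = f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            fh.write(
                f"{g.chrom}\t{src}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tx_id, exons in g.transcripts:
                tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tx_id}"; gene_biotype "{g.biotype}";'
                fh.write(
                    f"{g.chrom}\t{src}\ttranscript\t{exons[0][0] + 1}\t{exons[-1][1]}\t.\t{g.strand}\t.\t{tattrs}\n"
                )
                for s, e in exons:
                    fh.write(f"{g.chrom}\t{src}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tattrs}\n")


def generate(config: GeneratorConfig, out_dir: str | Path) -> Path:
    """Write the full dataset bundle; returns the bundle directory.

    Same seed, same config => byte-identical bundle.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "marks").mkdir(exist_ok=True)

    tissues = [f"T{i + 1:02d}" for i in range(cfg.n_tissues)]
    cell_lines = [f"CL{i + 1:02d}" for i in range(cfg.n_cell_lines)]
    tissue_cell_line = {t: f"CL_{t}" for t in tissues}

    # ------------------------------------------------------------------ labels
    lnc_ids = [f"LNC{i + 1:05d}" for i in range(cfg.n_lnc)]
    lnc_labels = (
        ["UE"] * cfg.n_ue_lnc
        + ["TS"] * cfg.n_ts_lnc
        + ["other"] * (cfg.n_lnc - cfg.n_ue_lnc - cfg.n_ts_lnc)
    )
    perm = rng.permutation(cfg.n_lnc)
    lnc_labels = [lnc_labels[i] for i in perm]

    n_chrom = math.ceil(cfg.n_lnc / cfg.genes_per_chrom)
    plans: dict[str, _GenePlan] = {}
    ts_counter = 0
    for i, (gid, label) in enumerate(zip(lnc_ids, lnc_labels)):
        chrom = f"chrS{i // cfg.genes_per_chrom + 1}"
        tstart = (i % cfg.genes_per_chrom) * cfg.territory
        ts_tissue = None
        if label == "TS":
            ts_tissue = tissues[ts_counter % cfg.n_tissues]
            ts_counter += 1
        plans[gid] = _GenePlan(
            gene_id=gid, biotype="lncRNA", label=label, chrom=chrom,
            start=tstart + 100_000, strand="+" if rng.random() < 0.5 else "-",
            ts_tissue=ts_tissue,
        )

    ue_lnc = [g for g in lnc_ids if plans[g].label == "UE"]
    ts_lnc = [g for g in lnc_ids if plans[g].label == "TS"]

    # planted proximity sets (essential-planted is a subset of neighbor-planted)
    n_neighbor = round(cfg.neighbor_fraction_ue * len(ue_lnc))
    n_ess_ue = round(cfg.essential_fraction_ue * len(ue_lnc))
    n_ess_ue = min(n_ess_ue, n_neighbor)
    neighbor_hosts = list(rng.choice(ue_lnc, size=n_neighbor, replace=False))
    ess_ue_hosts = neighbor_hosts[:n_ess_ue]
    n_ess_ts = round(cfg.essential_fraction_ts * len(ts_lnc))
    ess_ts_hosts = list(rng.choice(ts_lnc, size=n_ess_ts, replace=False))
    for g in neighbor_hosts:
        plans[g].neighbor_planted = True
    for g in ess_ue_hosts + ess_ts_hosts:
        plans[g].essential_planted = True

    # ------------------------------------------------------------- pc genes
    pc_ids = [f"PC{i + 1:05d}" for i in range(cfg.n_pc)]
    planted_hosts = neighbor_hosts + ess_ts_hosts
    if len(planted_hosts) > cfg.n_pc:
        raise ValueError("n_pc too small for the planted proximity fractions")
    n_ue_pc = max(round(cfg.ue_pc_fraction * cfg.n_pc), len(planted_hosts))
    n_ts_pc = round(cfg.ts_pc_fraction * cfg.n_pc)
    pc_plans: dict[str, _GenePlan] = {}
    host_lnc: dict[str, str] = {}
    free_territories = [g for g in lnc_ids if g not in set(planted_hosts)]
    free_cycle = 0
    ts_pc_counter = 0
    for j, pid in enumerate(pc_ids):
        if j < len(planted_hosts):
            host = planted_hosts[j]
            label = "UE"
            essential = plans[host].essential_planted
        else:
            host = free_territories[free_cycle % len(free_territories)]
            free_cycle += 1
            essential = False
            if j < n_ue_pc:
                label = "UE"
            elif j < n_ue_pc + n_ts_pc:
                label = "TS"
            else:
                label = "other"
        ts_tissue = None
        if label == "TS":
            ts_tissue = tissues[ts_pc_counter % cfg.n_tissues]
            ts_pc_counter += 1
        pc_plans[pid] = _GenePlan(
            gene_id=pid, biotype="protein_coding", label=label, chrom=plans[host].chrom,
            strand="+" if rng.random() < 0.5 else "-",
            ts_tissue=ts_tissue, essential=essential,
        )
        host_lnc[pid] = host

    # ----------------------------------------------------------- structures
    order_gt: list[_GenePlan] = []
    for gid in lnc_ids:
        g = plans[gid]
        median = cfg.ue_genomic_median if g.label == "UE" else cfg.ts_genomic_median
        max_ex = cfg.ue_max_exons if g.label == "UE" else cfg.ts_max_exons
        n_tx_max = 2 if g.label == "UE" else 3
        g.transcripts, g.end = _gene_structure(
            rng, gid, g.start, g.strand, median, cfg.genomic_sdlog, max_ex, n_tx_max
        )
        order_gt.append(g)
    for pid in pc_ids:
        p = pc_plans[pid]
        host = plans[host_lnc[pid]]
        if host.essential_planted and p.essential:
            gap = int(rng.integers(2_000, 40_000))
        elif host.neighbor_planted and pid in pc_ids[: len(planted_hosts)]:
            gap = int(rng.integers(2_000, 90_000))
        else:
            gap = int(rng.integers(110_000, 140_000))
        p.start = host.end + gap
        p.transcripts, p.end = _gene_structure(
            rng, pid, p.start, p.strand, cfg.pc_genomic_median, cfg.genomic_sdlog, 8, 3
        )
        order_gt.append(p)

    # a few extra distant essential pc genes (far from every lncRNA)
    far_other = [p for p in pc_ids if pc_plans[p].label == "other"][:30]
    for pid in far_other:
        pc_plans[pid].essential = True

    # redundant cross-source duplicates of random lncRNA loci
    dup_plans: list[_GenePlan] = []
    dup_sources: dict[str, str] = {}
    dup_of: dict[str, str] = {}
    if cfg.n_redundant_duplicates:
        targets = rng.choice(lnc_ids, size=min(cfg.n_redundant_duplicates, cfg.n_lnc), replace=False)
        for i, tgt in enumerate(targets):
            g = plans[tgt]
            shift = max(1, (g.end - g.start) // 20)  # ~5% shift keeps overlap > 0.8
            did = f"DUP{i + 1:04d}"
            dup = _GenePlan(
                gene_id=did, biotype="lncRNA", label="duplicate", chrom=g.chrom,
                start=g.start + shift, strand=g.strand,
            )
            dup.transcripts = [
                (f"{did}.t1", [(s + shift, e + shift) for s, e in g.transcripts[0][1]])
            ]
            dup.end = dup.transcripts[0][1][-1][1]
            dup_plans.append(dup)
            dup_sources[did] = "Ensembl"
            dup_of[did] = tgt

    all_plans = order_gt + dup_plans
    _write_gtf(out / "genes.gtf", all_plans, dup_sources)

    chrom_sizes = {}
    for g in all_plans:
        chrom_sizes[g.chrom] = max(chrom_sizes.get(g.chrom, 0), g.end + 200_000)
    with open(out / "chrom.sizes.tsv", "w") as fh:
        for c in sorted(chrom_sizes):
            fh.write(f"{c}\t{chrom_sizes[c]}\n")

    # ------------------------------------------------------------ cytobands
    band_rows = []
    band_span = cfg.territories_per_band * cfg.territory
    for c in sorted(chrom_sizes):
        size = chrom_sizes[c]
        for bi, bstart in enumerate(range(0, size, band_span)):
            band_rows.append((c, bstart, min(bstart + band_span, size), f"q{bi + 11}"))
    pd.DataFrame(band_rows, columns=["chrom", "start", "end", "band"]).to_csv(
        out / "cytobands.tsv", sep="\t", index=False
    )

    # ----------------------------------------------------------- expression
    n_samples = rng.integers(1, cfg.max_samples_per_tissue + 1, size=cfg.n_tissues)
    sample_names, sample_tissue = [], []
    for t, ns in zip(tissues, n_samples):
        for k in range(int(ns)):
            sample_names.append(f"S_{t}_{k + 1}")
            sample_tissue.append(t)
    pd.DataFrame({"sample": sample_names, "tissue": sample_tissue}).to_csv(
        out / "sample_map.tsv", sep="\t", index=False
    )

    tindex = {t: i for i, t in enumerate(tissues)}
    rows, row_ids = [], []
    shared_noise: dict[str, np.ndarray] = {}
    for g in order_gt:
        ts_idx = tindex[g.ts_tissue] if g.ts_tissue else None
        shared = None
        if g.biotype == "protein_coding" and host_lnc.get(g.gene_id) in shared_noise and g.label == "UE":
            host = host_lnc[g.gene_id]
            if plans[host].neighbor_planted:
                shared = shared_noise[host]
        for tx_id, _ex in g.transcripts:
            prof, noise = _tissue_profile(
                rng, cfg, g.label, ts_idx, shared_log_noise=shared,
                pc=g.biotype == "protein_coding",
            )
            if g.biotype == "lncRNA" and g.label == "UE" and noise is not None:
                shared_noise.setdefault(g.gene_id, noise)
            sample_vals = np.empty(len(sample_names))
            pos = 0
            for ti, ns in enumerate(n_samples):
                v = prof[ti]
                sample_vals[pos] = v  # first sample carries the tissue maximum
                for k in range(1, int(ns)):
                    sample_vals[pos + k] = v * rng.uniform(0.4, 0.95)
                pos += int(ns)
            rows.append(sample_vals)
            row_ids.append(tx_id)
    sample_matrix = pd.DataFrame(np.vstack(rows), index=row_ids, columns=sample_names)
    sample_matrix.index.name = "feature_id"
    sample_matrix.to_csv(out / "samples.fpkm.tsv", sep="\t", float_format="%.6g")

    bg = rng.exponential(cfg.background_mean, size=cfg.n_background)
    pd.DataFrame(
        {"region_id": [f"BG{i + 1:05d}" for i in range(cfg.n_background)], "fpkm": bg}
    ).to_csv(out / "background.fpkm.tsv", sep="\t", index=False, float_format="%.6g")

    # --------------------------------------------------------- conservation
    cons_mean = {"UE": cfg.cons_ue, "TS": cfg.cons_ts, "other": cfg.cons_other}
    with open(out / "conservation.bedGraph", "w") as fh:
        for gid in lnc_ids:
            g = plans[gid]
            mean = cons_mean[g.label]
            prom_lo, prom_hi = max(0, g.tss - 2000), g.tss + 2000
            regions = [(prom_lo, prom_hi)]
            for s, e in g.transcripts[0][1]:
                regions.append((s, e))
            for lo, hi in regions:
                for seg in range(lo, hi, cfg.cons_segment):
                    seg_hi = min(seg + cfg.cons_segment, hi)
                    v = float(np.clip(rng.normal(mean, cfg.cons_sd), 0.0, 1.0))
                    fh.write(f"{g.chrom}\t{seg}\t{seg_hi}\t{v:.4f}\n")

    # ------------------------------------------------------------ CGI / enhancers
    cgi_rows, enh_rows = [], []
    # CGIs at exactly the configured fraction of UE promoters; background rate
    # elsewhere is an independent coin flip per gene
    cgi_ue = set(rng.choice(ue_lnc, size=round(cfg.cgi_fraction_ue * len(ue_lnc)), replace=False))
    for gid in lnc_ids:
        g = plans[gid]
        planted_cgi = gid in cgi_ue if g.label == "UE" else rng.random() < cfg.cgi_fraction_other
        if planted_cgi:
            g.cgi_planted = True
            length = int(rng.integers(300, 800))
            offset = int(rng.integers(-1500, 1500 - length))
            lo = max(0, g.tss + offset)
            cgi_rows.append((g.chrom, lo, lo + length))
        prob = {"UE": cfg.enhancer_prob_ue, "TS": cfg.enhancer_prob_ts, "other": cfg.enhancer_prob_other}
        if rng.random() < prob[g.label]:
            length = int(rng.integers(200, 1000))
            gap = int(rng.integers(500, 9000))
            lo = max(0, g.start - gap - length) if rng.random() < 0.5 else g.end + gap
            if g.label == "UE":
                n_cells = int(rng.integers(3, cfg.n_cell_lines + 1))
            elif g.label == "TS":
                n_cells = int(rng.integers(1, 3))
            else:
                n_cells = int(rng.integers(1, cfg.n_cell_lines + 1))
            cells = sorted(rng.choice(cell_lines, size=n_cells, replace=False))
            strength = "strong" if rng.random() < 0.5 else "weak"
            g.enhancer_label = "UE" if n_cells > 2 else "TS"
            enh_rows.append((g.chrom, lo, lo + length, ",".join(cells), strength))
    with open(out / "cgi.bed", "w") as fh:
        for c, s, e in sorted(cgi_rows):
            fh.write(f"{c}\t{s}\t{e}\n")
    with open(out / "enhancers.bed", "w") as fh:
        for c, s, e, cells, strength in sorted(enh_rows):
            fh.write(f"{c}\t{s}\t{e}\t{cells}\t{strength}\n")

    # -------------------------------------------------------------- marks
    # Two-block signatures per tissue: block 0 is high in the first three
    # active marks and low in the last three; block 1 is the mirror image.
    sep = cfg.mark_high - cfg.mark_low
    noise_sd = cfg.mark_noise_frac * sep
    cluster_counter: dict[str, int] = {t: 0 for t in tissues}
    ts_genes = [g for g in order_gt if g.label == "TS"]
    for g in ts_genes:
        g.cluster_id = cluster_counter[g.ts_tissue] % cfg.n_clusters_per_tissue
        cluster_counter[g.ts_tissue] += 1
    mark_files: dict[tuple[str, str], list[str]] = {}
    for g in ts_genes:
        cell = tissue_cell_line[g.ts_tissue]
        prom_lo = max(0, g.tss - 2000)
        for mi, mark in enumerate(MARKS):
            high_block = mi < 3
            level = cfg.mark_high if (g.cluster_id == 0) == high_block else cfg.mark_low
            bins = np.maximum(np.rint(rng.normal(level, noise_sd, size=40)), 0).astype(int)
            lines = mark_files.setdefault((cell, mark), [])
            for b, v in enumerate(bins):
                lines.append(f"{g.chrom}\t{prom_lo + b * 100}\t{prom_lo + (b + 1) * 100}\t{v}")
    # reference cell line carrying marks over every lncRNA promoter
    ref_level = {"UE": 8, "TS": 1, "other": 3}
    for gid in lnc_ids:
        g = plans[gid]
        prom_lo = max(0, g.tss - 2000)
        for mark in MARKS:
            lines = mark_files.setdefault(("CL_REF", mark), [])
            vals = np.maximum(
                np.rint(rng.normal(ref_level[g.label], 0.5, size=4)), 0
            ).astype(int)
            for s4, v in enumerate(vals):
                lines.append(f"{g.chrom}\t{prom_lo + s4 * 1000}\t{prom_lo + (s4 + 1) * 1000}\t{v}")
    for (cell, mark), lines in sorted(mark_files.items()):
        with open(out / "marks" / f"{cell}.{mark}.bedGraph", "w") as fh:
            fh.write("\n".join(lines) + "\n")

    # ---------------------------------------------------------- regulators
    tf_pool = [f"TF{i + 1:03d}" for i in range(120)]
    mir_pool = [f"MIR{i + 1:03d}" for i in range(300)]
    reg_rows = []
    lam_tf = {"UE": 20, "TS": 3, "other": 8}
    lam_mir = {"UE": 10, "TS": 2, "other": 5}
    for gid in lnc_ids:
        g = plans[gid]
        n_tf = min(int(rng.poisson(lam_tf[g.label])), len(tf_pool))
        n_mir = min(int(rng.poisson(lam_mir[g.label])), len(mir_pool))
        for r in rng.choice(tf_pool, size=n_tf, replace=False):
            reg_rows.append((r, gid, "TF"))
        for r in rng.choice(mir_pool, size=n_mir, replace=False):
            reg_rows.append((r, gid, "miRNA"))
    pd.DataFrame(reg_rows, columns=["regulator_id", "target_id", "regulator_type"]).to_csv(
        out / "regulators.tsv", sep="\t", index=False
    )

    essential_ids = sorted(p for p in pc_ids if pc_plans[p].essential)
    pd.DataFrame({"gene_id": essential_ids}).to_csv(
        out / "essential_genes.tsv", sep="\t", index=False
    )

    # ------------------------------------------------------------------ GO
    go_rows = []
    hk_terms = [(f"GO:HK{i + 1:03d}", f"housekeeping process {i + 1}") for i in range(5)]
    ue_pc = [p for p in pc_ids if pc_plans[p].label == "UE"]
    for term, name in hk_terms:
        for p in ue_pc:
            if rng.random() < 0.4:
                go_rows.append((p, term, name))
    for t in tissues:
        for c in range(cfg.n_clusters_per_tissue):
            members = [
                p for p in pc_ids
                if pc_plans[p].label == "TS" and pc_plans[p].ts_tissue == t
                and pc_plans[p].cluster_id == c
            ]
            term = f"GO:TS_{t}_c{c}"
            for p in members:
                go_rows.append((p, term, f"{t} specific process {c}"))
    for i in range(20):
        term, name = f"GO:BG{i + 1:03d}", f"background process {i + 1}"
        for p in pc_ids:
            if rng.random() < 0.05:
                go_rows.append((p, term, name))
    pd.DataFrame(go_rows, columns=["gene_id", "term_id", "term_name"]).to_csv(
        out / "go_annotation.tsv", sep="\t", index=False
    )

    # ---------------------------------------------------------- ground truth
    gt_rows = []
    for g in order_gt:
        gt_rows.append(
            {
                "gene_id": g.gene_id,
                "biotype": g.biotype,
                "label": g.label,
                "ts_tissue": g.ts_tissue or "",
                "cluster_id": "" if g.cluster_id is None else g.cluster_id,
                "neighbor_planted": int(g.neighbor_planted),
                "essential_within_50kb": int(g.essential_planted),
                "cgi_planted": int(g.cgi_planted),
                "enhancer_label": g.enhancer_label,
                "essential": int(g.essential),
                "duplicate_of": "",
            }
        )
    for d in dup_plans:
        gt_rows.append(
            {
                "gene_id": d.gene_id, "biotype": d.biotype, "label": "duplicate",
                "ts_tissue": "", "cluster_id": "", "neighbor_planted": 0,
                "essential_within_50kb": 0, "cgi_planted": 0, "enhancer_label": "",
                "essential": 0, "duplicate_of": dup_of[d.gene_id],
            }
        )
    pd.DataFrame(gt_rows).to_csv(out / "ground_truth.tsv", sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "tissues": tissues,
        "cell_lines": cell_lines,
        "tissue_cell_line": tissue_cell_line,
        "marks": list(MARKS),
        "files": {
            "gtf": "genes.gtf",
            "samples": "samples.fpkm.tsv",
            "sample_map": "sample_map.tsv",
            "background": "background.fpkm.tsv",
            "conservation": "conservation.bedGraph",
            "cgi": "cgi.bed",
            "enhancers": "enhancers.bed",
            "marks_dir": "marks",
            "regulators": "regulators.tsv",
            "essential": "essential_genes.tsv",
            "go": "go_annotation.tsv",
            "cytobands": "cytobands.tsv",
            "chrom_sizes": "chrom.sizes.tsv",
            "ground_truth": "ground_truth.tsv",
        },
        "config": asdict(cfg),
    }
    with open(out / "dataset.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


@dataclass
class MicroExample:
    """Hand-checkable fixture: 3 tissues, a handful of genes, frozen oracles."""

    matrix: pd.DataFrame
    threshold: float
    expected: dict


def worked_micro_example() -> MicroExample:
    """Tiny fixed dataset whose intermediate values were computed by hand.

    Frozen values: sample-sd CV of (5, 6, 5) = (sqrt(1/3) / (16/3)) = 0.108253;
    JS specificity of a point profile is exactly 1; of (1, 1, 0) it is
    1 - sqrt(H(3/4, 1/4, 0) - 1/2) = 0.442077 with base-2 entropies; the
    hypergeometric upper tail for overlap 4 of a size-4 term, size-5 query,
    size-10 universe is C(4,4) * C(6,1) / C(10,5) = 6/252 = 0.0238095.
    """
    matrix = pd.DataFrame(
        {
            "T1": [5.0, 0.0, 1.0, 0.10, 0.5],
            "T2": [6.0, 0.0, 1.0, 0.10, 9.0],
            "T3": [5.0, 9.0, 0.0, 0.10, 0.5],
        },
        index=["UE_1", "TS_1", "OTH_1", "OTH_2", "UE_2"],
    )
    expected = {
        "threshold": 0.14,
        "labels": {"UE_1": "UE", "TS_1": "TS", "OTH_1": "other", "OTH_2": "other", "UE_2": "other"},
        "cv": {"UE_1": 0.10825317547305482, "UE_2": 1.4722431864335457},
        "widths": {"UE_1": 3, "TS_1": 1, "OTH_1": 2, "OTH_2": 0, "UE_2": 3},
        "js": {"TS_1": 1.0, "OTH_1": 0.4420769547158562},
        "ts_tissue": {"TS_1": "T3"},
        "hypergeom_example": {
            "universe": 10, "term": 4, "set": 5, "overlap": 4, "p_raw": 6 / 252,
        },
    }
    return MicroExample(matrix=matrix, threshold=0.14, expected=expected)
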