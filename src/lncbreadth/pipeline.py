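"""End-to-end orchestration over a dataset bundle.

Stages: annotation -> expression -> classification -> feature
characterization -> epigenome -> function prediction. Every stage is a pure
function of its declared inputs; the run manifest (config echo plus stage
counts) is deterministic, so reruns on the same bundle produce byte-identical
outputs. Timing information goes to stderr logging only.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import classify as cls
from . import epigenome as epi
from . import expression as expr
from . import features as feat
from . import function_prediction as fp
from .intervals import GenomicInterval, IntervalIndex, promoter
from .stats import hypergeom_upper_tail

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    bundle_dir: str
    out_dir: str
    thresholds: dict | str = "estimate"  # biotype -> FPKM, or "estimate"
    cv_max: float = 1.0
    ts_min: float = 0.4
    promoter_up: int = 2000
    promoter_down: int = 2000
    tf_upstream: int = 5000
    tf_downstream: int = 1000
    enhancer_window: int = 10_000
    essential_window: int = 50_000
    neighbor_windows: tuple = (5_000, 10_000, 25_000, 50_000, 100_000)
    neighbor_enrichment_window: int = 100_000
    enhancer_rule: str = ">2"  # or ">=2"
    enrichment_p_max: float = 0.1
    enrichment_min_overlap: int = 2
    n_perm: int = 1000
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "promoter_up", "promoter_down", "tf_upstream", "tf_downstream",
            "enhancer_window", "essential_window", "neighbor_enrichment_window",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if isinstance(self.thresholds, dict):
            for b, t in self.thresholds.items():
                if t <= 0:
                    raise ValueError(f"fixed threshold for {b} must be > 0")


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _bundle_paths(bundle: Path) -> dict:
    ds = bundle / "dataset.json"
    if not ds.exists():
        raise FileNotFoundError(f"bundle manifest not found: {ds}")
    manifest = json.loads(ds.read_text())
    files = {k: bundle / v for k, v in manifest["files"].items()}
    return {"manifest": manifest, "files": files}


def run(config: PipelineConfig) -> dict:
    """Execute the whole analysis; returns the run manifest dict."""
    config.validate()
    bundle = Path(config.bundle_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    info = _bundle_paths(bundle)
    files = info["files"]
    tissue_cell_line = info["manifest"].get("tissue_cell_line", {})
    marks = info["manifest"].get("marks", list(fp.ACTIVE_MARKS))
    counts: dict[str, object] = {}
    t0 = time.perf_counter()

    # ------------------------------------------------------------ annotation
    try:
        models = ann.load_gene_models(files["gtf"])
        retained, redundancy = ann.build_nonredundant_set(models)
        bands = pd.read_csv(files["cytobands"], sep="\t")
        ann.assign_bands(retained, bands)
    except Exception as e:
        raise StageError("annotation", f"{e} (input {files['gtf']})") from e
    ann.write_loci_bed(retained, out / "genes.nonredundant.bed")
    redundancy.to_csv(out / "redundancy_log.tsv", sep="\t", index=False, float_format="%.4f")
    genes = {m.gene_id: m for m in retained}
    lnc_genes = {g: m for g, m in genes.items() if m.biotype == "lncRNA"}
    pc_genes = {g: m for g, m in genes.items() if m.biotype == "protein_coding"}
    counts["annotation"] = {
        "input_models": len(models), "retained": len(retained),
        "removed_redundant": int(len(redundancy)),
        "lncRNA": len(lnc_genes), "protein_coding": len(pc_genes),
    }
    log.info("annotation done (%.1fs)", time.perf_counter() - t0)

    # ------------------------------------------------------------ expression
    try:
        samples = pd.read_csv(files["samples"], sep="\t", index_col=0)
        sample_map = expr.read_sample_map(files["sample_map"])
        matrix = expr.aggregate_to_tissues(samples, sample_map)
        background = pd.read_csv(files["background"], sep="\t")["fpkm"].to_numpy()
    except Exception as e:
        raise StageError("expression", str(e)) from e

    tx_gene = {t.transcript_id: m.gene_id for m in retained for t in m.transcripts}
    tx_biotype = {t.transcript_id: m.biotype for m in retained for t in m.transcripts}
    keep = [f for f in matrix.feature_ids if f in tx_gene]
    matrix = expr.ExpressionMatrix(matrix.values.loc[keep], level="transcript")

    thresholds: dict[str, float] = {}
    threshold_reports = {}
    if config.thresholds == "estimate":
        # each annotated feature is transcribed in the tissue where it peaks,
        # so per-feature maxima sample the transcribed-region distribution
        row_max = matrix.values.max(axis=1)
        for biotype in sorted({tx_biotype[f] for f in matrix.feature_ids}):
            vals = row_max[[f for f in matrix.feature_ids if tx_biotype[f] == biotype]]
            det = expr.estimate_detection_threshold(vals.to_numpy(), background, biotype)
            thresholds[biotype] = det.threshold
            threshold_reports[biotype] = asdict(det)
    else:
        thresholds = dict(config.thresholds)
        threshold_reports = {b: {"biotype": b, "threshold": t, "grid": "fixed"} for b, t in thresholds.items()}
    matrix.write_tsv(out / "tissue_matrix.tsv")
    (out / "thresholds.json").write_text(json.dumps(threshold_reports, indent=2, sort_keys=True))
    counts["expression"] = {
        "features": len(matrix.feature_ids), "tissues": len(matrix.tissue_ids),
        "thresholds": {b: round(t, 6) for b, t in thresholds.items()},
    }

    # ---------------------------------------------------------- classification
    try:
        tx_results, gene_results = cls.classify_matrix(
            matrix, thresholds, tx_biotype, tx_gene, cv_max=config.cv_max, ts_min=config.ts_min
        )
    except Exception as e:
        raise StageError("classify", str(e)) from e
    cls.write_results_tsv(tx_results, out / "classification.transcripts.tsv")
    cls.write_results_tsv(gene_results, out / "classification.genes.tsv")
    gene_label = {r.feature_id: r.label for r in gene_results}
    gene_ts_tissue = {r.feature_id: r.ts_tissue for r in gene_results if r.label == "TS"}

    def members(biotype: str, label: str) -> list[str]:
        pool = lnc_genes if biotype == "lncRNA" else pc_genes
        return sorted(g for g in pool if gene_label.get(g) == label)

    ue_lnc, ts_lnc = members("lncRNA", "UE"), members("lncRNA", "TS")
    oth_lnc = sorted(g for g in lnc_genes if gene_label.get(g) == "other")
    ue_pc, ts_pc = members("protein_coding", "UE"), members("protein_coding", "TS")
    counts["classify"] = {
        "UE_lncRNA": len(ue_lnc), "TS_lncRNA": len(ts_lnc), "other_lncRNA": len(oth_lnc),
        "UE_pc": len(ue_pc), "TS_pc": len(ts_pc),
        "gene_conflicts": int(sum(r.conflict for r in gene_results)),
    }
    log.info("classification done (%.1fs)", time.perf_counter() - t0)

    # -------------------------------------------------------------- features
    try:
        cons = feat.GenomeTrack.from_bedgraph(files["conservation"])
        cgi_index = IntervalIndex((iv, None) for iv in feat.read_bed_intervals(files["cgi"]))
        regulators = feat.read_regulator_table(files["regulators"])
    except Exception as e:
        raise StageError("features", str(e)) from e

    def lnc_promoter(gid: str) -> GenomicInterval:
        m = lnc_genes[gid]
        return promoter(m.tss, m.locus.chrom, m.locus.strand, config.promoter_up, config.promoter_down)

    feat_rows = []
    for gid in sorted(lnc_genes):
        m = lnc_genes[gid]
        prom = lnc_promoter(gid)
        feat_rows.append(
            {
                "gene_id": gid,
                "label": gene_label.get(gid, "other"),
                "exon_conservation": feat.mean_conservation_regions(m.union_exons(), cons),
                "promoter_conservation": feat.mean_conservation(prom, cons),
                "cgi_overlap": int(feat.cgi_overlap(prom, cgi_index)),
            }
        )
    feat_table = pd.DataFrame(feat_rows).set_index("gene_id")
    reg_counts = feat.count_regulators_all(sorted(lnc_genes), regulators)
    feat_table = feat_table.join(reg_counts)
    struct = feat.structure_stats(lnc_genes.values())
    feat_table = feat_table.join(struct)
    feat_table.to_csv(out / "features.tsv", sep="\t", float_format="%.6g")

    group_stats = {}
    if ue_lnc and ts_lnc:
        comp = feat.compare_structure(struct.loc[ue_lnc], struct.loc[ts_lnc])
        group_stats["structure_UE_vs_TS"] = json.loads(comp.to_json(orient="index"))
    n_cgi_ue = int(feat_table.loc[ue_lnc, "cgi_overlap"].sum()) if ue_lnc else 0
    group_stats["cgi"] = {
        "ue_fraction": n_cgi_ue / len(ue_lnc) if ue_lnc else float("nan"),
        "all_fraction": float(feat_table["cgi_overlap"].mean()),
        "hypergeom_p": hypergeom_upper_tail(
            n_cgi_ue, len(lnc_genes), int(feat_table["cgi_overlap"].sum()), len(ue_lnc)
        ) if ue_lnc else float("nan"),
    }
    (out / "group_stats.json").write_text(json.dumps(group_stats, indent=2, sort_keys=True))
    counts["features"] = {"genes": len(feat_table), "cgi_fraction_UE": round(group_stats["cgi"]["ue_fraction"], 4)}

    # -------------------------------------------------------------- epigenome
    try:
        enhancers = epi.classify_enhancers(epi.read_enhancer_bed(files["enhancers"]), rule=config.enhancer_rule)
        essential_ids = set(pd.read_csv(files["essential"], sep="\t")["gene_id"])
    except Exception as e:
        raise StageError("epigenome", str(e)) from e
    essential_loci = [pc_genes[g].locus for g in sorted(essential_ids) if g in pc_genes]
    epig = {}
    per_feature = {}
    for name, subset in (("UE", ue_lnc), ("TS", ts_lnc)):
        if not subset:
            continue
        loci = {g: lnc_genes[g].locus for g in subset}
        frac_enh, enh_flags = epi.proximity_fraction(
            loci, [e.interval for e in enhancers], config.enhancer_window
        )
        frac_ess, ess_flags = epi.proximity_fraction(loci, essential_loci, config.essential_window)
        ue_only = [e.interval for e in enhancers if e.ubiquity_label == name]
        frac_same, _ = epi.proximity_fraction(loci, ue_only, config.enhancer_window)
        epig[name] = {
            "enhancer_fraction": frac_enh,
            "essential_fraction": frac_ess,
            "same_class_enhancer_fraction": frac_same,
        }
        per_feature[name] = pd.DataFrame({"enhancer": enh_flags, "essential": ess_flags})
    if per_feature:
        pd.concat(per_feature, names=["category", "gene_id"]).to_csv(
            out / "proximity.tsv", sep="\t"
        )
    (out / "epigenome.json").write_text(json.dumps(epig, indent=2, sort_keys=True))
    counts["epigenome"] = {
        "enhancers": len(enhancers),
        "UE_enhancers": sum(e.ubiquity_label == "UE" for e in enhancers),
        **{f"{k}_essential_fraction": round(v["essential_fraction"], 4) for k, v in epig.items()},
    }
    log.info("epigenome done (%.1fs)", time.perf_counter() - t0)

    # ------------------------------------------------------ function prediction
    try:
        go_ann = pd.read_csv(files["go"], sep="\t")
    except Exception as e:
        raise StageError("function_prediction", f"GO annotation unreadable: {e} ({files['go']})") from e
    universe = sorted(pc_genes)
    rng = np.random.default_rng(config.seed)
    func: dict[str, object] = {}

    if ue_lnc:
        lnc_loci = {g: lnc_genes[g].locus for g in ue_lnc}
        ue_pc_loci = {g: pc_genes[g].locus for g in ue_pc}
        assignments = fp.neighbors_within(lnc_loci, ue_pc_loci, config.neighbor_windows)
        func["ue_neighbor_fractions"] = {
            str(w): fp.neighbor_fraction(assignments, w) for w in config.neighbor_windows
        }
        # co-expression of each UE lncRNA with its nearest UE pc neighbor
        gene_matrix = matrix.values.groupby(pd.Series(tx_gene).reindex(matrix.feature_ids)).max()
        pairs = [(a.lncRNA_id, a.nearest_gene_id) for a in assignments if a.nearest_gene_id]
        obs = np.array(
            [
                fp.coexpression(gene_matrix.loc[l], gene_matrix.loc[[p]]).iloc[0]
                for l, p in pairs
            ]
        )
        background_ids = [g for g in universe if g not in {p for _l, p in pairs}]
        p_rand, null = fp.randomization_test(
            obs,
            gene_matrix.loc[[l for l, _p in pairs]],
            gene_matrix.loc[background_ids],
            n_perm=config.n_perm,
            seed=rng,
        )
        func["ue_coexpression"] = {
            "n_pairs": len(pairs),
            "observed_mean": float(np.nanmean(obs)),
            "null_mean": float(null.mean()),
            "randomization_p": p_rand,
        }
        neighbor_sets = sorted(
            {p for a in assignments for p in a.neighbors.get(config.neighbor_enrichment_window, [])}
        )
        ue_terms = fp.go_enrichment(
            neighbor_sets, go_ann, universe,
            p_max=config.enrichment_p_max, min_overlap=config.enrichment_min_overlap,
        )
        pd.DataFrame(
            [
                {
                    "term_id": t.term_id, "term_name": t.term_name,
                    "overlap": t.overlap_count, "p_raw": t.p_raw, "p_adjusted": t.p_adjusted,
                    "evidence": "neighbor",
                }
                for t in ue_terms
            ]
        ).to_csv(out / "ue_go_enrichment.tsv", sep="\t", index=False, float_format="%.4g")
        func["ue_enriched_terms"] = len(ue_terms)

    band_tbl = fp.band_enrichment(
        ue_lnc,
        {g: m.band for g, m in lnc_genes.items()},
        {g: m.locus.chrom for g, m in lnc_genes.items()},
    )
    band_tbl.to_csv(out / "band_enrichment.ue.tsv", sep="\t", index=False, float_format="%.4g")

    # TS lncRNAs: co-modification clustering per tissue
    predictions = []
    cluster_report = {}
    marks_dir = files["marks_dir"]
    for tissue in sorted({t for t in gene_ts_tissue.values() if t}):
        cell = tissue_cell_line.get(tissue)
        if cell is None:
            continue
        t_lnc = [g for g in ts_lnc if gene_ts_tissue.get(g) == tissue]
        t_pc = [g for g in ts_pc if gene_ts_tissue.get(g) == tissue]
        gene_ids = t_lnc + t_pc
        if len(gene_ids) < 3:
            continue
        tracks = {}
        missing = False
        for mark in marks:
            path = Path(marks_dir) / f"{cell}.{mark}.bedGraph"
            if not path.exists():
                missing = True
                break
            tracks[mark] = feat.GenomeTrack.from_bedgraph(path, fill=0.0)
        if missing:
            continue
        profiles = {}
        for gid in gene_ids:
            m = genes[gid]
            prom = promoter(m.tss, m.locus.chrom, m.locus.strand, config.promoter_up, config.promoter_down)
            profiles[gid] = {
                mark: epi.bin_promoter_signal(prom, tracks[mark], feature_id=gid, mark=mark, cell_line=cell).bins
                for mark in marks
            }
        clusters = fp.predict_ts_function(
            tissue, t_lnc, t_pc, profiles, go_ann, universe, marks=marks,
            p_max=config.enrichment_p_max, min_overlap=config.enrichment_min_overlap,
        )
        predictions.append(fp.predictions_frame(clusters, t_lnc))
        cluster_report[tissue] = [
            {
                "cluster_id": c.cluster_id,
                "n_members": len(c.member_ids),
                "n_lncRNA": sum(g in set(t_lnc) for g in c.member_ids),
                "terms": [t.term_id for t in c.enriched_terms],
            }
            for c in clusters
        ]
    predictions = [p for p in predictions if len(p)]
    pred_df = (
        pd.concat(predictions, ignore_index=True)
        if predictions
        else fp.predictions_frame([], [])
    )
    pred_df.to_csv(out / "ts_predictions.tsv", sep="\t", index=False, float_format="%.4g")
    (out / "ts_clusters.json").write_text(json.dumps(cluster_report, indent=2, sort_keys=True))
    func["ts_predicted_lncRNAs"] = int(pred_df["lncRNA_id"].nunique()) if len(pred_df) else 0
    counts["function_prediction"] = func
    log.info("function prediction done (%.1fs)", time.perf_counter() - t0)

    # the output directory is where the manifest itself lives; echoing it would
    # make otherwise-identical runs differ byte-wise
    config_echo = {k: v for k, v in asdict(config).items() if k != "out_dir"}
    manifest = {"config": config_echo, "counts": counts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
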