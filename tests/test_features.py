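import math

import numpy as np
import pandas as pd
import pytest

from lncbreadth.annotation import GeneModel, TranscriptModel
from lncbreadth.features import (
    GenomeTrack,
    CpGClassParams,
    categorize_promoter_cpg,
    compare_structure,
    count_regulators,
    count_regulators_all,
    mean_conservation,
    mean_conservation_regions,
    structure_stats,
    tf_edges_from_binding_sites,
)
from lncbreadth.intervals import GenomicInterval, IntervalIndex


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


def gene(gene_id, exon_coords, strand="+", chrom="chr1", biotype="lncRNA"):
    tx = TranscriptModel(
        f"{gene_id}.t1", gene_id, [GenomicInterval(chrom, s, e, strand) for s, e in exon_coords]
    )
    return GeneModel(gene_id, biotype, "GENCODE", [tx])


class TestMeanConservation:
    def test_constant_track(self):
        track = GenomeTrack.from_arrays({"chr1": np.full(200, 0.5)})
        assert mean_conservation(iv(50, 150), track) == pytest.approx(0.5)

    def test_half_high_half_low(self):
        arr = np.zeros(100)
        arr[:50] = 1.0
        track = GenomeTrack.from_arrays({"chr1": arr})
        assert mean_conservation(iv(0, 100), track) == pytest.approx(0.5)

    def test_random_track_matches_position_loop(self):
        rng = np.random.default_rng(5)
        arr = rng.uniform(0, 1, 64)
        track = GenomeTrack.from_arrays({"chr1": arr})
        region = iv(20, 30)
        oracle = sum(arr[i] for i in range(20, 30)) / 10
        assert mean_conservation(region, track) == pytest.approx(oracle, abs=1e-12)

    def test_missing_positions_excluded(self):
        track = GenomeTrack({"chr1": (np.array([10]), np.array([20]), np.array([0.8]))})
        # region half covered: mean over covered positions only
        assert mean_conservation(iv(0, 20), track) == pytest.approx(0.8)
        assert math.isnan(mean_conservation(iv(100, 120), track))

    def test_length_weighted_over_subregions(self):
        rng = np.random.default_rng(6)
        arr = rng.uniform(0, 1, 300)
        track = GenomeTrack.from_arrays({"chr1": arr})
        whole = mean_conservation(iv(0, 300), track)
        parts = [iv(0, 100), iv(100, 250), iv(250, 300)]
        weighted = sum(mean_conservation(p, track) * p.length for p in parts) / 300
        assert whole == pytest.approx(weighted, abs=1e-12)
        assert mean_conservation_regions(parts, track) == pytest.approx(whole, abs=1e-12)


class TestStructureStats:
    def test_single_exon_gene_has_no_introns(self):
        t = structure_stats([gene("g", [(0, 400)])])
        assert t.loc["g", "intronic_length"] == 0
        assert t.loc["g", "genomic_length"] == 400

    def test_two_exon_gene(self):
        t = structure_stats([gene("g", [(0, 100), (200, 300)])])
        assert t.loc["g", "intronic_length"] == 100
        assert t.loc["g", "genomic_length"] == 300
        assert t.loc["g", "exon_count"] == 2

    def test_planted_length_difference_detected(self, default_bundle):
        from lncbreadth.annotation import load_gene_models

        gt = pd.read_csv(default_bundle / "ground_truth.tsv", sep="\t")
        models = {m.gene_id: m for m in load_gene_models(default_bundle / "genes.gtf")}
        ue = gt[(gt.biotype == "lncRNA") & (gt.label == "UE")]["gene_id"]
        ts = gt[(gt.biotype == "lncRNA") & (gt.label == "TS")]["gene_id"]
        stats_ue = structure_stats([models[g] for g in ue])
        stats_ts = structure_stats([models[g] for g in ts])
        comp = compare_structure(stats_ue, stats_ts)
        assert comp.loc["genomic_length", "median_a"] < comp.loc["genomic_length", "median_b"]
        assert comp.loc["genomic_length", "wilcoxon_p"] < 0.01


class TestRegulators:
    table = pd.DataFrame(
        {
            "regulator_id": ["TF_A", "TF_A", "miR_1"],
            "target_id": ["g", "g", "g"],
            "regulator_type": ["TF", "TF", "miRNA"],
        }
    )

    def test_absent_feature_is_zero(self):
        assert count_regulators("absent", self.table) == (0, 0)

    def test_duplicate_edges_deduplicated(self):
        assert count_regulators("g", self.table) == (1, 1)

    def test_bulk_counts_sum_over_types(self):
        out = count_regulators_all(["g", "absent"], self.table)
        assert out.loc["g", "tf_count"] + out.loc["g", "mirna_count"] == 2
        assert out.loc["absent"].sum() == 0

    def test_tss_window_five_kb_up_one_kb_down(self):
        g = gene("g", [(100_000, 101_000)], strand="+")
        sites = pd.DataFrame(
            {
                "tf_id": ["near_up", "far_up", "near_down", "far_down"],
                "chrom": ["chr1"] * 4,
                "start": [100_000 - 4_900, 100_000 - 5_150, 100_500, 101_200],
                "end": [100_000 - 4_850, 100_000 - 5_100, 100_550, 101_250],
            }
        )
        edges = tf_edges_from_binding_sites(sites, [g])
        tfs = set(edges["regulator_id"])
        assert "near_up" in tfs and "near_down" in tfs
        assert "far_up" not in tfs  # 5,100 nt upstream: outside the 5 kb window
        assert "far_down" not in tfs  # 1,200 nt downstream: outside the 1 kb window

    def test_tss_window_is_strand_aware(self):
        g = gene("g", [(100_000, 101_000)], strand="-")  # TSS at 101,000
        sites = pd.DataFrame(
            {
                "tf_id": ["upstream_minus"],
                "chrom": ["chr1"],
                "start": [101_000 + 4_000],
                "end": [101_000 + 4_050],
            }
        )
        edges = tf_edges_from_binding_sites(sites, [g])
        assert list(edges["regulator_id"]) == ["upstream_minus"]


class TestCpGCategorization:
    def test_cgi_overlap_by_one_base(self):
        idx = IntervalIndex([(iv(1000, 1200), None)])
        out = categorize_promoter_cpg("ATAT" * 200, cgi_index=idx, promoter=iv(800, 1001))
        assert out["CGI_overlap"] is True

    def test_all_at_sequence_is_low(self):
        out = categorize_promoter_cpg("AT" * 400)
        assert out["cpg_class"] == "low"

    def test_alternating_cg_is_high(self):
        # window GC = 1.0; CpG o/e = (#CG * w) / (#C * #G) = (249*500)/(250*250) ~ 2
        out = categorize_promoter_cpg("CG" * 250)
        assert out["cpg_class"] == "high"

    def test_intermediate_between_the_extremes(self):
        # CpGs present (o/e above 0.4) but GC-poor: intermediate
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("AATTCG"), 1000))
        out = categorize_promoter_cpg(seq)
        assert out["cpg_class"] == "intermediate"

    def test_non_acgtn_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            categorize_promoter_cpg("ACGTX" * 100)
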