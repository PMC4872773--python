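import math

import numpy as np
import pandas as pd
import pytest

from lncbreadth.function_prediction import (
    band_enrichment,
    coexpression,
    go_enrichment,
    neighbor_fraction,
    neighbors_within,
    predict_ts_function,
    randomization_test,
)
from lncbreadth.intervals import GenomicInterval
from lncbreadth.stats import bh_adjust


def iv(start, end, chrom="chr1"):
    return GenomicInterval(chrom, start, end, "+")


class TestNeighborsWithin:
    def test_overlapping_gene_in_every_window(self):
        out = neighbors_within({"l": iv(10_000, 15_000)}, {"p": iv(12_000, 20_000)})
        (a,) = out
        assert all(a.neighbors[w] == ["p"] for w in a.neighbors)
        assert a.nearest_gene_id == "p" and a.nearest_distance == 0

    def test_sixty_kb_gene_only_in_largest_window(self):
        out = neighbors_within({"l": iv(0, 1000)}, {"p": iv(61_000, 62_000)})
        (a,) = out
        assert a.neighbors[50_000] == []
        assert a.neighbors[100_000] == ["p"]

    def test_same_tissue_filter(self):
        out = neighbors_within(
            {"l": iv(0, 1000)},
            {"p1": iv(2000, 3000), "p2": iv(4000, 5000)},
            windows=[10_000],
            same_tissue={"p1": "liver", "p2": "brain"},
            lnc_tissue={"l": "liver"},
        )
        assert out[0].neighbors[10_000] == ["p1"]

    def test_planted_fraction_recovered(self, default_bundle, default_run):
        gt = pd.read_csv(default_bundle / "ground_truth.tsv", sep="\t")
        planted = gt[(gt.label == "UE") & (gt.biotype == "lncRNA")]["neighbor_planted"].mean()
        out_dir, manifest = default_run
        measured = manifest["counts"]["function_prediction"]["ue_neighbor_fractions"]["100000"]
        # binomial 99% CI around the planted fraction at n = number of UE lncRNAs
        n = int((gt.label == "UE").sum() - (gt.biotype == "protein_coding").sum() * 0)
        n_ue = len(gt[(gt.label == "UE") & (gt.biotype == "lncRNA")])
        half = 2.58 * math.sqrt(planted * (1 - planted) / n_ue)
        assert abs(measured - planted) <= max(half, 0.01)


class TestCoexpression:
    def test_identical_vectors(self):
        rows = pd.DataFrame([[1, 2, 3, 4.0]], index=["p"])
        r = coexpression([1, 2, 3, 4.0], rows, log_transform=False)
        assert r["p"] == pytest.approx(1.0)

    def test_perfectly_anticorrelated(self):
        rows = pd.DataFrame([[4, 3, 2, 1.0]], index=["p"])
        r = coexpression([1, 2, 3, 4.0], rows, log_transform=False)
        assert r["p"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # (1,2,3,4) vs (1,3,2,4): covariance 4/3, sd products 5/3 -> r = 0.8
        rows = pd.DataFrame([[1, 3, 2, 4.0]], index=["p"])
        r = coexpression([1, 2, 3, 4.0], rows, log_transform=False)
        assert r["p"] == pytest.approx(0.8)

    def test_zero_variance_flagged_nan(self):
        rows = pd.DataFrame([[2, 2, 2, 2.0]], index=["p"])
        r = coexpression([1, 2, 3, 4.0], rows, log_transform=False)
        assert math.isnan(r["p"])

    def test_spearman_option(self):
        rows = pd.DataFrame([[10, 100, 1000, 10_000.0]], index=["p"])
        r = coexpression([1, 2, 3, 4.0], rows, method="spearman", log_transform=False)
        assert r["p"] == pytest.approx(1.0)


class TestRandomizationTest:
    def _data(self, seed=0, n=8, tissues=12, n_bg=100):
        rng = np.random.default_rng(seed)
        lnc = pd.DataFrame(rng.lognormal(1, 1, size=(n, tissues)))
        bg = pd.DataFrame(rng.lognormal(1, 1, size=(n_bg, tissues)))
        return lnc, bg

    def test_observed_above_all_null_gives_plus_one_p(self):
        lnc, bg = self._data()
        p, null = randomization_test(np.ones(len(lnc)), lnc, bg, n_perm=1000, seed=1)
        assert p == pytest.approx(1 / 1001)
        assert null.shape == (1000,)

    def test_zero_permutations_rejected(self):
        lnc, bg = self._data()
        with pytest.raises(ValueError):
            randomization_test(np.ones(len(lnc)), lnc, bg, n_perm=0)

    def test_small_background_rejected(self):
        lnc, bg = self._data(n=8, n_bg=4)
        with pytest.raises(ValueError, match="background"):
            randomization_test(np.ones(len(lnc)), lnc, bg, n_perm=10)


def hypergeom_enumeration(overlap, universe, term, drawn):
    """Oracle: exact tail by summing binomial-coefficient products."""
    total = math.comb(universe, drawn)
    return sum(
        math.comb(term, k) * math.comb(universe - term, drawn - k)
        for k in range(overlap, min(term, drawn) + 1)
    ) / total


class TestGoEnrichment:
    def _annotation(self):
        # universe of 10; term T1 covers 4 genes
        rows = [(f"g{i}", "T1", "term one") for i in range(4)]
        rows += [(f"g{i}", "T2", "term two") for i in range(10)]
        return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])

    def test_exact_p_for_printed_example(self):
        universe = [f"g{i}" for i in range(10)]
        res = go_enrichment([f"g{i}" for i in range(5)], self._annotation(), universe, p_max=1.1)
        t1 = next(r for r in res if r.term_id == "T1")
        assert t1.overlap_count == 4
        assert t1.p_raw == pytest.approx(6 / 252, abs=1e-12)
        assert t1.p_raw == pytest.approx(hypergeom_enumeration(4, 10, 4, 5), abs=1e-12)

    def test_single_gene_overlap_excluded(self):
        ann = pd.DataFrame({"gene_id": ["g0"], "term_id": ["T9"], "term_name": ["x"]})
        res = go_enrichment(["g0"], ann, ["g0", "g1"], p_max=1.1)
        assert res == []  # overlap 1 < 2, dropped regardless of p

    def test_bh_triple_by_hand(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    def test_adjusted_never_below_raw(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 50)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_gene_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment(["gX"], self._annotation(), ["g0"])

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            go_enrichment([], self._annotation(), [])


class TestBandEnrichment:
    def test_concentrated_band_significant(self):
        # 100 genes; band b1 holds 5 genes, 4 of them in the 20-gene category
        bands = {f"g{i}": ("b1" if i < 5 else "b2") for i in range(100)}
        chroms = {f"g{i}": "chr1" for i in range(100)}
        category = [f"g{i}" for i in range(4)] + [f"g{i}" for i in range(50, 66)]
        out = band_enrichment(category, bands, chroms)
        row = out[(out.scope == "band") & (out.label == "b1")].iloc[0]
        oracle = hypergeom_enumeration(4, 100, 5, 20)
        assert row["p_raw"] == pytest.approx(oracle, abs=1e-12)
        assert row["significant"]

    def test_empty_band_not_significant(self):
        bands = {"g0": "b1", "g1": "b2"}
        chroms = {"g0": "chr1", "g1": "chr1"}
        out = band_enrichment(["g1"], bands, chroms)
        row = out[(out.scope == "band") & (out.label == "b1")].iloc[0]
        assert row["p_raw"] == pytest.approx(1.0)

    def test_category_equals_universe_saturates(self):
        # when the category is the whole universe the overlap is its maximum
        # with certainty, so the upper-tail p degenerates to exactly 1
        bands = {f"g{i}": f"b{i % 3}" for i in range(9)}
        chroms = {f"g{i}": "chr1" for i in range(9)}
        out = band_enrichment(list(bands), bands, chroms)
        assert np.allclose(out["p_raw"], 1.0)


def block_profiles(n_per_block=25, sigma_frac=0.1, seed=0, prefix=("L", "P")):
    """Two planted co-modification blocks over the six active marks."""
    from lncbreadth.function_prediction import ACTIVE_MARKS

    rng = np.random.default_rng(seed)
    high, low = 10.0, 2.0
    sigma = sigma_frac * (high - low)
    profiles, truth = {}, {}
    for b in (0, 1):
        for kind in prefix:
            for i in range(n_per_block):
                gid = f"{kind}{b}_{i}"
                per_mark = {}
                for mi, mark in enumerate(ACTIVE_MARKS):
                    level = high if (mi < 3) == (b == 0) else low
                    per_mark[mark] = np.maximum(rng.normal(level, sigma, 40), 0.0)
                profiles[gid] = per_mark
                truth[gid] = b
    return profiles, truth


class TestPredictTsFunction:
    def _setup(self):
        profiles, truth = block_profiles()
        lnc = sorted(g for g in profiles if g.startswith("L"))
        pc = sorted(g for g in profiles if g.startswith("P"))
        ann = pd.DataFrame(
            [(g, f"GO:BLOCK{truth[g]}", f"block {truth[g]}") for g in pc],
            columns=["gene_id", "term_id", "term_name"],
        )
        return profiles, truth, lnc, pc, ann

    def test_row_order_invariance(self):
        profiles, truth, lnc, pc, ann = self._setup()
        a = predict_ts_function("liver", lnc, pc, profiles, ann, pc)
        b = predict_ts_function("liver", lnc[::-1], pc[::-1], profiles, ann, pc)
        sets_a = sorted((sorted(c.member_ids) for c in a))
        sets_b = sorted((sorted(c.member_ids) for c in b))
        assert sets_a == sets_b

    def test_lnc_only_cluster_predicts_nothing(self):
        profiles, truth, lnc, pc, ann = self._setup()
        only_lnc = {g: profiles[g] for g in lnc}
        clusters = predict_ts_function("liver", lnc, [], only_lnc, ann, pc)
        assert all(c.enriched_terms == [] for c in clusters)

    def test_too_few_members_warns_and_returns_empty(self):
        profiles, truth, lnc, pc, ann = self._setup()
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = predict_ts_function("liver", lnc[:1], pc[:1], profiles, ann, pc)
        assert out == []
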