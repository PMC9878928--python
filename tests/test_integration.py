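"""z-scores, gene-peak association, non-dominated sorting, recovery metrics."""

import numpy as np
import pandas as pd
import pytest

from zfintegrate import integration as integ
from zfintegrate.core import Gene, GenomicInterval, Peak


def brute_force_levels(pts):
    """O(n^2) reference non-dominated sorting for 2D maximization."""
    pts = np.asarray(pts, float)
    n = len(pts)
    levels = np.zeros(n, dtype=int)
    remaining = set(range(n))
    lvl = 0
    while remaining:
        lvl += 1
        front = []
        for i in remaining:
            dominated = any(
                j != i
                and pts[j, 0] >= pts[i, 0]
                and pts[j, 1] >= pts[i, 1]
                and (pts[j, 0] > pts[i, 0] or pts[j, 1] > pts[i, 1])
                for j in remaining
            )
            if not dominated:
                front.append(i)
        for i in front:
            levels[i] = lvl
        remaining -= set(front)
    return levels


class TestZScores:
    def test_definition_and_reconstruction(self, rng):
        fc = pd.DataFrame({"log2fc": rng.normal(0, 1.7, 100)},
                          index=[f"g{i}" for i in range(100)])
        zv = integ.zscore_fold_changes(fc)
        sd = np.std(fc["log2fc"], ddof=1)
        np.testing.assert_allclose(zv.z, fc["log2fc"] / sd, atol=1e-12)
        np.testing.assert_allclose(zv.reconstruct_log2fc(), fc["log2fc"],
                                   atol=1e-12)

    def test_no_centering(self):
        fc = pd.DataFrame({"log2fc": [10.0, 11.0, 12.0]}, index=list("abc"))
        zv = integ.zscore_fold_changes(fc)
        assert zv.z.mean() > 5  # centering would put the mean at 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            integ.zscore_fold_changes(
                pd.DataFrame({"log2fc": [1.0, np.nan]}, index=list("ab"))
            )
        with pytest.raises(ValueError, match="identical"):
            integ.zscore_fold_changes(
                pd.DataFrame({"log2fc": [2.0, 2.0, 2.0]}, index=list("abc"))
            )


class TestAssociation:
    def test_window_edges_inclusive(self):
        g = Gene("g", GenomicInterval("chr1", 100_000, 110_000, "+"))
        # window is [50_000, 159_999 + 50_000] = [50_000, 159_999]
        inside_lo = Peak("lo", GenomicInterval("chr1", 49_900, 50_001))
        at_lo_edge = Peak("edge", GenomicInterval("chr1", 49_000, 50_000))
        inside_hi = Peak("hi", GenomicInterval("chr1", 159_999, 160_100))
        past_hi = Peak("past", GenomicInterval("chr1", 160_000, 160_100))
        pairs = integ.associate_gene_peaks(
            [g], [inside_lo, at_lo_edge, inside_hi, past_hi]
        )
        assert set(pairs["peak_id"]) == {"lo", "hi"}

    def test_strand_independent_window(self):
        plus = Gene("p", GenomicInterval("chr1", 100_000, 110_000, "+"))
        minus = Gene("m", GenomicInterval("chr1", 100_000, 110_000, "-"))
        peak = Peak("x", GenomicInterval("chr1", 60_000, 60_400))
        pairs = integ.associate_gene_peaks([plus, minus], [peak])
        assert set(pairs["gene_id"]) == {"p", "m"}

    def test_many_to_many(self):
        g1 = Gene("g1", GenomicInterval("chr1", 100_000, 110_000, "+"))
        g2 = Gene("g2", GenomicInterval("chr1", 120_000, 130_000, "+"))
        shared = Peak("s", GenomicInterval("chr1", 115_000, 115_400))
        pairs = integ.associate_gene_peaks([g1, g2], [shared])
        assert len(pairs) == 2


class TestCombinedScores:
    def test_product_and_classes(self):
        pairs = pd.DataFrame({"gene_id": ["a", "b"], "peak_id": ["p", "q"]})
        zg = integ.ZScoreVector(pd.Series([2.0, -1.0], index=["a", "b"]), 1.0)
        zp = integ.ZScoreVector(pd.Series([3.0, 4.0], index=["p", "q"]), 1.0)
        out = integ.combined_scores(pairs, zg, zp)
        assert list(out["z_gp"]) == [6.0, -4.0]
        assert list(out["correlation_class"]) == ["correlated", "anti_correlated"]

    def test_missing_feature_raises(self):
        pairs = pd.DataFrame({"gene_id": ["a"], "peak_id": ["nope"]})
        zg = integ.ZScoreVector(pd.Series([1.0], index=["a"]), 1.0)
        zp = integ.ZScoreVector(pd.Series([1.0], index=["p"]), 1.0)
        with pytest.raises(KeyError):
            integ.combined_scores(pairs, zg, zp)


class TestNondominatedLevels:
    def test_toy_example(self):
        pts = np.array([[3, 3], [2, 1], [1, 2], [1, 1]])
        np.testing.assert_array_equal(
            integ.nondominated_levels(pts), [1, 2, 2, 3]
        )

    def test_duplicates_share_level(self):
        pts = np.array([[2.0, 2.0], [2.0, 2.0], [1.0, 1.0]])
        np.testing.assert_array_equal(integ.nondominated_levels(pts), [1, 1, 2])

    def test_matches_bruteforce_random(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 120))
            pts = rng.integers(0, 12, size=(n, 2)).astype(float)
            np.testing.assert_array_equal(
                integ.nondominated_levels(pts), brute_force_levels(pts)
            )

    def test_empty_and_bad_shape(self):
        assert len(integ.nondominated_levels(np.empty((0, 2)))) == 0
        with pytest.raises(ValueError):
            integ.nondominated_levels(np.zeros((3, 3)))


class TestParetoSelection:
    def make_pairs(self, rng, n=50):
        zg = rng.normal(0, 1, n)
        zp = rng.normal(0, 1, n)
        pairs = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "peak_id": [f"p{i}" for i in range(n)],
            "z_g": zg, "z_p": zp, "z_gp": zg * zp,
            "correlation_class": np.where(zg * zp > 0, "correlated",
                                          "anti_correlated"),
        })
        return pairs

    def test_levels_assigned_within_class(self, rng):
        pairs = self.make_pairs(rng)
        out = integ.pareto_levels(pairs)
        for cls in ("correlated", "anti_correlated"):
            sub = out[out["correlation_class"] == cls]
            ref = brute_force_levels(
                np.abs(sub[["z_g", "z_p"]].to_numpy(float))
            )
            np.testing.assert_array_equal(sub["pareto_level"].to_numpy(), ref)

    def test_unassigned_gets_no_level(self):
        pairs = pd.DataFrame({
            "gene_id": ["a"], "peak_id": ["p"], "z_g": [0.0], "z_p": [1.0],
            "z_gp": [0.0], "correlation_class": ["unassigned"],
        })
        out = integ.pareto_levels(pairs)
        assert out["pareto_level"].iloc[0] == 0
        assert len(integ.select_top_levels(out)) == 0

    def test_abs_product_objective_is_rank_by_magnitude(self, rng):
        pairs = self.make_pairs(rng)
        out = integ.pareto_levels(pairs, objective="abs_product")
        sub = out[out["correlation_class"] == "correlated"]
        srt = sub.sort_values("z_gp", key=np.abs, ascending=False)
        assert srt["pareto_level"].is_monotonic_increasing


class TestRecovery:
    def test_counts_and_rates(self):
        truth = pd.DataFrame(
            {"coupled": [True, True, False], "causal_peak": ["p1", "p2", None]},
            index=["g1", "g2", "g3"],
        )
        selected = pd.DataFrame(
            {"gene_id": ["g1", "g3"], "peak_id": ["p1", "p9"]}
        )
        r = integ.recover_planted_coupling(selected, truth)
        assert r["n_planted"] == 2 and r["n_recovered"] == 1
        assert r["recall"] == 0.5 and r["precision"] == 0.5
        assert list(r["scatter"]["is_planted_pair"]) == [True, False]

    def test_unknown_gene_raises(self):
        truth = pd.DataFrame({"coupled": [False], "causal_peak": [None]},
                             index=["g1"])
        sel = pd.DataFrame({"gene_id": ["gX"], "peak_id": ["p"]})
        with pytest.raises(KeyError):
            integ.recover_planted_coupling(sel, truth)


class TestIntegrateEndToEnd:
    def test_zscore_scale_invariance_of_selection(self, rng):
        genes = [
            Gene(f"g{i}", GenomicInterval("chr1", s, s + 5000, "+"))
            for i, s in enumerate(range(0, 900_000, 30_000))
        ]
        peaks = [
            Peak(f"p{i}", GenomicInterval("chr1", s, s + 400))
            for i, s in enumerate(range(1000, 900_000, 7000))
        ]
        gfc = pd.DataFrame({"log2fc": rng.normal(0, 2, len(genes))},
                           index=[g.gene_id for g in genes])
        pfc = pd.DataFrame({"log2fc": rng.normal(0, 1, len(peaks))},
                           index=[p.peak_id for p in peaks])
        a = integ.integrate(genes, peaks, gfc, pfc)
        b = integ.integrate(genes, peaks, gfc * 7.0, pfc * 0.1)
        np.testing.assert_array_equal(a["selected"], b["selected"])
        np.testing.assert_array_equal(a["pareto_level"], b["pareto_level"])

    def test_de_genes_only_restricts_pairing(self, rng):
        genes = [
            Gene("g1", GenomicInterval("chr1", 100_000, 110_000, "+")),
            Gene("g2", GenomicInterval("chr1", 300_000, 310_000, "+")),
        ]
        peaks = [
            Peak("p1", GenomicInterval("chr1", 105_000, 105_400)),
            Peak("p2", GenomicInterval("chr1", 305_000, 305_400)),
        ]
        gfc = pd.DataFrame({"log2fc": [2.0, -1.5]}, index=["g1", "g2"])
        pfc = pd.DataFrame({"log2fc": [1.0, -1.0]}, index=["p1", "p2"])
        labels = pd.Series(["up", "unchanged"], index=["g1", "g2"])
        out = integ.integrate(genes, peaks, gfc, pfc,
                              de_genes_only=True, de_labels=labels)
        assert set(out["gene_id"]) == {"g1"}
        with pytest.raises(ValueError):
            integ.integrate(genes, peaks, gfc, pfc, de_genes_only=True)
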