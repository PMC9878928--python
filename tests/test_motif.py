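"""PWM scoring, exact p-values, flank alignment, clustering, signatures."""

import itertools

import numpy as np
import pytest

from zfintegrate import motif as mo
from zfintegrate.motif import PWM, FlankAlignment, MotifHit, ScoreDistribution


class TestPWM:
    def test_from_consensus(self):
        p = PWM.from_consensus("ACG", fidelity=0.9)
        assert p.width == 3
        assert p.probs[0, 0] == pytest.approx(0.9)
        assert p.probs[0, 1] == pytest.approx(0.1 / 3)
        np.testing.assert_allclose(p.probs.sum(axis=1), 1.0)

    def test_background_column_scores_zero(self):
        # a column equal to the background has log-odds exactly zero
        bg = np.array([0.4, 0.1, 0.1, 0.4])
        p = PWM("m", np.vstack([bg, [0.97, 0.01, 0.01, 0.01]]), bg)
        lo = p.log_odds()
        np.testing.assert_allclose(lo[0], 0.0, atol=1e-12)

    def test_reverse_complement_scores_revcomp_sequence(self):
        rng = np.random.default_rng(3)
        probs = rng.dirichlet(np.ones(4), size=5)
        p = PWM("m", probs)
        lo, lo_rc = p.log_odds(), p.reverse_complement().log_odds()
        seq = "ACGTG"
        codes = [mo._CODE[b] for b in seq]
        rc_codes = [mo._CODE[b] for b in mo.revcomp(seq)]
        s_fwd = sum(lo[j, c] for j, c in enumerate(codes))
        s_rc = sum(lo_rc[j, c] for j, c in enumerate(rc_codes))
        assert s_fwd == pytest.approx(s_rc, abs=1e-12)

    def test_validation(self):
        with pytest.raises(ValueError):
            PWM("m", np.array([[0.5, 0.5, 0.5, 0.5]]))
        with pytest.raises(ValueError):
            PWM("m", np.full((2, 4), 0.25), background=[0.5, 0.5, 0.0, 0.0])


class TestExactPValues:
    @pytest.mark.parametrize("width,bg", [
        (3, np.full(4, 0.25)),
        (5, np.array([0.3, 0.2, 0.2, 0.3])),
        (6, np.array([0.1, 0.4, 0.4, 0.1])),
    ])
    def test_matches_exhaustive_enumeration(self, width, bg):
        rng = np.random.default_rng(width)
        pwm = PWM("m", rng.dirichlet(np.ones(4), size=width), bg)
        dist = ScoreDistribution(pwm, resolution=1e-3)
        ints = dist.int_scores
        # enumerate all 4^W words: exact tail probability per word score
        scores, probs = [], []
        for word in itertools.product(range(4), repeat=width):
            scores.append(sum(ints[j, b] for j, b in enumerate(word)))
            probs.append(np.prod([bg[b] for b in word]))
        scores = np.array(scores)
        probs = np.array(probs)
        for s in np.unique(scores)[::5]:
            expected = probs[scores >= s].sum()
            assert dist.pvalue_int(int(s)) == pytest.approx(expected, abs=1e-12)

    def test_pvalue_bounds(self):
        pwm = PWM.from_consensus("ACGT")
        dist = ScoreDistribution(pwm)
        assert dist.pvalue_int(dist.min_total) == pytest.approx(1.0, abs=1e-9)
        assert dist.pvalue_int(10**9) == 0.0

    def test_resolution_guard(self):
        pwm = PWM.from_consensus("ACGT")
        with pytest.raises(ValueError, match="resolution"):
            ScoreDistribution(pwm, resolution=0.1)


class TestScan:
    def test_finds_planted_site_both_strands(self):
        core = "TGGCCACCAGGG"
        pwm = PWM.from_consensus(core, fidelity=0.95)
        rng = np.random.default_rng(8)
        bgseq = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        fwd = bgseq(30) + core + bgseq(30)
        rev = bgseq(25) + mo.revcomp(core) + bgseq(35)
        hits = mo.scan({"f": fwd, "r": rev}, pwm, background="uniform")
        best = mo.best_hits(hits)
        assert best["f"].strand == "+" and best["f"].offset == 30
        assert best["r"].strand == "-" and best["r"].offset == 25

    def test_n_windows_are_skipped(self):
        core = "TGGCCACCAGGG"
        pwm = PWM.from_consensus(core, fidelity=0.95)
        seq = "A" * 10 + core[:5] + "N" + core[6:] + "A" * 10
        hits = mo.scan({"s": seq}, pwm, background="uniform")
        assert all(h.offset != 10 for h in hits)

    def test_background_estimation(self):
        bg = mo.estimate_background({"a": "AACC", "b": "GGNN"})
        np.testing.assert_allclose(bg, [2 / 6, 2 / 6, 2 / 6, 0.0])
        np.testing.assert_allclose(
            mo.estimate_background({"a": "NN"}), 0.25
        )


class TestFlankAlignment:
    def plain_hit(self, seq_id, offset, strand="+"):
        return MotifHit(seq_id, offset, strand, 10.0, 1e-6)

    def test_plus_strand_window(self):
        seq = "".join("ACGT"[i % 4] for i in range(60))
        aln = mo.extract_flanks({"s": self.plain_hit("s", 20)}, {"s": seq},
                                core_width=4, flank=5)
        assert aln.rows[0] == seq[15:29]
        assert not aln.padded[0]

    def test_minus_strand_is_reverse_complemented(self):
        seq = "".join("ACGT"[i % 4] for i in range(60))
        aln = mo.extract_flanks({"s": self.plain_hit("s", 20, "-")}, {"s": seq},
                                core_width=4, flank=5)
        assert aln.rows[0] == mo.revcomp(seq[15:29])

    def test_truncation_pads_with_n(self):
        aln = mo.extract_flanks({"s": self.plain_hit("s", 1)}, {"s": "ACGTACGT"},
                                core_width=4, flank=3)
        assert aln.rows[0] == "NNACGTACGT"
        assert aln.padded[0]

    def test_signature_column_mapping(self):
        aln = FlankAlignment(["a"], ["A" * 28], core_width=8, flank=10,
                             padded=[False])
        assert mo.signature_column(aln, 1) == 18
        assert mo.signature_column(aln, 4) == 21
        assert mo.signature_column(aln, -1) == 9
        with pytest.raises(ValueError):
            mo.signature_column(aln, 0)
        with pytest.raises(ValueError):
            mo.signature_column(aln, 11)


class TestHammingAndClusters:
    def make_alignment(self, rows):
        w = len(rows[0])
        return FlankAlignment([f"s{i}" for i in range(len(rows))], list(rows),
                              core_width=w - 4, flank=2,
                              padded=[False] * len(rows))

    def test_distance_definition(self):
        aln = self.make_alignment(["ACGTACGT", "ACGTACGA", "NCGTACGT"])
        D = mo.hamming_distance_matrix(aln)
        assert D[0, 1] == pytest.approx(1 / 8)
        assert D[0, 2] == pytest.approx(0.5 / 8)
        assert D[1, 2] == pytest.approx(1.5 / 8)
        np.testing.assert_allclose(D, D.T)

    def test_two_classes_split_perfectly_at_k2(self, rng):
        base_a = list("ACGTACGTACGTACGTACGT")
        base_b = base_a.copy()
        for pos in (1, 5, 9, 13, 17):  # 5 positions differ between classes
            base_b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[base_b[pos]]
        rows, truth = [], []
        for i in range(30):
            src = base_a if i % 2 == 0 else base_b
            row = src.copy()
            j = int(rng.integers(0, 20))  # one random within-class mismatch
            if j not in (1, 5, 9, 13, 17):
                row[j] = "ACGT"[int(rng.integers(0, 4))]
            rows.append("".join(row))
            truth.append(i % 2)
        aln = self.make_alignment(rows)
        labels, order = mo.hamming_cluster(aln, k=2)
        groups = [set(np.array(truth)[labels == c]) for c in (1, 2)]
        assert groups[0] != groups[1] and all(len(g) == 1 for g in groups)
        assert sorted(order) == list(range(30))

    def test_row_order_invariance_when_separated(self, rng):
        # with tied distances average linkage may break ties by input order,
        # so invariance is asserted on clearly separated classes
        base_a = list("ACGTACGTACGTACGTACGT")
        base_b = [{"A": "C", "C": "G", "G": "T", "T": "A"}[b] for b in base_a]
        rows = []
        for i in range(24):
            src = (base_a if i % 2 == 0 else base_b).copy()
            j = int(rng.integers(0, 20))
            src[j] = "ACGT"[int(rng.integers(0, 4))]
            rows.append("".join(src))
        labels, _ = mo.hamming_cluster(self.make_alignment(rows), k=2)
        perm = rng.permutation(24)
        labels2, _ = mo.hamming_cluster(
            self.make_alignment([rows[i] for i in perm]), k=2
        )
        part1 = {frozenset(np.flatnonzero(labels == c)) for c in set(labels)}
        part2 = {
            frozenset(perm[np.flatnonzero(labels2 == c)]) for c in set(labels2)
        }
        assert part1 == part2

    def test_k_exceeding_rows_rejected(self):
        aln = self.make_alignment(["ACGTAC"])
        with pytest.raises(ValueError):
            mo.hamming_cluster(aln, k=3)


class TestInformationAndSignature:
    def test_column_information_extremes(self):
        df = mo.column_information(["AAAA", "AAAA", "AACG", "AACT"])
        assert df.loc[0, "ic"] == pytest.approx(2.0)
        assert df.loc[0, "A"] == pytest.approx(2.0)
        # column 3: A,A,G,T -> f = (0.5, 0, 0.25, 0.25), ic = 2 - 1.5
        assert df.loc[3, "ic"] == pytest.approx(0.5)

    def test_all_n_column_gets_zero(self):
        df = mo.column_information(["NA", "NA"])
        assert df.loc[0, "ic"] == 0.0

    def test_signature_fraction_counts_and_ci(self):
        rows = ["AAAAGA", "AAAAGA", "AAAACA", "AAAANA"]
        aln = FlankAlignment([f"s{i}" for i in range(4)], rows,
                             core_width=2, flank=2, padded=[False] * 4)
        # offset +1 -> column flank + core_width = 4
        r = mo.signature_fraction(aln, 1, "G")
        assert r["n"] == 3 and r["count"] == 2
        assert r["fraction"] == pytest.approx(2 / 3)
        assert r["ci_low"] < r["fraction"] < r["ci_high"]

    def test_enrichment_over_control(self):
        sig = FlankAlignment(["a", "b"], ["AAAGA", "AAAGA"], 1, 2,
                             [False, False])
        ctrl = FlankAlignment(["c", "d"], ["AAAGA", "AAACA"], 1, 2,
                              [False, False])
        r = mo.signature_fraction(sig, 1, "G", control=ctrl)
        assert r["fraction"] == 1.0
        assert r["control_fraction"] == 0.5
        assert r["enrichment"] == pytest.approx(2.0)
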