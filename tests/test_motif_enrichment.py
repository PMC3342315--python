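"""PWM construction, strand-symmetric scanning, enrichment and distances."""

from collections import Counter

import numpy as np
import pytest

from regnet import motif_enrichment as me
from regnet.motif_enrichment import PWM


def rand_seq(rng, n):
    return "".join("ACGT"[b] for b in rng.integers(0, 4, n))


def plant(seq, instance, pos):
    return seq[:pos] + instance + seq[pos + len(instance):]


class TestPwmLogOdds:
    def test_uniform_counts_give_zero_matrix(self):
        pwm = PWM("flat", np.full((4, 6), 5.0))
        np.testing.assert_allclose(me.pwm_log_odds(pwm), 0.0, atol=1e-12)

    def test_sharp_columns_approach_log2_four(self):
        counts = np.zeros((4, 4))
        counts[0] = 100.0  # all-A consensus
        pwm = PWM("sharp", counts, pseudocount=1e-9)
        lom = me.pwm_log_odds(pwm)
        np.testing.assert_allclose(lom[0], np.log2(4.0), atol=1e-6)

    def test_hand_computed_toy(self):
        counts = np.array([[8, 0, 2, 1], [0, 8, 2, 1], [1, 1, 3, 1], [1, 1, 3, 7]], float)
        pwm = PWM("toy", counts, pseudocount=1.0)
        lom = me.pwm_log_odds(pwm)
        # entry(A, 0): (8 + 1*0.25) / (10 + 1) / 0.25
        assert lom[0, 0] == pytest.approx(np.log2((8.25 / 11.0) / 0.25))
        # entry(G, 2): (3 + 0.25) / 11 / 0.25
        assert lom[2, 2] == pytest.approx(np.log2((3.25 / 11.0) / 0.25))

    def test_zero_column_with_zero_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            me.pwm_log_odds(PWM("bad", np.zeros((4, 4)), pseudocount=0.0))


class TestScanWindow:
    pwm = me.pwm_from_consensus("M", "TGATTGAT")

    def test_planted_consensus_found_at_center(self):
        rng = np.random.default_rng(0)
        seq = plant(rand_seq(rng, 600), "TGATTGAT", 296)
        hits = me.scan_window(seq, self.pwm, 0.9)
        assert any(abs(h.offset) <= 4 and h.strand == "+" for h in hits)

    def test_reverse_complement_mirrors_hits(self):
        rng = np.random.default_rng(1)
        seq = plant(rand_seq(rng, 600), "TGATTGAT", 100)
        fwd = me.scan_window(seq, self.pwm, 0.9)
        rev = me.scan_window(me.reverse_complement(seq), self.pwm, 0.9)
        flipped = sorted((-h.offset, {"+": "-", "-": "+"}[h.strand]) for h in fwd)
        assert flipped == sorted((h.offset, h.strand) for h in rev)

    def test_exact_threshold_matches_string_search(self):
        rng = np.random.default_rng(2)
        consensus = "TGATTGAT"
        seq = plant(plant(rand_seq(rng, 600), consensus, 50), consensus, 400)
        hits = me.scan_window(seq, self.pwm, 1.0)
        expected = set()
        rc = me.reverse_complement(consensus)
        for i in range(len(seq) - len(consensus) + 1):
            word = seq[i : i + len(consensus)]
            if word == consensus:
                expected.add((i, "+"))
            if word == rc:
                expected.add((i, "-"))
        got = {(int(h.offset - len(consensus) / 2 + len(seq) / 2), h.strand) for h in hits}
        assert got == expected

    def test_n_containing_windows_are_skipped(self):
        seq = "N" * 296 + "TGATTGAT" + "N" * 296
        hits = me.scan_window(seq, self.pwm, 0.9)
        assert {h.offset for h in hits} == {0.0}

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError):
            me.scan_window("ACGTX" * 120, self.pwm)


class TestDinucleotideShuffle:
    def test_preserves_dinucleotide_counts(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            seq = rand_seq(rng, 300)
            shuf = me.dinucleotide_shuffle(seq, rng)
            assert len(shuf) == len(seq)
            assert Counter(zip(seq, seq[1:])) == Counter(zip(shuf, shuf[1:]))

    def test_actually_shuffles(self):
        rng = np.random.default_rng(4)
        seq = rand_seq(rng, 300)
        assert any(me.dinucleotide_shuffle(seq, rng) != seq for _ in range(5))


class TestEnrichMotifs:
    def test_planted_motif_ranks_first(self):
        rng = np.random.default_rng(5)
        pwm = me.pwm_from_consensus("PLANTED", "TGATTGAT")
        decoys = [me.pwm_from_consensus(f"D{i}", rand_seq(rng, 9)) for i in range(5)]
        windows = {f"w{i}": rand_seq(rng, 600) for i in range(200)}
        for i in range(100):  # plant in half the windows
            pos = int(rng.integers(0, 592))
            windows[f"w{i}"] = plant(windows[f"w{i}"], "TGATTGAT", pos)
        results = me.enrich_motifs(windows, [pwm] + decoys, seed=0)
        assert results[0].motif_id == "PLANTED"
        assert results[0].p_value < 0.05 and results[0].enriched

    def test_identical_windows_flag_nothing(self):
        rng = np.random.default_rng(6)
        library = [me.pwm_from_consensus(f"D{i}", rand_seq(rng, 8)) for i in range(5)]
        windows = {f"w{i}": rand_seq(rng, 300) for i in range(100)}
        results = me.enrich_motifs(windows, library, background=windows)
        assert not any(r.enriched for r in results)
        assert all(0 < r.p_value <= 1 for r in results)

    def test_absent_motif_not_enriched(self):
        rng = np.random.default_rng(7)
        pwm = me.pwm_from_consensus("ABSENT", "TGATTGATTG")
        windows = {f"w{i}": rand_seq(rng, 300) for i in range(50)}
        results = me.enrich_motifs(windows, [pwm], seed=1)
        assert results[0].p_value > 0.4

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            me.enrich_motifs({}, [me.pwm_from_consensus("M", "ACGTACGT")])
        with pytest.raises(ValueError):
            me.enrich_motifs({"w": "ACGT" * 100}, [])

    def test_null_pvalues_roughly_uniform(self):
        """Resampled null: peak and background windows from one pool.

        The motif's per-window hit rate (~0.35) keeps the binomial tail away
        from its degenerate near-zero regime, and the background sample is
        4x the peak sample so rate-estimation noise stays small.
        """
        rng = np.random.default_rng(8)
        pwm = me.pwm_from_consensus("M", "TGATC")
        pool = [rand_seq(rng, 300) for _ in range(2000)]
        hit = np.array([bool(me.scan_window(s, pwm, 0.8)) for s in pool])
        n, n_bg = 100, 400
        pvals = []
        from scipy import stats as ss
        for _ in range(1000):
            idx = rng.permutation(len(pool))
            h_peak = int(hit[idx[:n]].sum())
            h_bg = int(hit[idx[n : n + n_bg]].sum())
            rate = min(max(h_bg / n_bg, 0.5 / n_bg), 1 - 0.5 / n_bg)
            pvals.append(float(ss.binom.sf(h_peak - 1, n, rate)))
        grid = np.linspace(0, 1, 201)
        ecdf = np.searchsorted(np.sort(pvals), grid, side="right") / len(pvals)
        assert np.max(np.abs(ecdf - grid)) < 0.1


class TestPeakMotifDistances:
    def test_single_hit_at_zero(self):
        hits = [me.MotifHit("r1", 0.0, "+", 5.0)]
        assert me.peak_motif_distances(hits) == [0.0]

    def test_closest_by_absolute_value(self):
        hits = [me.MotifHit("r1", -50.0, "+", 5.0), me.MotifHit("r1", 120.0, "+", 5.0)]
        assert me.peak_motif_distances(hits) == [-50.0]

    def test_planted_gaussian_offsets_recovered(self):
        rng = np.random.default_rng(9)
        pwm = me.pwm_from_consensus("M", "TGATTGATCA")
        windows = {}
        for i in range(500):
            offset = int(np.clip(rng.normal(0, 75), -290, 290))
            pos = 300 + offset - 5
            windows[f"w{i}"] = plant(rand_seq(rng, 600), "TGATTGATCA", pos)
        dist = me.peak_motif_distances(me.scan_regions(windows, pwm, 0.9))
        assert len(dist) >= 450
        assert abs(np.mean(dist)) <= 15


class TestLibraryIO:
    TRANSFAC = """\
ID  motifA
P0      A      C      G      T
01      10      0      0      0
02      0      10      0      0
03      0      0      10      0
04      0      0      0      10
05      5      5      0      0
XX
//
ID  motifB
P0      A      C      G      T
01      1      2      3      4
02      4      3      2      1
03      0      0      0      10
04      10      0      0      0
XX
//
"""

    def test_parse_transfac_minimal_dialect(self):
        motifs = me.parse_transfac(self.TRANSFAC)
        assert [m.motif_id for m in motifs] == ["motifA", "motifB"]
        assert motifs[0].width == 5
        assert motifs[0].consensus == "ACGTA"
        assert motifs[1].counts[3, 2] == 10

    def test_parse_pfm_tsv(self):
        text = ">m1\n10\t0\t0\t0\n0\t10\t0\t0\n0\t0\t10\t0\n0\t0\t0\t10\n"
        motifs = me.parse_pfm_tsv(text)
        assert motifs[0].consensus == "ACGT"

    def test_load_dispatches_on_content(self, tmp_path):
        p1 = tmp_path / "lib.transfac"
        p1.write_text(self.TRANSFAC)
        assert len(me.load_motif_library(p1)) == 2
        p2 = tmp_path / "lib.tsv"
        p2.write_text(">m1\n1\t2\t3\t4\n4\t3\t2\t1\n1\t1\t1\t1\n2\t2\t2\t2\n")
        assert me.load_motif_library(p2)[0].width == 4
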