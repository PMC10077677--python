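import numpy as np
import pytest

import _oracles
from irekit.genome import Genome
from irekit.intervals import AnnotationSet, GenomicInterval
from irekit.motifs import (
    AP1,
    ETS,
    MOTIF_REGISTRY,
    MotifPattern,
    classify_motif_groups,
    gc_matched_background,
    motif_frequency,
    motif_presence_enrichment,
    relative_overlap_ratio,
    scan_motif,
)


def random_seq(rng, n, with_n=False):
    alphabet = "ACGTN" if with_n else "ACGT"
    p = [0.24, 0.24, 0.24, 0.24, 0.04] if with_n else None
    return "".join(rng.choice(list(alphabet), size=n, p=p))


class TestMotifPattern:
    def test_invalid_letters_and_short_codes_rejected(self):
        with pytest.raises(ValueError):
            MotifPattern("x", "other", "ACXG")
        with pytest.raises(ValueError):
            MotifPattern("x", "other", "ACG")

    def test_ap1_consensus_is_its_own_reverse_complement(self):
        assert AP1.is_palindromic()
        assert not ETS.is_palindromic()

    def test_registry_has_21_factor_codes(self):
        factors = [p for p in MOTIF_REGISTRY.values() if p.name not in ("AP-1", "ETS")]
        assert len(factors) == 21
        assert sum(p.family == "ETS" for p in factors) == 14
        assert sum(p.family == "AP-1" for p in factors) == 7


class TestScanMotif:
    def test_empty_sequence_no_hits(self):
        assert scan_motif("", AP1).count == 0

    def test_concrete_ap1_word_matches_forward(self):
        hits = scan_motif("TGACTCA", AP1, "forward")
        assert hits.count == 1 and hits.positions == [(0, "+")]

    def test_tandem_ap1_words_dedup(self):
        assert scan_motif("TGACTCATGACTCA", AP1, "both_dedup").count == 2

    def test_overlapping_windows_all_counted(self):
        # TKASTMA matches at 0 and (embedded) again at 7; overlapping windows
        # of a repeat like TGACTGACTCA... are each tested
        seq = "TGAGTAATGAGTAA"  # T-K(G)-A-S(G)-T-M(A)-A twice
        assert scan_motif(seq, AP1, "forward").count == 2

    def test_sequence_n_never_matches_concrete_positions(self):
        assert scan_motif("TGACTCN", AP1, "forward").count == 0

    def test_ap1_palindromy_makes_dedup_equal_forward(self, rng):
        for _ in range(5):
            seq = random_seq(rng, 1000)
            assert (
                scan_motif(seq, AP1, "both_dedup").count
                == scan_motif(seq, AP1, "forward").count
            )

    def test_ets_strand_modes_differ_in_general(self, rng):
        seq = "".join(
            "VVGGAWVY".replace("V", "A").replace("W", "A").replace("Y", "C")
            for _ in range(3)
        )
        fwd = scan_motif(seq, ETS, "forward").count
        both = scan_motif(seq, ETS, "both_sum").count
        assert both >= fwd

    @pytest.mark.parametrize("name", ["AP-1", "ETS", "ETS1", "SPIB", "ATF3", "ELF3"])
    def test_matches_word_expansion_oracle(self, rng, name):
        pat = MOTIF_REGISTRY[name]
        for _ in range(5):
            seq = random_seq(rng, 2000, with_n=True)
            got_fwd = {p for p, s in scan_motif(seq, pat, "forward").positions}
            assert got_fwd == _oracles.oracle_match_positions(seq, pat.iupac)
            got_both = {p for p, s in scan_motif(seq, pat, "both_dedup").positions}
            assert got_both == _oracles.oracle_match_positions(
                seq, pat.iupac, both_strands=True
            )


class TestMotifFrequency:
    @pytest.mark.parametrize(
        "c,s,expected",
        [(6, 800, 7.5), (3, 459, 6.536), (0, 1234, 0.0)],
    )
    def test_per_kb_formula(self, c, s, expected):
        assert motif_frequency(c, s) == pytest.approx(expected, abs=1e-3)

    def test_zero_length_errors(self):
        with pytest.raises(ValueError):
            motif_frequency(1, 0)

    def test_scales_linearly_in_count_inversely_in_size(self):
        assert motif_frequency(10, 500) == 2 * motif_frequency(5, 500)
        assert motif_frequency(5, 1000) == motif_frequency(5, 500) / 2

    def test_self_concatenation_roughly_preserves_frequency(self, rng):
        seq = random_seq(rng, 1500)
        single = scan_motif(seq, ETS)
        double = scan_motif(seq + seq, ETS)
        assert double.count >= 2 * single.count  # junction can only add
        assert abs(double.frequency - single.frequency) <= 1000 * len(ETS) / len(seq)


class TestClassifyMotifGroups:
    def test_constructed_four_way_partition(self):
        pad = "ATATATATAT" * 10
        seqs = {
            "ap1": pad + "TGACTCA" + pad,
            "ets": pad + "ACGGAAAC" + pad,
            "both": pad + "TGACTCA" + pad + "ACGGAAAC" + pad,
            "neither": pad + pad,
        }
        genome = Genome(seqs)
        ires = [GenomicInterval(k, 0, len(v), name=k) for k, v in seqs.items()]
        labels, counts = classify_motif_groups(ires, genome)
        assert counts == {"AP-1 only": 1, "ETS only": 1, "both": 1, "neither": 1}
        assert sum(counts.values()) == len(ires)

    def test_empty_input(self):
        labels, counts = classify_motif_groups([], Genome({"c": "ACGT"}))
        assert labels == [] and sum(counts.values()) == 0


class TestGcMatchedBackground:
    @staticmethod
    def _pool_genome(rng, n=300, length=200):
        seqs, ivs = {}, []
        for i in range(n):
            gc = rng.uniform(0.2, 0.7)
            seq = "".join(
                rng.choice(list("ACGT"), size=length,
                           p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
            )
            seqs[f"c{i}"] = seq
            ivs.append(GenomicInterval(f"c{i}", 0, length, name=f"r{i}"))
        return Genome(seqs), ivs

    def test_pool_equal_to_targets_reproduces_gc_histogram(self, rng):
        genome, ivs = self._pool_genome(rng)
        sel = gc_matched_background(ivs, ivs, genome, n=100, seed=3)
        assert len(sel) == 100
        width = 0.04
        tb = np.array([int(genome.gc(iv) / width) for iv in ivs])
        sb = np.array([int(genome.gc(iv) / width) for iv in sel])
        t_hist = np.bincount(tb, minlength=30) / len(tb)
        s_hist = np.bincount(sb, minlength=30) / len(sb)
        assert np.abs(t_hist - s_hist).max() < 0.02

    def test_impossible_gc_demand_errors_with_bin(self):
        genome = Genome({"at": "AT" * 100, "gc": "GC" * 100})
        pool = [GenomicInterval("at", 0, 200)] * 5
        targets = [GenomicInterval("gc", 0, 200)]
        with pytest.raises(ValueError, match="GC bin"):
            gc_matched_background(pool, targets, genome, n=1, seed=0)

    def test_seed_determinism(self, rng):
        genome, ivs = self._pool_genome(rng)
        a = gc_matched_background(ivs, ivs[:50], genome, n=30, seed=11)
        b = gc_matched_background(ivs, ivs[:50], genome, n=30, seed=11)
        assert a == b


class TestPresenceEnrichment:
    @staticmethod
    def _genome_with(present, absent):
        seqs = {}
        for i in range(present):
            seqs[f"p{i}"] = "ATAT" * 20 + "TGACTCA" + "ATAT" * 20
        for i in range(absent):
            seqs[f"a{i}"] = "ATAT" * 42
        genome = Genome(seqs)
        ivs = [GenomicInterval(c, 0, len(s), name=c) for c, s in seqs.items()]
        return genome, ivs

    def test_equal_proportions_give_odds_ratio_one(self):
        genome, ivs = self._genome_with(5, 5)
        res = motif_presence_enrichment(ivs, ivs, genome, AP1)
        assert res.odds_ratio == pytest.approx(1.0)

    def test_eight_vs_two_of_ten(self):
        genome, ivs = self._genome_with(10, 10)
        fore = ivs[:8] + ivs[10:12]  # 8 present, 2 absent
        back = ivs[8:10] + ivs[12:]  # 2 present, 8 absent
        res = motif_presence_enrichment(fore, back, genome, AP1)
        # independent hypergeometric oracle for the two-sided Fisher p
        from math import comb

        def p_table(a):
            return comb(10, a) * comb(10, 10 - a) / comb(20, 10)

        obs = p_table(8)
        expected = sum(p_table(a) for a in range(11) if p_table(a) <= obs + 1e-12)
        assert res.p_value == pytest.approx(expected, rel=1e-6)
        assert res.p_value == pytest.approx(0.023, abs=0.001)

    def test_complete_separation_closed_form(self):
        from math import comb

        genome, ivs = self._genome_with(10, 10)
        res = motif_presence_enrichment(ivs[:10], ivs[10:], genome, AP1)
        assert res.p_value == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_null_pvalues_roughly_uniform(self, rng):
        # fore and back drawn from one pool -> p ~ U(0,1); KS-style check
        genome, ivs = self._genome_with(60, 60)
        ps = []
        for _ in range(200):
            perm = rng.permutation(len(ivs))
            fore = [ivs[i] for i in perm[:20]]
            back = [ivs[i] for i in perm[20:40]]
            ps.append(motif_presence_enrichment(fore, back, genome, AP1).p_value)
        # Fisher p-values are discrete and conservative; demand no excess
        # of small p-values beyond binomial noise
        assert np.mean(np.array(ps) < 0.05) < 0.09


class TestRelativeOverlapRatio:
    def test_formula_and_reference_bin(self, rng):
        chrom_sizes = {"chr1": 1_000_000}
        seqs, freqs = [], []
        for i in range(200):
            s = 1000 + 2000 * i
            seqs.append(GenomicInterval("chr1", s, s + 1000, name=f"s{i}"))
            freqs.append(0.0 if i % 2 == 0 else 2.0)
        # peaks covering every sequence -> all bins overlap fully
        peaks = AnnotationSet(
            [GenomicInterval("chr1", 0, 500_000)], label="peaks"
        )
        curve = relative_overlap_ratio(seqs, freqs, peaks, bins=[1.0, 3.0],
                                       chrom_sizes=chrom_sizes, seed=0)
        assert curve.r[0] == pytest.approx(1.0)
        # 100 zero-frequency and 100 bin-2 sequences inside the peak
        n_in = sum(1 for s in seqs if s.end <= 500_000)
        assert curve.n[0] + sum(curve.n[1:]) == n_in

    def test_empty_reference_bin_errors(self):
        seqs = [GenomicInterval("chr1", 0, 1000)]
        peaks = AnnotationSet([GenomicInterval("chr1", 0, 10_000)], label="p")
        with pytest.raises(ValueError, match="empty reference bin"):
            relative_overlap_ratio(seqs, [5.0], peaks, bins=[1.0],
                                   chrom_sizes={"chr1": 10_000}, seed=0)

    def test_planted_association_monotone_vs_shuffled_flat(self, rng):
        # peaks preferentially placed over motif-dense sequences
        chrom_sizes = {"chr1": 4_000_000}
        seqs, freqs, peaks = [], [], []
        for i in range(600):
            s = 2000 + 6000 * i
            f = float(rng.choice([0.0, 1.0, 3.0, 6.0]))
            seqs.append(GenomicInterval("chr1", s, s + 1000, name=f"s{i}"))
            freqs.append(f)
            p_overlap = 0.1 + 0.12 * f
            if rng.random() < p_overlap:
                peaks.append(GenomicInterval("chr1", s + 200, s + 800))
        curve = relative_overlap_ratio(
            seqs, freqs, AnnotationSet(peaks, label="tf"),
            bins=[0.5, 2.0, 4.0], chrom_sizes=chrom_sizes, seed=5,
        )
        observed = [r for r, n in zip(curve.r, curve.n) if n > 0]
        assert observed == sorted(observed)  # non-decreasing in frequency
        shuffled = [r for r, n in zip(curve.r_shuffled, curve.n_shuffled) if n > 0]
        assert max(shuffled) - min(shuffled) < 1.0  # flat-ish control
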