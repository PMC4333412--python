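import numpy as np
import pytest
from hypothesis import given, strategies as st

from nfatseq.io_formats import GenomeAssembly, Peak, ValidationError
from nfatseq.motif import (IUPAC_CODES, PWM, core_positions, core_score,
                           core_score_scan, dinucleotide_shuffle,
                           extract_peak_sequences, iupac_scan,
                           motif_enrichment, oops_em_discover, revcomp,
                           sample_peak_groups)
from nfatseq.synthetic import simulate_motif_sequences


def brute_force_scan(seq, pattern):
    """Independent enumeration of every offset and strand."""
    seq = seq.upper()
    hits = []
    for pat, strand in ((pattern, "+"), (revcomp(pattern), "-")):
        if strand == "-" and pat == pattern:
            pat = pattern  # palindrome: same offsets
        for i in range(len(seq) - len(pat) + 1):
            if all(seq[i + j] in IUPAC_CODES[c] for j, c in enumerate(pat)):
                hits.append((i, strand))
    return sorted(hits)


def make_genome(seq):
    return GenomeAssembly(["chr1"], {"chr1": len(seq)}, {"chr1": seq})


class TestExtraction:
    def test_window_is_201_bp_centered(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 10_000))
        genome = make_genome(seq)
        p = Peak("p1", "chr1", 400, 600, 500, 5.0)
        out = extract_peak_sequences([p], genome, 100)
        assert out["p1"] == seq[400:601] and len(out["p1"]) == 201

    def test_clipped_at_chromosome_start(self):
        seq = "ACGT" * 2500
        genome = make_genome(seq)
        p = Peak("p1", "chr1", 0, 100, 50, 5.0)
        out = extract_peak_sequences([p], genome, 100)
        assert out["p1"] == seq[0:151] and len(out["p1"]) == 151

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValidationError):
            extract_peak_sequences([Peak("p1", "chrX", 0, 10, 5, 1.0)],
                                   make_genome("ACGTACGTACGT"), 5)


class TestSampling:
    def make_peaks(self, n):
        return [Peak(f"p{i}", "chr1", i * 10, i * 10 + 5, i * 10 + 2, 1.0)
                for i in range(n)]

    def test_deterministic_under_seed(self):
        peaks = self.make_peaks(1000)
        assert sample_peak_groups(peaks, 100, 3, seed=1) == \
            sample_peak_groups(peaks, 100, 3, seed=1)

    def test_group_of_all_peaks_is_permutation(self):
        peaks = self.make_peaks(50)
        (grp,) = sample_peak_groups(peaks, 50, 1, seed=2)
        assert sorted(grp) == sorted(p.peak_id for p in peaks)
        assert len(set(grp)) == 50  # without replacement

    def test_insufficient_peaks_rejected(self):
        with pytest.raises(ValidationError, match="lower n"):
            sample_peak_groups(self.make_peaks(10), 600)

    def test_sampling_is_uniform(self):
        from scipy import stats
        peaks = self.make_peaks(20)
        counts = np.zeros(20)
        for seed in range(500):
            (grp,) = sample_peak_groups(peaks, 5, 1, seed=seed)
            for pid in grp:
                counts[int(pid[1:])] += 1
        assert stats.chisquare(counts).pvalue > 0.01


class TestIUPACScan:
    def test_plus_strand_hit(self):
        hits = iupac_scan("TTGGAAAATT", "GGAAAA")
        assert [(h.offset, h.strand) for h in hits] == [(2, "+")]

    def test_minus_strand_hit(self):
        hits = iupac_scan("TTTTTCCTT", "GGAAAA")
        assert [(h.offset, h.strand, h.matched) for h in hits] == [(1, "-", "TTTTCC")]

    def test_degenerate_codes_match(self):
        assert any(h.strand == "+" for h in
                   iupac_scan("CACTGGAAAAGG", "NANWGGAAAANN"))

    def test_invalid_code_rejected(self):
        with pytest.raises(ValidationError):
            iupac_scan("ACGT", "GGXAAA")

    @given(st.text(alphabet="ACGT", min_size=6, max_size=200),
           st.sampled_from(["GGAAAA", "NANWGGAAAANN", "RYSWKM", "TTAA"]))
    def test_matches_brute_force_enumeration(self, seq, pattern):
        got = sorted((h.offset, h.strand) for h in iupac_scan(seq, pattern))
        assert got == brute_force_scan(seq, pattern)


class TestEnrichment:
    def test_null_when_background_equals_foreground(self):
        seqs, _ = simulate_motif_sequences(50, 100, seed=1, plant_rate=0.5)
        res = motif_enrichment(seqs, "GGAAAA", bg_sequences=seqs,
                               n_shuffles=50, seed=0)
        assert res["p_value"] > 0.05
        assert res["ratio"] == pytest.approx(1.0, abs=0.25)

    def test_minimum_attainable_p(self):
        seqs, _ = simulate_motif_sequences(30, 80, seed=2, plant_rate=1.0)
        res = motif_enrichment(seqs, "GGAAAA", n_shuffles=50, seed=0)
        assert res["p_value"] >= 1 / 51

    def test_dinucleotide_shuffle_preserves_composition(self):
        rng = np.random.default_rng(0)
        seqs, _ = simulate_motif_sequences(20, 60, seed=3)
        for s in seqs.values():
            t = dinucleotide_shuffle(s, rng)
            pairs = lambda x: sorted(zip(x, x[1:]))
            assert pairs(t) == pairs(s)
            assert t[0] == s[0] and t[-1] == s[-1]


class TestOOPSEM:
    def test_recovers_planted_motif(self):
        seqs, _ = simulate_motif_sequences(60, 80, seed=4, plant_rate=1.0)
        _, cons, info = oops_em_discover(seqs, width=6, seed=0, n_restarts=3)
        assert cons == "GGAAAA"
        assert info["gain_bits_per_sequence"] > 2

    def test_deterministic_under_seed(self):
        seqs, _ = simulate_motif_sequences(30, 60, seed=5, plant_rate=1.0)
        p1, c1, _ = oops_em_discover(seqs, width=6, seed=9, n_restarts=2)
        p2, c2, _ = oops_em_discover(seqs, width=6, seed=9, n_restarts=2)
        assert c1 == c2 and np.array_equal(p1.probs, p2.probs)

    def test_background_only_data_gains_little(self):
        seqs, _ = simulate_motif_sequences(40, 80, seed=6, plant_rate=0.0)
        _, _, info = oops_em_discover(seqs, width=6, seed=0, n_restarts=2)
        assert info["gain_bits_per_sequence"] < 2

    def test_pwm_columns_are_distributions(self):
        seqs, _ = simulate_motif_sequences(30, 60, seed=7, plant_rate=0.5)
        pwm, _, _ = oops_em_discover(seqs, width=6, seed=0, n_restarts=2)
        np.testing.assert_allclose(pwm.probs.sum(axis=1), 1.0)
        assert (pwm.probs >= 0).all()

    def test_reverse_complement_symmetry(self):
        """Every EM step is equivariant under reverse complement, so
        mirrored starting points must converge to the mirrored motif."""
        seqs, _ = simulate_motif_sequences(60, 80, seed=8, plant_rate=1.0)
        rng = np.random.default_rng(0)
        inits = []
        for _ in range(3):
            mat = rng.dirichlet([1.0] * 4, size=6)
            inits.append(mat)
        _, cons_fwd, _ = oops_em_discover(seqs, width=6, seed=0, init_pwms=inits)
        rc_seqs = {k: revcomp(s) for k, s in seqs.items()}
        rc_inits = [m[::-1, ::-1] for m in inits]  # reverse positions, complement bases
        _, cons_rc, _ = oops_em_discover(rc_seqs, width=6, seed=0, init_pwms=rc_inits)
        assert cons_rc == revcomp(cons_fwd)


def strong_pwm(consensus, p=0.91):
    mat = np.full((len(consensus), 4), (1 - p) / 3)
    for i, b in enumerate(consensus):
        mat[i, "ACGT".index(b)] = p
    return PWM(mat)


class TestCoreScoreScan:
    def test_core_is_most_informative_stretch(self):
        # uniform flanks around a sharp 5-mer core
        mat = np.full((9, 4), 0.25)
        for i, b in enumerate("GGAAA"):
            mat[2 + i] = [0.01] * 4
            mat[2 + i, "ACGT".index(b)] = 0.97
        mat /= mat.sum(axis=1, keepdims=True)
        assert core_positions(PWM(mat)) == (2, 7)

    def test_perfect_core_match_scores_one(self):
        pwm = strong_pwm("GGAAAA")
        assert core_score("GGAAAA", pwm) == pytest.approx(1.0)

    def test_single_core_mismatch_fails_cutoff_one(self):
        pwm = strong_pwm("GGAAAA")
        lo, hi = core_positions(pwm)
        s = list("GGAAAA")
        s[lo] = "C"
        assert core_score("".join(s), pwm) < 1.0

    def test_counts_match_brute_force_rescoring(self):
        rng = np.random.default_rng(1)
        pwm = strong_pwm("GGAAAA")
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), 60)) + "GGAAAA"
                for i in range(10)}
        res = core_score_scan(seqs, {"nfat": pwm}, core_cutoff=1.0).iloc[0]
        expected = 0
        for s in seqs.values():
            for target in (s, revcomp(s)):
                for off in range(len(target) - pwm.width + 1):
                    if core_score(target[off:off + pwm.width], pwm) >= 1.0:
                        expected += 1
        assert res["n_hits"] == expected
        assert res["n_sequences_with_hit"] == 10

    def test_narrow_pwm_rejected(self):
        with pytest.raises(ValidationError):
            core_positions(strong_pwm("GGAA"))
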