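"""PWM loading, promoter windows, log-odds scanning and hit fractions."""

import numpy as np
import pandas as pd
import pytest

from rescue_seq import (
    SyntheticConfig,
    are_fraction,
    consensus_counts,
    define_promoters,
    extract_promoters,
    load_pwm,
    pwm_from_counts,
    reverse_complement,
    scan_promoters,
    scan_sequence,
    simulate_promoters,
)
from rescue_seq.motif import ALPHABET


def scan_oracle(seq, pwm, threshold):
    """Exhaustive enumeration over every offset and both strands."""
    seq = seq.upper()
    lo = pwm.log_odds
    out = []
    for off in range(len(seq) - len(pwm) + 1):
        window = seq[off:off + len(pwm)]
        if "N" in window:
            continue
        fwd = sum(lo[i, ALPHABET.index(b)] for i, b in enumerate(window))
        rev = sum(lo[i, ALPHABET.index(b)]
                  for i, b in enumerate(reverse_complement(window)))
        if fwd >= threshold:
            out.append((off, "+", fwd))
        if rev >= threshold:
            out.append((off, "-", rev))
    return sorted(out, key=lambda h: (h[0], h[1]))


class TestLoadPwm:
    def test_pure_counts_no_pseudocount(self):
        pwm = load_pwm(">M1\nA 10\nC 0\nG 0\nT 0\n", pseudocount=0.0)
        np.testing.assert_allclose(pwm.probs, [[1.0, 0.0, 0.0, 0.0]])

    def test_pseudocount_hand_arithmetic(self):
        pwm = load_pwm("A 3\nC 1\nG 0\nT 0\n", pseudocount=1.0)
        np.testing.assert_allclose(pwm.probs, [[0.5, 0.25, 0.125, 0.125]])

    def test_jaspar_bracket_format(self):
        text = ">MA0007.2 AR\nA [ 3 10 ]\nC [ 1 0 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        pwm = load_pwm(text, pseudocount=0.0)
        assert pwm.motif_id == "MA0007.2"
        assert len(pwm) == 2

    def test_missing_row_rejected(self):
        with pytest.raises(ValueError):
            load_pwm("A 1\nC 1\nG 1\n")

    def test_unequal_rows_rejected(self):
        with pytest.raises(ValueError):
            load_pwm("A 1 2\nC 1\nG 1 2\nT 1 2\n")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            pwm_from_counts(np.array([[-1.0, 1, 1, 1]]))

    def test_unknown_row_label_rejected(self):
        with pytest.raises(ValueError):
            load_pwm("A 1\nC 1\nG 1\nX 1\n")


class TestDefinePromoters:
    def _table(self, gene, strand, tss):
        return pd.DataFrame([{"gene": gene, "chrom": "chr1", "strand": strand,
                              "tss": tss}])

    def test_plus_strand_window(self):
        (r,) = define_promoters(self._table("g", "+", 5000))
        assert (r.start, r.end) == (4000, 5100)

    def test_minus_strand_window(self):
        (r,) = define_promoters(self._table("g", "-", 5000))
        assert (r.start, r.end) == (4900, 6000)

    def test_truncated_at_contig_start(self):
        (r,) = define_promoters(self._table("g", "+", 200))
        assert (r.start, r.end) == (0, 300)

    def test_tss_beyond_contig_rejected(self):
        with pytest.raises(ValueError):
            define_promoters(self._table("g", "+", 900), contig_lengths={"chr1": 500})

    def test_bad_strand_rejected(self):
        with pytest.raises(ValueError):
            define_promoters(self._table("g", ".", 100))

    def test_extraction_orients_minus_strand(self):
        contig = {"chr1": "A" * 10 + "CGT" + "A" * 10}
        regions = define_promoters(
            self._table("g", "-", 10), upstream=3, downstream=0,
            contig_lengths={"chr1": 23})
        seqs = extract_promoters(regions, contig)
        assert seqs["g"] == reverse_complement(contig["chr1"][10:13])


class TestScanSequence:
    def test_uniform_pwm_scores_zero_everywhere(self):
        pwm = pwm_from_counts(np.ones((2, 4)), pseudocount=0.0)
        hits = scan_sequence("ACGTACGT", pwm, threshold=0.0)
        assert len(hits) == 14  # every offset, both strands
        assert all(h.score == 0.0 for h in hits)

    def test_dimer_hand_enumeration(self):
        # AA motif on AATT: forward hit at 0; TT hit on the reverse strand at 2
        pwm = pwm_from_counts(np.array([[1.0, 0, 0, 0], [1.0, 0, 0, 0]]),
                              pseudocount=0.0)
        hits = scan_sequence("AATT", pwm, threshold=3.9)
        assert [(h.offset, h.strand) for h in hits] == [(0, "+"), (2, "-")]
        assert hits[0].score == pytest.approx(4.0)  # 2 x log2(1/0.25)

    def test_windows_with_n_skipped(self):
        pwm = pwm_from_counts(np.ones((2, 4)), pseudocount=0.0)
        hits = scan_sequence("ANA", pwm, threshold=-10.0)
        assert hits == []

    def test_sequence_shorter_than_motif(self):
        pwm = pwm_from_counts(np.ones((5, 4)), pseudocount=0.0)
        assert scan_sequence("ACG", pwm, threshold=-10.0) == []

    def test_invalid_base_rejected(self):
        pwm = pwm_from_counts(np.ones((2, 4)))
        with pytest.raises(ValueError):
            scan_sequence("ACGU", pwm, threshold=0.0)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            width = int(rng.integers(1, 5))
            length = int(rng.integers(width, 51))
            pwm = pwm_from_counts(rng.integers(0, 20, size=(width, 4)).astype(float),
                                  pseudocount=0.5)
            seq = "".join(rng.choice(list("ACGTN"), size=length,
                                     p=[0.23, 0.23, 0.23, 0.23, 0.08]))
            threshold = float(rng.uniform(-3.0, pwm.max_score()))
            mine = [(h.offset, h.strand, h.score)
                    for h in scan_sequence(seq, pwm, threshold)]
            expect = scan_oracle(seq, pwm, threshold)
            assert len(mine) == len(expect)
            for a, b in zip(mine, expect):
                assert a[:2] == b[:2]
                assert a[2] == pytest.approx(b[2], abs=1e-9)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(9)
        pwm = pwm_from_counts(rng.integers(0, 10, size=(4, 4)).astype(float),
                              pseudocount=0.5)
        seq = "".join(rng.choice(list("ACGT"), size=40))
        fwd = sorted(round(h.score, 9) for h in scan_sequence(seq, pwm, -50.0))
        rev = sorted(round(h.score, 9)
                     for h in scan_sequence(reverse_complement(seq), pwm, -50.0))
        assert fwd == rev


class TestPlantedPromoters:
    def test_planted_motifs_all_recovered(self):
        cfg = SyntheticConfig(seed=3)
        promoters, truth = simulate_promoters(cfg)
        pwm = pwm_from_counts(consensus_counts(cfg.motif_consensus), "ARE")
        hits = scan_promoters(promoters, pwm, rel_threshold=0.8)
        hit_genes = set(hits["gene_id"])
        planted = set(truth.index[truth["planted"]])
        assert planted <= hit_genes  # sensitivity 1.0 at 80% of max score

    def test_background_rate_matches_analytic(self):
        """On motif-free uniform sequence, the per-window hit probability
        equals the exact score-distribution convolution."""
        cfg = SyntheticConfig(seed=6, planted_motif_fraction=0.0,
                              motif_consensus="GGTACA", n_promoters=300)
        promoters, _ = simulate_promoters(cfg)
        pwm = pwm_from_counts(consensus_counts(cfg.motif_consensus, match=10, mismatch=2),
                              pseudocount=0.0)
        threshold = 0.55 * pwm.max_score()
        # exact null distribution of the window score by convolution
        dist = {0.0: 1.0}
        for row in pwm.log_odds:
            new = {}
            for s, prob in dist.items():
                for b in range(4):
                    key = round(s + row[b], 9)
                    new[key] = new.get(key, 0.0) + prob * 0.25
            dist = new
        p_window = sum(prob for s, prob in dist.items() if s >= threshold - 1e-9)
        n_windows = 2 * (cfg.promoter_length - len(pwm) + 1) * cfg.n_promoters
        hits = scan_promoters(promoters, pwm, abs_threshold=threshold)
        expected = n_windows * p_window
        assert len(hits) == pytest.approx(expected, abs=4 * np.sqrt(expected))

    def test_are_fraction_counting(self):
        hits = pd.DataFrame({"gene_id": ["g1", "g1", "g3"]})
        res = are_fraction(["g1", "g2", "g3", "g4"], hits)
        assert res["n_with_hit"] == 2
        assert res["fraction"] == 0.5

    def test_are_fraction_with_missing_promoters(self):
        hits = pd.DataFrame({"gene_id": ["g1"]})
        res = are_fraction(["g1", "g2", "g5"], hits, available={"g1", "g2"})
        assert res["n_missing_promoter"] == 1
        assert res["fraction"] == 0.5

    def test_empty_gene_list_rejected(self):
        with pytest.raises(ValueError):
            are_fraction([], pd.DataFrame({"gene_id": []}))
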