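"""PWM scanning, initiation anchors, central enrichment, motif profiles."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ernascope.io_formats import SignalTrack
from ernascope.motifs import (
    PWMMotif,
    anchor_initiation_max,
    central_enrichment,
    default_inr_pwm,
    positional_motif_profile,
    revcomp,
    scan_pwm,
)

from conftest import element, make_track

DNA = st.text(alphabet="ACGT", min_size=8, max_size=60)


def one_hot_pwm(consensus, p=0.997):
    rows = []
    off = (1 - p) / 3
    for b in consensus:
        rows.append([p if x == b else off for x in "ACGT"])
    return PWMMotif(probs=np.array(rows), name="onehot")


class TestScanPwm:
    def test_background_pwm_scores_zero(self):
        pwm = PWMMotif(probs=np.tile(0.25, (4, 4)))
        scores, best = scan_pwm("ACGTACGT", pwm)
        np.testing.assert_allclose(scores, 0.0)
        assert best == 0  # leftmost tie

    def test_one_hot_match_score(self):
        # 4 matched bases at probability 0.997 over uniform background
        pwm = one_hot_pwm("TCAG")
        scores, best = scan_pwm("TCAG", pwm)
        assert best == 0
        assert scores[0] == pytest.approx(4 * math.log2(0.997 / 0.25), abs=1e-9)

    def test_n_contributes_zero(self):
        pwm = one_hot_pwm("TCAG")
        scores, _ = scan_pwm("NNNN", pwm)
        assert scores[0] == 0.0

    def test_too_short_sequence(self):
        with pytest.raises(ValueError):
            scan_pwm("AC", one_hot_pwm("TCAG"))

    def test_minus_strand_offsets_in_original_frame(self):
        pwm = one_hot_pwm("TCAG")
        seq = "AAAA" + revcomp("TCAG") + "AAAA"
        scores, best = scan_pwm(seq, pwm, strand="-")
        assert best == 4  # leftmost base of the reverse-strand site

    @given(DNA)
    @settings(max_examples=100, deadline=None)
    def test_revcomp_strand_swap_symmetry(self, seq):
        pwm = default_inr_pwm()
        if len(seq) < pwm.width:
            return
        s_plus, _ = scan_pwm(seq, pwm, "+")
        s_minus_rc, _ = scan_pwm(revcomp(seq), pwm, "-")
        assert max(s_plus) == pytest.approx(max(s_minus_rc), abs=1e-9)


class TestAnchor:
    def test_argmax_position(self):
        t = make_track([("c", "+", 100, 3), ("c", "+", 120, 7)])
        a = anchor_initiation_max(t, element(0, 250, chrom="c", summit=110),
                                  "+", 100)
        assert a.position == 120

    def test_leftmost_tie(self):
        t = make_track([("c", "+", 100, 5), ("c", "+", 120, 5)])
        a = anchor_initiation_max(t, element(0, 250, chrom="c", summit=110),
                                  "+", 100)
        assert a.position == 100

    def test_empty_window_skipped(self):
        a = anchor_initiation_max(
            SignalTrack(), element(0, 250, chrom="c", summit=110), "+", 100
        )
        assert a is None


def exact_binom_upper_tail(k, n, p):
    """Independent oracle: direct summation of binomial pmf terms."""
    return sum(
        math.comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(k, n + 1)
    )


class TestCentralEnrichment:
    def test_motif_width_shrinks_valid_offsets(self):
        # hw=2, width 1: 5 valid offsets, central hw=1 covers 3
        assert central_enrichment([0], 2, 1).p_null == pytest.approx(3 / 5)
        # width 3: valid starts [-2, 0] -> 3, central starts [-1, 0] -> 2
        assert central_enrichment([0], 2, 1, motif_width=3).p_null == (
            pytest.approx(2 / 3)
        )

    def test_all_central_is_pnull_power_n(self):
        # when every site is central the upper tail is the single term
        # p_null^n; hw=7, central hw=1 gives p_null = 3/15 = 0.2, so
        # 10 central sites of 10 give p = 0.2^10 = 1.024e-7
        res = central_enrichment([0] * 10, 7, 1)
        assert res.p_null == pytest.approx(0.2)
        assert res.p_value == pytest.approx(0.2 ** 10, rel=1e-9)
        assert res.p_value == pytest.approx(1.024e-7, rel=1e-9)

    def test_zero_central_full_tail(self):
        res = central_enrichment([100] * 7, 200, 50)
        assert res.n_central == 0 and res.p_value == pytest.approx(1.0)

    def test_central_equals_window_gives_one(self):
        res = central_enrichment([0, 1, -1], 50, 50)
        assert res.p_value == 1.0

    def test_matches_pmf_summation_oracle(self):
        offsets = [0, 3, -40, 120, 7, -2, 99, 1, 0, -60]
        res = central_enrichment(offsets, 250, 50, motif_width=6)
        assert res.p_value == pytest.approx(
            exact_binom_upper_tail(res.n_central, res.n_total, res.p_null),
            rel=1e-9,
        )

    def test_window_ladder_bonferroni(self):
        from ernascope.motifs import central_enrichment_ladder

        offsets = [0, 2, -3, 1, 0, 150, -200]
        results, best, adjusted = central_enrichment_ladder(
            offsets, 250, [10, 50, 100]
        )
        assert len(results) == 3
        assert best.p_value == min(r.p_value for r in results)
        assert adjusted == pytest.approx(min(1.0, best.p_value * 3))

    def test_invalid_central_width(self):
        with pytest.raises(ValueError):
            central_enrichment([0], 50, 60)

    @given(st.integers(1, 60), st.integers(0, 60))
    @settings(max_examples=60, deadline=None)
    def test_monotone_decreasing_in_central_count(self, n_total, n_central):
        n_central = min(n_central, n_total)
        offsets = [0] * n_central + [200] * (n_total - n_central)
        p1 = central_enrichment(offsets, 250, 50).p_value
        if n_central < n_total:
            offsets2 = [0] * (n_central + 1) + [200] * (n_total - n_central - 1)
            p2 = central_enrichment(offsets2, 250, 50).p_value
            assert p2 <= p1 + 1e-12


class TestPositionalProfile:
    def _genome_with_planted(self, rng, pattern="AATAAA", offset=-30,
                             length=2001):
        seq = rng.choice(list("CG"), size=length)  # AT-free background
        center = length // 2
        start = center + offset
        seq[start:start + len(pattern)] = list(pattern)
        return {"c": "".join(seq)}

    def test_planted_spike_at_offset(self, rng):
        genome = self._genome_with_planted(rng)
        els = [element(900, 1100, chrom="c", summit=1000)]
        df = positional_motif_profile(els, "AATAAA", genome,
                                      window_halfwidth=250)
        hit = df.loc[df["frequency"] > 0, "offset"]
        assert list(hit) == [-30]

    def test_uniform_background_frequency(self, rng):
        # expected per-offset frequency of a 6-mer in uniform sequence: 4^-6
        n, hw = 400, 250
        genome = {"c": "".join(rng.choice(list("ACGT"), size=300_000))}
        els = [element(i * 700 + 300, i * 700 + 500, chrom="c",
                       summit=i * 700 + 400, id=f"e{i}") for i in range(n)]
        df = positional_motif_profile(els, "AATAAA", genome,
                                      window_halfwidth=hw)
        p = 0.25 ** 6
        mean_freq = df["frequency"].mean()
        sd = math.sqrt(p * (1 - p) / (n * len(df)))
        assert abs(mean_freq - p) < 3 * sd

    def test_empty_elements(self):
        df = positional_motif_profile([], "AATAAA", {"c": "ACGT" * 100})
        assert (df["frequency"] == 0).all()
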