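"""Expectation scoring, inhibition classification, transcript scanning."""

import pytest

from conftest import random_dna
from oracles import best_window_expectation

from mir166kit.synthetic import build_target_site, generate_transcripts
from mir166kit.targets import (
    DEFAULT_WEIGHTS,
    align_window,
    classify_inhibition,
    scan_transcripts,
    score_duplex,
)
from mir166kit.seq import revcomp

MIRNA = "UCGGACCAGGCUUCAUUCCCC"  # 21 nt


def _site_with_edit(mirna, position, new_base):
    site = list(revcomp(mirna))
    site[len(mirna) - position] = new_base
    return "".join(site)


class TestScoreDuplex:
    def test_perfect_complement_is_zero(self):
        aln = align_window(MIRNA, revcomp(MIRNA))
        assert score_duplex(aln) == 0.0
        assert all(s == "WC" for s in aln.states)

    def test_non_seed_mismatch_costs_one(self):
        # position 15 pairs an A; plant a non-pairing C
        site = _site_with_edit(MIRNA, 15, "C")
        aln = align_window(MIRNA, site)
        assert aln.states[14] == "mismatch"
        assert score_duplex(aln) == 1.0

    def test_seed_gu_wobble_doubled(self):
        # miRNA position 5 is A in this miRNA; use position 4 (G): G:U = T
        assert MIRNA[3] == "G"
        site = _site_with_edit(MIRNA, 4, "T")
        aln = align_window(MIRNA, site)
        assert aln.states[3] == "GU"
        assert score_duplex(aln) == 1.0  # 0.5 x 2 (seed)

    def test_seed_doubling_of_single_mismatch(self):
        non_seed = align_window(MIRNA, _site_with_edit(MIRNA, 15, "C"))
        seed = align_window(MIRNA, _site_with_edit(MIRNA, 5, "C"))
        assert score_duplex(seed) == 2 * score_duplex(non_seed)

    def test_adding_penalty_never_decreases_expectation(self):
        site = revcomp(MIRNA)
        base = score_duplex(align_window(MIRNA, site))
        for pos in (1, 5, 9, 15, 21):
            worse = align_window(MIRNA, _site_with_edit(MIRNA, pos, "C"))
            assert score_duplex(worse) >= base
            base_site = _site_with_edit(MIRNA, pos, "C")
            even_worse = list(base_site)
            # stack a second edit on a different position
            other = 10 if pos != 10 else 12
            even_worse[len(MIRNA) - other] = "C"
            aln2 = align_window(MIRNA, "".join(even_worse))
            assert score_duplex(aln2) >= score_duplex(
                align_window(MIRNA, base_site)
            )

    def test_bulge_penalties(self):
        site = revcomp(MIRNA)
        aln = align_window(MIRNA, site[1:], bulge=("mirna", 21))
        # bulged miRNA position 21 (non-seed): 2.0
        assert score_duplex(aln) == pytest.approx(2.0)


class TestClassifyInhibition:
    def test_perfect_duplex_is_cleavage(self):
        assert classify_inhibition(align_window(MIRNA, revcomp(MIRNA))) == "cleavage"

    def test_central_mismatch_is_translation(self):
        aln = align_window(MIRNA, _site_with_edit(MIRNA, 10, "A"))
        assert classify_inhibition(aln) == "translation"

    def test_peripheral_mismatch_is_cleavage(self):
        aln = align_window(MIRNA, _site_with_edit(MIRNA, 2, "C"))
        assert classify_inhibition(aln) == "cleavage"


class TestScanTranscripts:
    def test_exact_complement_found_with_zero_expectation(self):
        t = "GG" + revcomp(MIRNA) + "AAGG"
        sites = scan_transcripts("m", MIRNA, {"t1": t}, cutoff=5.0)
        assert len(sites) == 1
        assert sites[0].expectation == 0.0
        assert sites[0].transcript_span == (3, 3 + len(MIRNA) - 1)

    def test_planted_penalties_recovered_below_cutoff(self):
        spec = [
            ("m", "t1", 0.0),
            ("m", "t2", 1.0),
            ("m", "t3", 3.0),
            ("m", "t4", 6.0),
        ]
        transcripts, truth = generate_transcripts(
            {"m": MIRNA}, spec, transcript_len=200, seed=4
        )
        sites = scan_transcripts("m", MIRNA, transcripts, cutoff=5.0)
        assert sorted(s.expectation for s in sites) == [0.0, 1.0, 3.0]
        by_t = {s.transcript_id: s for s in sites}
        for t in truth:
            if t.penalty <= 5.0:
                site = by_t[t.transcript_id]
                assert site.transcript_span == (t.start, t.end)

    def test_cutoff_zero_keeps_only_perfect_sites(self):
        transcripts, _ = generate_transcripts(
            {"m": MIRNA}, [("m", "t1", 0.0), ("m", "t2", 2.0)],
            transcript_len=120, seed=1,
        )
        sites = scan_transcripts("m", MIRNA, transcripts, cutoff=0.0)
        assert [s.expectation for s in sites] == [0.0]

    def test_agrees_with_ungapped_window_bruteforce(self, rng):
        for _ in range(5):
            t = random_dna(rng, 60)
            brute = best_window_expectation(MIRNA, t, DEFAULT_WEIGHTS)
            sites = scan_transcripts("m", MIRNA, {"t": t}, cutoff=1e9)
            best = min(s.expectation for s in sites)
            assert best <= brute  # bulge variants may only improve

    def test_empty_transcript_set(self):
        assert scan_transcripts("m", MIRNA, {}, cutoff=5.0) == []

    def test_negative_penalty_rejected_by_generator(self):
        with pytest.raises(ValueError):
            build_target_site(MIRNA, -1.0)

    def test_unachievable_penalty_rejected(self):
        with pytest.raises(ValueError):
            build_target_site("CCCCCCCCCCCCCCCCCCCCC", 0.5)  # no G/U wobble
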