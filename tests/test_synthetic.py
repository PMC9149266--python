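"""Ground-truth generators: determinism, invariants, round-trips."""

import numpy as np
import pytest

from mir166kit import references
from mir166kit.hairpin import characterize
from mir166kit.homology import scan_genome
from mir166kit.promoter import DEFAULT_MOTIFS, MotifDefinition
from mir166kit.seq import revcomp
from mir166kit.synthetic import (
    default_reference_precursors,
    generate_genome,
    generate_promoters,
    generate_transcripts,
    rescan_matrix,
    synthesize_precursor,
)


class TestGenerateGenome:
    def test_zero_mutation_implants_are_identical_copies(self):
        refs = {"pre": synthesize_precursor(references.MATURE_MIR166["Vco-miR166g-3p"], seed=1)}
        genome, truths = generate_genome(
            refs, n_scaffolds=1, scaffold_len=1000, n_implants=1,
            mutation_rate=0.0, seed=7,
        )
        (t,) = truths
        assert t.mutation_count == 0
        region = genome[t.scaffold_id][t.start - 1 : t.end]
        if t.strand == "-":
            region = revcomp(region)
        assert region == refs["pre"]

    def test_observed_divergence_near_requested_rate(self):
        refs = default_reference_precursors(seed=5)
        genome, truths = generate_genome(
            refs, n_scaffolds=2, scaffold_len=3000, n_implants=5,
            mutation_rate=0.05, seed=1,
        )
        assert len(truths) == 5
        total_len = total_mut = 0
        for t in truths:
            length = t.end - t.start + 1
            total_len += length
            total_mut += t.mutation_count
            assert t.mutation_count <= length
        rate = total_mut / total_len
        # binomial error band around 5% for ~460 trials
        assert 0.02 <= rate <= 0.09

    def test_truth_intervals_never_overlap(self):
        refs = default_reference_precursors(seed=2)
        _, truths = generate_genome(
            refs, n_scaffolds=1, scaffold_len=2000, n_implants=8,
            mutation_rate=0.0, seed=2,
        )
        by_scaffold = {}
        for t in truths:
            by_scaffold.setdefault(t.scaffold_id, []).append((t.start, t.end))
        for spans in by_scaffold.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 < s2

    def test_same_seed_is_byte_identical(self):
        refs = default_reference_precursors(seed=3)
        g1, t1 = generate_genome(refs, seed=42)
        g2, t2 = generate_genome(refs, seed=42)
        assert g1 == g2 and t1 == t2

    def test_saturating_mutation_defeats_the_scan(self):
        refs = default_reference_precursors(seed=9)
        genome, _ = generate_genome(
            refs, n_scaffolds=1, scaffold_len=2000, n_implants=3,
            mutation_rate=0.9, seed=9,
        )
        hits, _ = scan_genome(refs, genome, min_identity=0.9)
        assert hits == []

    def test_impossible_placement_raises(self):
        refs = {"pre": "ACGT" * 50}  # 200 nt
        with pytest.raises((RuntimeError, ValueError)):
            generate_genome(
                refs, n_scaffolds=1, scaffold_len=250, n_implants=5,
                mutation_rate=0.0, seed=0,
            )

    def test_synthesized_precursors_are_screenable_hairpins(self):
        refs = default_reference_precursors(seed=0)
        for rid, seq in refs.items():
            cand = characterize(rid, seq, mature_refs=references.MATURE_MIR166)
            assert cand.is_simple_stemloop
            assert cand.nm is not None and cand.nm <= 2
            assert any(m.arm == "3p" for m in cand.matures)


class TestGeneratePromoters:
    def test_spec_matrix_round_trip_exact(self):
        spec = references.promoter_element_matrix()
        seqs, truth = generate_promoters(spec, promoter_len=1600, seed=11)
        assert len(seqs) == 9
        assert all(len(s) == 1600 for s in seqs.values())
        assert rescan_matrix(seqs).loc[spec.index, spec.columns].equals(spec)

    def test_all_false_spec_contains_no_motif(self):
        spec = references.promoter_element_matrix().iloc[:3] & False
        seqs, truth = generate_promoters(spec, promoter_len=600, seed=3)
        assert truth == []
        assert not rescan_matrix(seqs).any().any()

    def test_single_true_cell_positions_are_recoverable(self):
        spec = references.promoter_element_matrix().iloc[:1] & False
        spec.loc[:, "anaerobic induction"] = True
        seqs, truth = generate_promoters(spec, promoter_len=400, seed=5)
        (planted,) = truth
        from mir166kit.promoter import scan_promoter

        hits = scan_promoter(next(iter(seqs.values())), DEFAULT_MOTIFS)
        assert any(
            h.motif == planted.motif
            and h.position == planted.position
            and h.strand == planted.strand
            for h in hits
        )

    def test_non_iupac_motif_rejected(self):
        with pytest.raises(ValueError):
            MotifDefinition("bad", "ACGX", "anaerobic induction")

    def test_determinism(self):
        spec = references.promoter_element_matrix().iloc[:4]
        s1, t1 = generate_promoters(spec, promoter_len=500, seed=8)
        s2, t2 = generate_promoters(spec, promoter_len=500, seed=8)
        assert s1 == s2 and t1 == t2


class TestGenerateTranscripts:
    def test_planted_site_scores_exactly_as_requested(self):
        from mir166kit.targets import align_window, score_duplex

        m = references.MATURE_MIR166["Vco-miR166g-3p"]
        transcripts, truth = generate_transcripts(
            {"g": m}, [("g", "t1", 0.0), ("g", "t2", 1.0)], transcript_len=120,
            seed=2,
        )
        for t in truth:
            window = transcripts[t.transcript_id][t.start - 1 : t.end]
            assert score_duplex(align_window(m, window)) == t.penalty
        perfect = [t for t in truth if t.penalty == 0.0][0]
        site = transcripts[perfect.transcript_id][perfect.start - 1 : perfect.end]
        assert site == revcomp(m)

    def test_determinism(self):
        m = references.MATURE_MIR166["Vco-miR166g-3p"]
        spec = [("g", "t1", 1.5)]
        assert generate_transcripts({"g": m}, spec, seed=4) == generate_transcripts(
            {"g": m}, spec, seed=4
        )
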