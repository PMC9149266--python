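"""Folding, MFEI arithmetic, arm extraction, NM counting, mature placement."""

import numpy as np
import pytest

from conftest import random_rna
from oracles import min_energy_bruteforce

from mir166kit import hairpin, references
from mir166kit.hairpin import (
    FoldResult,
    HairpinCandidate,
    NotStemLoopError,
    count_duplex_mismatches,
    extract_arms,
    fold,
    gc_content,
    locate_mature,
    mfei,
    screen_candidates,
)
from mir166kit.seq import revcomp, to_rna


class TestFold:
    def test_triloop_hairpin(self):
        f = fold("GGGAAACCC", min_loop=3)
        assert f.structure == "(((...)))"
        assert f.mfe == pytest.approx(-9.0)

    def test_unpairable_sequence_stays_open(self):
        f = fold("AAAAAA")
        assert f.structure == "......"
        assert f.mfe == 0.0

    def test_short_sequence_returns_open_structure(self):
        f = fold("GAC", min_loop=3)
        assert f.structure == "..."
        assert f.mfe == 0.0

    def test_reversal_symmetry(self, rng):
        # the pair-energy table is symmetric, so reversing the sequence
        # mirrors every structure (reverse-complementation would not: a G:U
        # wobble maps to C:A, which cannot pair)
        for _ in range(20):
            s = random_rna(rng, int(rng.integers(6, 30)))
            assert fold(s).mfe == pytest.approx(fold(s[::-1]).mfe)

    def test_matches_bruteforce_enumeration_small(self, rng):
        for _ in range(30):
            s = random_rna(rng, int(rng.integers(5, 13)))
            assert fold(s).mfe == pytest.approx(min_energy_bruteforce(s))

    def test_structure_is_consistent_with_pairs(self, rng):
        s = random_rna(rng, 40)
        f = fold(s)
        assert len(f.structure) == len(s)
        assert f.structure.count("(") == len(f.pairs)
        for i, j in f.pairs:
            assert (f.sequence[i - 1], f.sequence[j - 1]) in hairpin.PAIR_ENERGY
            assert j - i > hairpin.MIN_LOOP


class TestMfei:
    def test_gc_content(self):
        assert gc_content("GGCC") == 1.0
        assert gc_content("AUAU") == 0.0
        assert gc_content("GAUC") == 0.5

    def test_forced_by_formula(self):
        assert mfei(-50, 100, 0.50) == pytest.approx(1.00)
        assert mfei(0, 100, 0.5) == 0.0

    @pytest.mark.parametrize(
        "row", list(references.PRECURSOR_CHARACTERISTICS.itertuples(index=False))
    )
    def test_published_rows_roundtrip_by_gc_inversion(self, row):
        # invert the published MFEI for GC, then recompute: the round trip
        # must reproduce the printed MFEI at its precision
        gc = (abs(row.mfe) / row.length_nt * 100) / (row.mfei * 100)
        assert 0 < gc < 1
        assert mfei(row.mfe, row.length_nt, gc) == pytest.approx(row.mfei)

    def test_scale_invariance(self):
        # same MFE/length ratio and GC leaves MFEI unchanged
        assert mfei(-30, 60, 0.4) == pytest.approx(mfei(-60, 120, 0.4))

    def test_gc_zero_is_an_error(self):
        with pytest.raises(ValueError):
            mfei(-10, 50, 0.0)


def _fold_from_bracket(seq, bracket):
    stack, pairs = [], set()
    for pos, ch in enumerate(bracket, start=1):
        if ch == "(":
            stack.append(pos)
        elif ch == ")":
            pairs.add((stack.pop(), pos))
    return FoldResult(to_rna(seq), bracket, 0.0, frozenset(pairs))


class TestExtractArms:
    def test_minimal_hairpin(self):
        f = _fold_from_bracket("GGGAAACCC", "(((...)))")
        assert extract_arms(f) == ((1, 3), (7, 9), (4, 6))

    def test_interior_loop_columns_belong_to_arms(self):
        f = _fold_from_bracket("GGAAGGAAACCAACC", "((..((...))..))")
        arm5, arm3, loop = extract_arms(f)
        assert (arm5, loop, arm3) == ((1, 6), (7, 9), (10, 15))

    def test_two_stemloops_rejected(self):
        f = _fold_from_bracket("GGAAACCGGAAACC", "((...))((...))")
        with pytest.raises(NotStemLoopError):
            extract_arms(f)

    def test_unfolded_rejected(self):
        f = _fold_from_bracket("AAAA", "....")
        with pytest.raises(NotStemLoopError):
            extract_arms(f)


MATURE = "GCUGGAGUCCAUGCAACGGCA"  # 21 nt, arbitrary fixed mature


def _perfect_hairpin(mature=MATURE, loop="AAA"):
    return revcomp(mature) + loop + mature


class TestDuplexMismatches:
    def test_perfect_duplex_has_zero(self):
        pre = _perfect_hairpin()
        f = fold(pre)
        L = len(MATURE)
        nm = count_duplex_mismatches(f, (1, L), (L + 4, 2 * L + 3))
        assert nm == 0

    def test_engineered_unpaired_columns_counted(self):
        # mutate both strands of three duplex columns to A/A: the column
        # cannot pair and no freed base is left for the energy model to
        # re-pair elsewhere, so exactly three columns open up
        pre = list(_perfect_hairpin())
        L = len(MATURE)
        for mature_pos in (6, 11, 17):
            pre[L - mature_pos] = "A"  # partner in the 5' arm
            pre[L + 3 + mature_pos - 1] = "A"  # mature position itself
        f = fold("".join(pre))
        nm = count_duplex_mismatches(f, (1, L), (L + 4, 2 * L + 3))
        assert nm == 3

    def test_spans_outside_stem_count_fully(self):
        pre = _perfect_hairpin() + "A" * 10  # unpaired 3' tail
        f = fold(pre)
        L = len(MATURE)
        tail = (2 * L + 4, 2 * L + 13)
        assert count_duplex_mismatches(f, (1, 10), tail) == 10

    def test_same_arm_spans_rejected(self):
        f = fold(_perfect_hairpin())
        with pytest.raises(ValueError):
            count_duplex_mismatches(f, (1, 8), (10, 18))


class TestLocateMature:
    def test_exact_reference_copy_on_3p_arm(self):
        ref = references.MATURE_MIR166["Vco-miR166h-3p"]  # 22 nt
        pre = _perfect_hairpin(ref.replace("U", "T"))
        f = fold(pre)
        anns = locate_mature(pre, f, {"Vco-miR166h-3p": ref}, locus_id="loc")
        by_arm = {a.arm: a for a in anns}
        assert by_arm["3p"].nm_to_homolog == 0
        assert by_arm["3p"].length == 22
        assert by_arm["3p"].sequence == to_rna(ref)
        assert by_arm["3p"].mature_id == "loc-3p"

    def test_mutated_copy_counts_substitutions(self):
        ref = references.MATURE_MIR166["Vco-miR166g-3p"]
        mutated = list(ref.replace("U", "T"))
        mutated[5] = "A" if mutated[5] != "A" else "C"
        mutated[15] = "A" if mutated[15] != "A" else "C"
        pre = _perfect_hairpin("".join(mutated))
        f = fold(pre)
        anns = locate_mature(pre, f, {"Vco-miR166g-3p": ref})
        nm3 = [a for a in anns if a.arm == "3p"]
        assert nm3 and nm3[0].nm_to_homolog == 2

    def test_zero_tolerance_rejects_mutated_copy(self):
        ref = references.MATURE_MIR166["Vco-miR166g-3p"]
        mutated = list(ref.replace("U", "T"))
        mutated[5] = "A" if mutated[5] != "A" else "C"
        pre = _perfect_hairpin("".join(mutated))
        f = fold(pre)
        anns = locate_mature(pre, f, {"Vco-miR166g-3p": ref}, max_mismatch=0)
        assert [a for a in anns if a.nm_to_homolog > 0] == []


def _candidate(nm=0, mfei_value=1.0, mfe=-40.0, simple=True):
    f = FoldResult("A" * 10, "." * 10, mfe, frozenset())
    return HairpinCandidate(
        locus_id=f"nm{nm}mfei{mfei_value}",
        fold=f,
        gc=0.5,
        mfei=mfei_value,
        is_simple_stemloop=simple,
        nm=nm,
    )


class TestScreen:
    def test_nm_boundary_is_inclusive(self):
        decisions = screen_candidates([_candidate(nm=4)], max_nm=4)
        assert decisions[0].accepted

    def test_low_mfei_rejected_with_reason(self):
        decisions = screen_candidates([_candidate(mfei_value=0.80)], min_mfei=0.85)
        assert not decisions[0].accepted
        assert decisions[0].reason == "mfei"

    def test_non_stemloop_rejected_first(self):
        decisions = screen_candidates([_candidate(simple=False)])
        assert decisions[0].reason == "not a simple stem-loop"

    def test_dinucleotide_shuffle_typically_rejected(self, rng):
        from mir166kit import synthetic

        pre = synthetic.synthesize_precursor(
            references.MATURE_MIR166["Vco-miR166h-3p"], seed=0
        )
        rejected = 0
        for _ in range(10):
            pairs = [pre[i : i + 2] for i in range(0, len(pre) - 1, 2)]
            rng.shuffle(pairs)
            shuffled = "".join(pairs)
            cand = hairpin.characterize(
                "shuf", shuffled, mature_refs=references.MATURE_MIR166
            )
            if not screen_candidates([cand])[0].accepted:
                rejected += 1
        assert rejected >= 8

    def test_tightening_thresholds_never_grows_accepted_set(self, rng):
        cands = [
            _candidate(
                nm=int(rng.integers(0, 8)),
                mfei_value=float(rng.uniform(0.3, 1.5)),
                mfe=float(rng.uniform(-60, -5)),
            )
            for _ in range(30)
        ]
        base = {
            d.locus_id
            for d in screen_candidates(cands, max_nm=4, min_mfei=0.8, max_mfe=-10)
            if d.accepted
        }
        for kwargs in (
            {"max_nm": 3, "min_mfei": 0.8, "max_mfe": -10},
            {"max_nm": 4, "min_mfei": 0.9, "max_mfe": -10},
            {"max_nm": 4, "min_mfei": 0.8, "max_mfe": -20},
        ):
            tighter = {
                d.locus_id
                for d in screen_candidates(cands, **kwargs)
                if d.accepted
            }
            assert tighter <= base
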