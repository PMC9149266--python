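"""Hairpin folding and precursor screening.

Folding is a Nussinov-style dynamic program that minimizes a sum of base-pair
energies (G:C -3.0, A:U -2.0, G:U -1.0 kcal/mol) over all pseudoknot-free
structures with a minimum hairpin loop of 3 unpaired bases.  The model is
exact and fully checkable by enumeration; its absolute energies are not
comparable to nearest-neighbor thermodynamic folders, so the screening
thresholds (MFE, MFEI) are explicit parameters rather than literature
constants.  An external thermodynamic folder can be slotted in by building
``FoldResult`` objects from its output; every downstream operation consumes
only ``FoldResult``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .seq import gc_fraction, to_rna

PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}

MIN_LOOP = 3
_EPS = 1e-9


class NotStemLoopError(ValueError):
    """Raised when a structure is not a simple single-hairpin stem-loop."""


@dataclass
class FoldResult:
    sequence: str  # RNA
    structure: str  # dot-bracket
    mfe: float  # kcal/mol under the pair-energy model
    pairs: frozenset[tuple[int, int]]  # 1-based (i, j), i < j

    def partner(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for i, j in self.pairs:
            out[i] = j
            out[j] = i
        return out


@dataclass
class MatureAnnotation:
    mature_id: str
    arm: str  # '5p' or '3p'
    sequence: str  # RNA
    length: int
    best_homolog: str
    nm_to_homolog: int
    span: tuple[int, int]  # 1-based inclusive, on the precursor


@dataclass
class HairpinCandidate:
    locus_id: str
    fold: FoldResult
    gc: float
    mfei: Optional[float]
    is_simple_stemloop: bool
    arm5: Optional[tuple[int, int]] = None
    arm3: Optional[tuple[int, int]] = None
    loop_span: Optional[tuple[int, int]] = None
    nm: Optional[int] = None
    matures: list[MatureAnnotation] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.fold.sequence)


def fold(seq: str, min_loop: int = MIN_LOOP) -> FoldResult:
    """Minimum-energy nested structure under the pair-energy model.

    Ties are broken deterministically: pairing the leftmost pairable base is
    preferred, and among its partners the smallest j wins.
    """
    s = to_rna(seq)
    n = len(s)
    if n < min_loop + 2:
        return FoldResult(s, "." * n, 0.0, frozenset())
    E = [[0.0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            row_i1 = E[i + 1]
            best = row_i1[j]
            si = s[i]
            for k in range(i + min_loop + 1, j + 1):
                e = PAIR_ENERGY.get((si, s[k]))
                if e is None:
                    continue
                v = e + (row_i1[k - 1] if k - 1 > i else 0.0)
                if k + 1 <= j:
                    v += E[k + 1][j]
                if v < best:
                    best = v
            E[i][j] = best
    pairs: set[tuple[int, int]] = set()
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        while i < j - min_loop:
            target = E[i][j]
            si = s[i]
            chosen = None
            for k in range(i + min_loop + 1, j + 1):
                e = PAIR_ENERGY.get((si, s[k]))
                if e is None:
                    continue
                v = e + (E[i + 1][k - 1] if k - 1 > i else 0.0)
                if k + 1 <= j:
                    v += E[k + 1][j]
                if abs(v - target) < _EPS:
                    chosen = k
                    break
            if chosen is None:
                i += 1  # i unpaired
                continue
            pairs.add((i + 1, chosen + 1))
            if chosen + 1 <= j:
                stack.append((chosen + 1, j))
            i, j = i + 1, chosen - 1
    structure = ["."] * n
    for i, j in pairs:
        structure[i - 1] = "("
        structure[j - 1] = ")"
    return FoldResult(s, "".join(structure), E[0][n - 1], frozenset(pairs))


def gc_content(seq: str) -> float:
    return gc_fraction(seq)


def mfei(mfe: float, length: int, gc: float) -> float:
    """MFE index: (|MFE| / length * 100) / (GC * 100), reported positive."""
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0 < gc <= 1:
        raise ValueError("GC fraction must be in (0, 1]")
    return (abs(mfe) / length * 100.0) / (gc * 100.0)


def _prune_lone_pairs(pairs: frozenset[tuple[int, int]]) -> set[tuple[int, int]]:
    """Drop helices consisting of a single un-stacked pair (noLP convention)."""
    return {
        (i, j)
        for i, j in pairs
        if (i + 1, j - 1) in pairs or (i - 1, j + 1) in pairs
    }


MIN_STEM_PAIRS = 3


def extract_arms(
    fold_result: FoldResult, min_stem: int = MIN_STEM_PAIRS
) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """Locate the 5' arm, hairpin loop, and 3' arm of a simple stem-loop.

    Lone pairs are pruned, then each hairpin loop is weighted by the number
    of pairs that enclose it and no other loop (its closing stem).  The
    structure is a simple stem-loop when exactly one loop is closed by a
    substantial stem (>= ``min_stem`` pairs); incidental short helices
    elsewhere are ignored, while genuinely branched structures raise
    :class:`NotStemLoopError`.  Interior-loop and bulge columns inside the
    stem belong to the arms.
    """
    pairs = _prune_lone_pairs(fold_result.pairs)
    if not pairs:
        raise NotStemLoopError("no stacked helix in structure")
    # innermost pairs (nothing nested inside) each close one hairpin loop
    innermost = [
        (i, j)
        for i, j in pairs
        if not any(i < a and b < j for a, b in pairs)
    ]
    stems = {}
    for li, lj in innermost:
        stems[(li, lj)] = [
            (a, b)
            for a, b in pairs
            if a <= li
            and lj <= b
            and not any(
                (a < i2 and j2 < b) for i2, j2 in innermost if (i2, j2) != (li, lj)
            )
        ]
    substantial = [
        loop for loop, closing in stems.items() if len(closing) >= min_stem
    ]
    if len(substantial) != 1:
        raise NotStemLoopError(
            f"not a simple stem-loop: {len(substantial)} substantial hairpin "
            f"loops ({len(innermost)} total)"
        )
    (li, lj) = substantial[0]
    closing = stems[(li, lj)]
    first_i = min(a for a, _ in closing)
    last_j = max(b for _, b in closing)
    arm5 = (first_i, li)
    loop = (li + 1, lj - 1)
    arm3 = (lj, last_j)
    return arm5, arm3, loop


def count_duplex_mismatches(
    fold_result: FoldResult,
    mature5_span: tuple[int, int],
    mature3_span: tuple[int, int],
) -> int:
    """Arm-duplex mismatch count (NM) over the mature-duplex columns.

    Walking the duplex between the two spans, each run of bases not engaged
    in a WC or G:U pair with the opposite span contributes
    max(unpaired on 5' side, unpaired on 3' side) columns: a symmetric
    mismatch counts once, a bulged base counts once.  Spans are clipped to
    the stem arms (columns outside the stem do not belong to the arm
    duplex), and lone pairs do not anchor duplex columns.
    """
    arm5, arm3, _ = extract_arms(fold_result)
    for span in (mature5_span, mature3_span):
        if not 1 <= span[0] <= span[1] <= len(fold_result.sequence):
            raise ValueError(f"span {span} outside precursor")

    def side(span):
        if span[1] <= arm5[1]:
            return 5
        if span[0] >= arm3[0]:
            return 3
        return 0  # straddles the loop

    if {side(mature5_span), side(mature3_span)} in ({5}, {3}):
        raise ValueError("mature spans lie on the same arm")
    len5 = mature5_span[1] - mature5_span[0] + 1
    len3 = mature3_span[1] - mature3_span[0] + 1
    s5, e5 = max(mature5_span[0], arm5[0]), min(mature5_span[1], arm5[1])
    s3, e3 = max(mature3_span[0], arm3[0]), min(mature3_span[1], arm3[1])
    if s5 > e5 or s3 > e3:
        return max(len5, len3)
    partner = {}
    for i, j in _prune_lone_pairs(fold_result.pairs):
        partner[i] = j
        partner[j] = i
    anchors = [
        (i, partner[i])
        for i in range(s5, e5 + 1)
        if i in partner and s3 <= partner[i] <= e3
    ]
    if not anchors:
        return max(len5, len3)
    nm = max(anchors[0][0] - s5, e3 - anchors[0][1])
    for (i0, j0), (i1, j1) in zip(anchors, anchors[1:]):
        nm += max(i1 - i0 - 1, j0 - j1 - 1)
    nm += max(e5 - anchors[-1][0], anchors[-1][1] - s3)
    return nm


def _mismatches(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def locate_mature(
    precursor: str,
    fold_result: FoldResult,
    mature_refs: dict[str, str],
    max_mismatch: int = 3,
    locus_id: str = "candidate",
) -> list[MatureAnnotation]:
    """Place mature miRNAs on the hairpin arms by ungapped sliding comparison.

    For each arm the reference with the fewest mismatches is reported when it
    is within ``max_mismatch`` (ties: first reference in input order, then
    leftmost window).  Arm assignment follows position relative to the loop.
    """
    seq = to_rna(precursor)
    _, _, loop = extract_arms(fold_result)
    loop_mid = (loop[0] + loop[1]) / 2.0
    best: dict[str, tuple[int, int, str, int]] = {}  # arm -> (nm, order, ref, start)
    for order, (ref_id, ref_seq) in enumerate(mature_refs.items()):
        ref = to_rna(ref_seq)
        if not 20 <= len(ref) <= 24:
            raise ValueError(f"mature reference {ref_id} outside 20-24 nt")
        for start in range(len(seq) - len(ref) + 1):
            window = seq[start : start + len(ref)]
            nm = _mismatches(window, ref)
            if nm > max_mismatch:
                continue
            mid = start + (len(ref) + 1) / 2.0
            arm = "5p" if mid <= loop_mid else "3p"
            key = (nm, order, start)
            if arm not in best or key < (best[arm][0], best[arm][1], best[arm][3]):
                best[arm] = (nm, order, ref_id, start)
    out = []
    for arm in ("5p", "3p"):
        if arm not in best:
            continue
        nm, _, ref_id, start = best[arm]
        length = len(to_rna(mature_refs[ref_id]))
        out.append(
            MatureAnnotation(
                mature_id=f"{locus_id}-{arm}",
                arm=arm,
                sequence=seq[start : start + length],
                length=length,
                best_homolog=ref_id,
                nm_to_homolog=nm,
                span=(start + 1, start + length),
            )
        )
    return out


def _project_span(
    fold_result: FoldResult, span: tuple[int, int]
) -> Optional[tuple[int, int]]:
    """Span of stem partners of the paired positions within ``span``.

    Lone pairs are ignored and partners are restricted to the opposite arm,
    so loop-adjacent incidental pairs cannot stretch the projection.
    """
    try:
        arm5, arm3, _ = extract_arms(fold_result)
    except NotStemLoopError:
        return None
    partner = {}
    for i, j in _prune_lone_pairs(fold_result.pairs):
        partner[i] = j
        partner[j] = i
    opposite = arm3 if span[0] <= arm5[1] else arm5
    partners = [
        partner[i]
        for i in range(span[0], span[1] + 1)
        if i in partner and opposite[0] <= partner[i] <= opposite[1]
    ]
    if not partners:
        return None
    return (min(partners), max(partners))


_PAIRED_RNA = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}


def arm_duplex_nm(
    sequence: str, mature_span: tuple[int, int], opposite_arm: tuple[int, int]
) -> int:
    """Mismatches between a mature span and the opposite arm, by sequence.

    The mature subsequence (5'->3') is slid ungapped along the opposite arm
    in duplex orientation; the best window's count of columns that are
    neither Watson-Crick nor G:U wobble is returned.  Unlike the
    structure-walk counter this is insensitive to register shifts of the
    energy-minimal fold, which under the flat pair-energy model can widen a
    single broken column into a multi-column interior loop.
    """
    seq = to_rna(sequence)
    m = seq[mature_span[0] - 1 : mature_span[1]]
    region = seq[opposite_arm[0] - 1 : opposite_arm[1]]
    L = len(m)
    if len(region) < L:  # short arm: missing partners count as mismatches
        overlap = sum(
            1 for a, b in zip(m, reversed(region)) if (a, b) not in _PAIRED_RNA
        )
        return min(L, (L - len(region)) + overlap)
    best = L
    for st in range(len(region) - L + 1):
        w = region[st : st + L]
        nm = sum(1 for a, b in zip(m, reversed(w)) if (a, b) not in _PAIRED_RNA)
        best = min(best, nm)
    return best


def _best_paired_window(
    fold_result: FoldResult, arm: tuple[int, int], width: int = 21
) -> tuple[int, int]:
    """Most-paired window of the given width inside an arm interval."""
    partner = fold_result.partner()
    lo, hi = arm
    width = min(width, hi - lo + 1)
    best_start, best_n = lo, -1
    for start in range(lo, hi - width + 2):
        n = sum(1 for i in range(start, start + width) if i in partner)
        if n > best_n:
            best_start, best_n = start, n
    return (best_start, best_start + width - 1)


def characterize(
    locus_id: str,
    sequence: str,
    mature_refs: Optional[dict[str, str]] = None,
    min_loop: int = MIN_LOOP,
    max_mismatch: int = 3,
) -> HairpinCandidate:
    """Fold a candidate and compute its screening characteristics.

    The arm-duplex mismatch count (NM) is taken over the mature-duplex
    columns: the located mature span(s) when references are given, otherwise
    the best-paired 21-nt window of the 5' arm and its paired projection.
    """
    seq = to_rna(sequence)
    f = fold(seq, min_loop=min_loop)
    gc = gc_content(seq)
    cand = HairpinCandidate(
        locus_id=locus_id,
        fold=f,
        gc=gc,
        mfei=mfei(f.mfe, len(seq), gc) if gc > 0 else None,
        is_simple_stemloop=True,
    )
    try:
        arm5, arm3, loop = extract_arms(f)
    except NotStemLoopError:
        cand.is_simple_stemloop = False
        return cand
    cand.arm5, cand.arm3, cand.loop_span = arm5, arm3, loop
    if mature_refs:
        cand.matures = locate_mature(
            seq, f, mature_refs, max_mismatch=max_mismatch, locus_id=locus_id
        )
    span5 = next((m.span for m in cand.matures if m.arm == "5p"), None)
    span3 = next((m.span for m in cand.matures if m.arm == "3p"), None)
    if span5 is None and span3 is None:
        span5 = _best_paired_window(f, arm5)
    # NM by best ungapped duplex of the mature span against everything on
    # the other side of the loop (robust to arm-boundary detection noise)
    values = []
    if span5 is not None and span5[1] < len(seq):
        values.append(arm_duplex_nm(seq, span5, (span5[1] + 1, len(seq))))
    if span3 is not None and span3[0] > 1:
        values.append(arm_duplex_nm(seq, span3, (1, span3[0] - 1)))
    if values:
        cand.nm = max(values)
    return cand


@dataclass
class ScreenDecision:
    locus_id: str
    accepted: bool
    reason: str  # first failed rule, or 'pass'


def screen_candidates(
    candidates: Sequence[HairpinCandidate],
    max_nm: int = 4,
    min_mfei: float = 0.85,
    max_mfe: float = -15.0,
) -> list[ScreenDecision]:
    """Accept candidates that are simple stem-loops with nm <= max_nm,
    MFEI >= min_mfei and MFE <= max_mfe; rejections carry the first failed
    rule (checked in that order)."""
    out = []
    for cand in candidates:
        if not cand.is_simple_stemloop:
            decision = ScreenDecision(cand.locus_id, False, "not a simple stem-loop")
        elif cand.nm is None or cand.nm > max_nm:
            decision = ScreenDecision(cand.locus_id, False, "nm")
        elif cand.mfei is None or cand.mfei < min_mfei:
            decision = ScreenDecision(cand.locus_id, False, "mfei")
        elif cand.fold.mfe > max_mfe:
            decision = ScreenDecision(cand.locus_id, False, "mfe")
        else:
            decision = ScreenDecision(cand.locus_id, True, "pass")
        out.append(decision)
    return out
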