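"""Expectation-scored miRNA target prediction on transcript sequences.

A miRNA:site duplex is scored by an additive penalty (expectation): each
mismatch costs 1.0, each G:U wobble 0.5, each bulged base 2.0, and penalties
at miRNA positions inside the seed span (2-13 from the 5' end by default)
are doubled.  Lower is better; sites are reported up to a cutoff (default
5.0).  Windows are ungapped except for at most one single-base bulge on
either strand.  Inhibition mode follows the plant convention: translational
repression when any non-Watson-Crick state falls on central positions 9-11,
cleavage otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .seq import to_dna, to_rna

WC = "WC"
GU = "GU"
MISMATCH = "mismatch"
BULGE = "bulge"

_WC_PAIRS = {("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "T"), ("U", "G")}


@dataclass(frozen=True)
class PenaltyWeights:
    mismatch: float = 1.0
    gu: float = 0.5
    bulge: float = 2.0
    seed_span: tuple[int, int] = (2, 13)  # miRNA positions, 1-based, inclusive
    seed_factor: float = 2.0
    cutoff: float = 5.0


DEFAULT_WEIGHTS = PenaltyWeights()


@dataclass
class DuplexAlignment:
    """States over miRNA positions 1..L plus bulged transcript bases.

    ``states[k-1]`` is the state of miRNA position k (5'->3').  A bulged
    transcript base is recorded in ``transcript_bulges`` by the miRNA
    position 5' of it, since it occupies no miRNA position itself.
    """

    mirna: str  # RNA, 5'->3'
    site: str  # transcript subsequence (DNA, sense strand)
    states: list[str]
    transcript_bulges: list[int] = field(default_factory=list)


@dataclass
class TargetSite:
    mirna_id: str
    transcript_id: str
    transcript_span: tuple[int, int]  # 1-based inclusive
    expectation: float
    inhibition: str  # 'cleavage' or 'translation'
    alignment: DuplexAlignment | None = None


def pair_state(mirna_base: str, transcript_base: str) -> str:
    """State of one duplex column: miRNA base (RNA) vs transcript base (DNA,
    sense strand read 3'->5' relative to the miRNA)."""
    pair = (mirna_base, transcript_base)
    if pair in _WC_PAIRS:
        return WC
    if pair in _GU_PAIRS:
        return GU
    return MISMATCH


def align_window(mirna: str, window: str, bulge: tuple[str, int] | None = None) -> DuplexAlignment:
    """Build the duplex alignment of a miRNA against one transcript window.

    The window is a sense-strand transcript subsequence; miRNA position k
    pairs the window base at distance k from the window's 3' end.  ``bulge``
    is None (ungapped), ('mirna', k) for an unpaired miRNA position k, or
    ('transcript', k) for an extra transcript base between miRNA positions
    k and k+1.
    """
    m = to_rna(mirna)
    w = to_dna(window)
    L = len(m)
    states = [MISMATCH] * L
    tb: list[int] = []
    if bulge is None:
        if len(w) != L:
            raise ValueError("ungapped window must match miRNA length")
        for k in range(1, L + 1):
            states[k - 1] = pair_state(m[k - 1], w[L - k])
    elif bulge[0] == "mirna":
        if len(w) != L - 1:
            raise ValueError("miRNA-bulge window must be one base shorter")
        b = bulge[1]
        wi = len(w)  # consume window bases from the 3'-most end backwards
        for k in range(1, L + 1):
            if k == b:
                states[k - 1] = BULGE
                continue
            wi -= 1
            states[k - 1] = pair_state(m[k - 1], w[wi])
    elif bulge[0] == "transcript":
        if len(w) != L + 1:
            raise ValueError("transcript-bulge window must be one base longer")
        b = bulge[1]
        if not 1 <= b <= L - 1:
            raise ValueError("transcript bulge must sit between miRNA positions")
        wi = len(w)
        for k in range(1, L + 1):
            wi -= 1
            states[k - 1] = pair_state(m[k - 1], w[wi])
            if k == b:
                wi -= 1  # skip the bulged transcript base
        tb = [b]
    else:
        raise ValueError(f"unknown bulge spec: {bulge}")
    return DuplexAlignment(m, w, states, tb)


def _seed_mult(pos: int, w: PenaltyWeights) -> float:
    return w.seed_factor if w.seed_span[0] <= pos <= w.seed_span[1] else 1.0


def score_duplex(aln: DuplexAlignment, weights: PenaltyWeights = DEFAULT_WEIGHTS) -> float:
    """Sum of per-position penalties, seed positions doubled."""
    total = 0.0
    for k, state in enumerate(aln.states, start=1):
        if state == WC:
            continue
        base = {GU: weights.gu, MISMATCH: weights.mismatch, BULGE: weights.bulge}[state]
        total += base * _seed_mult(k, weights)
    for b in aln.transcript_bulges:
        total += weights.bulge * _seed_mult(b, weights)
    return total


def classify_inhibition(aln: DuplexAlignment) -> str:
    """'translation' iff any non-WC state at central miRNA positions 9-11."""
    central = set(range(9, 12))
    for k, state in enumerate(aln.states, start=1):
        if k in central and state != WC:
            return "translation"
    if any(b in central for b in aln.transcript_bulges):
        return "translation"
    return "cleavage"


def _window_variants(mirna: str, transcript: str, start: int, max_bulge: int):
    """Yield (alignment, span_len) for the ungapped window at ``start`` and
    its single-bulge variants."""
    L = len(mirna)
    if start + L <= len(transcript):
        yield align_window(mirna, transcript[start : start + L]), L
    if max_bulge < 1:
        return
    if start + L - 1 <= len(transcript):
        w = transcript[start : start + L - 1]
        for b in range(1, L + 1):
            yield align_window(mirna, w, bulge=("mirna", b)), L - 1
    if start + L + 1 <= len(transcript):
        w = transcript[start : start + L + 1]
        for b in range(1, L):
            yield align_window(mirna, w, bulge=("transcript", b)), L + 1


def scan_transcripts(
    mirna_id: str,
    mirna: str,
    transcripts: dict[str, str],
    cutoff: float = 5.0,
    weights: PenaltyWeights = DEFAULT_WEIGHTS,
    max_bulge: int = 1,
) -> list[TargetSite]:
    """Scan sense-strand transcripts for target sites with expectation <=
    cutoff; overlapping windows collapse to the best-scoring site per locus,
    and sites are sorted by expectation then coordinates."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    m = to_rna(mirna)
    found: list[TargetSite] = []
    for tid, raw in transcripts.items():
        t = to_dna(raw)
        per_start: list[TargetSite] = []
        for start in range(len(t) - len(m) + 2):
            best = None
            for aln, span_len in _window_variants(m, t, start, max_bulge):
                e = score_duplex(aln, weights)
                if best is None or e < best[0]:
                    best = (e, aln, span_len)
            if best is None or best[0] > cutoff:
                continue
            e, aln, span_len = best
            per_start.append(
                TargetSite(
                    mirna_id=mirna_id,
                    transcript_id=tid,
                    transcript_span=(start + 1, start + span_len),
                    expectation=e,
                    inhibition=classify_inhibition(aln),
                    alignment=aln,
                )
            )
        # collapse overlapping windows to the best-scoring site
        kept: list[TargetSite] = []
        for site in sorted(
            per_start, key=lambda x: (x.expectation, x.transcript_span)
        ):
            if any(
                _overlaps(site.transcript_span, k.transcript_span) for k in kept
            ):
                continue
            kept.append(site)
        found.extend(kept)
    found.sort(key=lambda x: (x.expectation, x.transcript_id, x.transcript_span))
    return found


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]
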