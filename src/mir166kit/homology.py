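"""Homology screening of genome scaffolds with known precursor queries.

Candidate precursor loci are found by exact local alignment (Smith-Waterman
with affine gaps) of each query against both strands of every scaffold,
thresholded on identity and query coverage.  A gap of length k costs
``gap_open + k * gap_extend``.  Coordinates are 0-based half-open
internally and 1-based inclusive in every report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .seq import revcomp, to_dna

MASK_CHAR = "N"
_MASK_SCORE = -1000.0  # forbids alignments through previously reported loci


@dataclass(frozen=True)
class ScoringScheme:
    """Affine-gap scoring; gap of length k costs gap_open + k*gap_extend."""

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0

    def __post_init__(self):
        if self.match <= 0:
            raise ValueError("match score must be positive")
        if self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("mismatch and gap penalties must be <= 0")


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class AlignmentHit:
    query_id: str
    scaffold_id: str
    query_span: tuple[int, int]  # 1-based inclusive, on the original query
    scaffold_span: tuple[int, int]  # 1-based inclusive, + reference frame
    strand: str  # '+' or '-'
    score: float
    identity: float  # matches / aligned columns (gap columns count)
    coverage: float  # aligned query residues / query length
    n_columns: int = 0
    candidate_id: str = field(default="")


def _make_aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    alphabet = "ACGT" + MASK_CHAR
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            if MASK_CHAR in (x, y):
                matrix[x, y] = _MASK_SCORE
            else:
                matrix[x, y] = scheme.match if x == y else scheme.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # biopython charges open_gap_score for the first gapped position
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, int, tuple[int, int], tuple[int, int]]:
    """(matches, columns, aligned_query_bases, target_span, query_span)."""
    tsegs, qsegs = alignment.aligned
    target, query = alignment.target, alignment.query
    matches = columns = qbases = 0
    prev_t = prev_q = None
    for (t0, t1), (q0, q1) in zip(tsegs, qsegs):
        if prev_t is not None:
            columns += (t0 - prev_t) + (q0 - prev_q)  # internal gap columns
        columns += t1 - t0
        qbases += q1 - q0
        matches += sum(
            1 for a, b in zip(target[t0:t1], query[q0:q1]) if a == b
        )
        prev_t, prev_q = t1, q1
    tspan = (int(tsegs[0][0]), int(tsegs[-1][1]))
    qspan = (int(qsegs[0][0]), int(qsegs[-1][1]))
    return matches, columns, qbases, tspan, qspan


def local_align(
    a: str, b: str, scheme: ScoringScheme = DEFAULT_SCHEME
) -> AlignmentHit:
    """Best local alignment of query ``a`` against subject ``b``.

    Returns the maximal-scoring local alignment under the affine-gap scheme;
    the score is the exact dynamic-programming optimum.
    """
    qa, tb = to_dna(a), to_dna(b)
    if not qa or not tb:
        raise ValueError("empty sequence")
    aligner = _make_aligner(scheme)
    alignments = aligner.align(tb, qa)
    if alignments.score <= 0:  # no positive-scoring local alignment exists
        return AlignmentHit(
            "a", "b", (0, 0), (0, 0), "+", 0.0, 0.0, 0.0, 0
        )
    alignment = alignments[0]
    matches, columns, qbases, tspan, qspan = _alignment_stats(alignment)
    return AlignmentHit(
        query_id="a",
        scaffold_id="b",
        query_span=(qspan[0] + 1, qspan[1]),
        scaffold_span=(tspan[0] + 1, tspan[1]),
        strand="+",
        score=float(alignment.score),
        identity=matches / columns if columns else 0.0,
        coverage=qbases / len(qa),
        n_columns=columns,
    )


def _iter_locus_hits(
    aligner, query_id, query, scaffold_id, scaffold, strand, min_identity,
    min_coverage, max_hits=64,
):
    """Repeated best-hit extraction with masking, one (query, strand) pair."""
    qlen = len(query)
    work = scaffold
    for _ in range(max_hits):
        alignments = aligner.align(work, query)
        if alignments.score <= 0:
            return
        alignment = alignments[0]
        matches, columns, qbases, tspan, qspan = _alignment_stats(alignment)
        identity = matches / columns if columns else 0.0
        coverage = qbases / qlen
        if identity < min_identity or coverage < min_coverage:
            return
        if strand == "+":
            query_span = (qspan[0] + 1, qspan[1])
        else:  # map back onto the original (+) query coordinates
            query_span = (qlen - qspan[1] + 1, qlen - qspan[0])
        yield AlignmentHit(
            query_id=query_id,
            scaffold_id=scaffold_id,
            query_span=query_span,
            scaffold_span=(tspan[0] + 1, tspan[1]),
            strand=strand,
            score=float(alignment.score),
            identity=identity,
            coverage=coverage,
            n_columns=columns,
        )
        work = work[: tspan[0]] + MASK_CHAR * (tspan[1] - tspan[0]) + work[tspan[1] :]


def _reciprocal_overlap(span1, span2) -> float:
    s1, e1 = span1
    s2, e2 = span2
    inter = min(e1, e2) - max(s1, s2) + 1
    if inter <= 0:
        return 0.0
    return min(inter / (e1 - s1 + 1), inter / (e2 - s2 + 1))


def scan_genome(
    queries: dict[str, str],
    scaffolds: dict[str, str],
    min_identity: float = 0.85,
    min_coverage: float = 0.8,
    flank: int = 0,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[list[AlignmentHit], dict[str, str]]:
    """Scan both strands of every scaffold with every query.

    Overlapping hits to the same locus (>= 50% reciprocal overlap) are merged
    keeping the best score.  Each surviving hit's candidate sequence is the
    scaffold subsequence extended by ``flank`` on each side (clipped at
    scaffold ends), reverse-complemented for minus-strand hits.
    """
    if not scaffolds:
        raise ValueError("no scaffolds provided")
    if not (0 <= min_identity <= 1 and 0 <= min_coverage <= 1):
        raise ValueError("min_identity and min_coverage must be in [0, 1]")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    aligner = _make_aligner(scheme)
    raw: list[AlignmentHit] = []
    for sid, scaffold in scaffolds.items():
        scaffold = to_dna(scaffold)
        for qid, query in queries.items():
            query = to_dna(query)
            if not query:
                raise ValueError(f"empty query {qid}")
            for strand, qseq in (("+", query), ("-", revcomp(query))):
                raw.extend(
                    _iter_locus_hits(
                        aligner, qid, qseq, sid, scaffold, strand,
                        min_identity, min_coverage,
                    )
                )
    # merge loci: best score wins among reciprocally overlapping hits
    kept: list[AlignmentHit] = []
    for hit in sorted(raw, key=lambda h: (-h.score, h.scaffold_id, h.scaffold_span)):
        if any(
            k.scaffold_id == hit.scaffold_id
            and _reciprocal_overlap(k.scaffold_span, hit.scaffold_span) >= 0.5
            for k in kept
        ):
            continue
        kept.append(hit)
    kept.sort(key=lambda h: (h.scaffold_id, h.scaffold_span[0]))
    candidates: dict[str, str] = {}
    for hit in kept:
        s, e = hit.scaffold_span
        scaffold = scaffolds[hit.scaffold_id]
        s = max(1, s - flank)
        e = min(len(scaffold), e + flank)
        seq = to_dna(scaffold[s - 1 : e])
        if hit.strand == "-":
            seq = revcomp(seq)
        hit.candidate_id = f"{hit.scaffold_id}:{s}-{e}({hit.strand})"
        candidates[hit.candidate_id] = seq
    return kept, candidates
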