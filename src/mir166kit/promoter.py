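"""Cis-regulatory element scanning of promoter windows.

Promoter sequences (taken as given fixed-length windows upstream of the TSS)
are scanned on both strands for exact IUPAC matches to a motif dictionary in
which every motif belongs to one response category (gibberellin, methyl
jasmonate, salicylic acid, auxin, abscisic acid, defense/stress, drought,
low temperature, anaerobic induction).  Presence is summarized per category
into a promoters x categories boolean matrix and per-category prevalence
percentages.

The default dictionary ships editable consensus strings modelled on public
plant cis-element descriptions; element names but not sequences are fixed by
the category mapping, so any motif TSV with the same name/category layout can
be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .references import CIS_ELEMENT_CATEGORIES
from .seq import iupac_regex, revcomp, to_dna


@dataclass(frozen=True)
class MotifDefinition:
    name: str
    pattern: str  # IUPAC degenerate string (DNA)
    category: str

    def __post_init__(self):
        if not self.pattern:
            raise ValueError("empty motif pattern")
        iupac_regex(self.pattern)  # validates the alphabet


#: Default motif dictionary: one consensus per named element.
DEFAULT_MOTIFS: list[MotifDefinition] = [
    MotifDefinition("GARE-motif", "TCTGTTG", "gibberellin responsive"),
    MotifDefinition("P-box", "CCTTTTG", "gibberellin responsive"),
    MotifDefinition("TGACG-motif", "TGACG", "methyl jasmonate responsiveness"),
    MotifDefinition("CGTCA-motif", "CGTCA", "methyl jasmonate responsiveness"),
    MotifDefinition("TCA-element", "CCATCTTTTT", "salicylic acid responsiveness"),
    MotifDefinition("TGA-box", "TGACGTAA", "auxin responsiveness"),
    MotifDefinition("TGA-element", "AACGAC", "auxin responsiveness"),
    MotifDefinition("AuxRR-core", "GGTCCAT", "auxin responsiveness"),
    MotifDefinition("ABRE", "ACGTG", "abscisic acid responsiveness"),
    MotifDefinition("TC-rich", "ATTTTCTTCA", "defense and stress responsiveness"),
    MotifDefinition("MBS", "CAACTG", "drought inducibility"),
    MotifDefinition("LTR", "CCGAAA", "low-temperature responsiveness"),
    MotifDefinition("ARE", "AAACCA", "anaerobic induction"),
]


@dataclass(frozen=True)
class MotifHit:
    motif: str
    category: str
    position: int  # 1-based start on the + strand
    strand: str  # '+' or '-'


def motifs_from_tsv(path) -> list[MotifDefinition]:
    df = pd.read_csv(path, sep="\t")
    return [
        MotifDefinition(r["name"], r["pattern"], r["category"])
        for _, r in df.iterrows()
    ]


def scan_promoter(
    seq: str,
    motifs: list[MotifDefinition] = DEFAULT_MOTIFS,
    both_strands: bool = True,
) -> list[MotifHit]:
    """All exact IUPAC matches (overlaps allowed) with 1-based + strand
    positions; minus-strand matches are found on the reverse complement and
    mapped back to the + frame."""
    s = to_dna(seq)
    hits: list[MotifHit] = []
    for motif in motifs:
        rex = iupac_regex(motif.pattern)
        for m in _finditer_overlapping(rex, s):
            hits.append(MotifHit(motif.name, motif.category, m + 1, "+"))
        if both_strands:
            rc = revcomp(s)
            mlen = len(motif.pattern)
            for m in _finditer_overlapping(rex, rc):
                pos = len(s) - m - mlen + 1
                hits.append(MotifHit(motif.name, motif.category, pos, "-"))
    hits.sort(key=lambda h: (h.position, h.motif, h.strand))
    return hits


def _finditer_overlapping(rex, s):
    start = 0
    while True:
        m = rex.search(s, start)
        if m is None:
            return
        yield m.start()
        start = m.start() + 1


def presence_matrix(
    hits_per_promoter: dict[str, list[MotifHit]],
    categories: list[str] = CIS_ELEMENT_CATEGORIES,
) -> pd.DataFrame:
    """Promoters x categories boolean matrix: TRUE iff >= 1 hit of any motif
    in that category."""
    rows = {}
    for pid, hits in hits_per_promoter.items():
        for h in hits:
            if h.category not in categories:
                raise ValueError(f"unknown category: {h.category}")
        present = {cat: any(h.category == cat for h in hits) for cat in categories}
        rows[pid] = present
    if not rows:
        return pd.DataFrame(columns=categories, dtype=bool)
    return pd.DataFrame.from_dict(rows, orient="index")[categories]


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def prevalence_summary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-category (count, n, percent) with percent rounded half-up to one
    decimal; categories keep input column order."""
    n = len(matrix)
    if n < 1:
        raise ValueError("empty presence matrix")
    rows = []
    for cat in matrix.columns:
        count = int(matrix[cat].sum())
        rows.append(
            {
                "category": cat,
                "count": count,
                "n": n,
                "percent": _round_half_up(100.0 * count / n),
            }
        )
    return pd.DataFrame(rows)


def build_presence_matrix(
    promoters: dict[str, str],
    motifs: list[MotifDefinition] = DEFAULT_MOTIFS,
    both_strands: bool = True,
    categories: list[str] = CIS_ELEMENT_CATEGORIES,
) -> tuple[pd.DataFrame, dict[str, list[MotifHit]]]:
    """Scan every promoter and assemble the presence matrix."""
    hits = {
        pid: scan_promoter(seq, motifs, both_strands)
        for pid, seq in promoters.items()
    }
    return presence_matrix(hits, categories), hits
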