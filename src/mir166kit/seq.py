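"""Small sequence helpers shared across modules.

All genomic work happens in the DNA alphabet; RNA appears only for folding
and mature-miRNA reporting.  U and T are interchangeable on input.
"""

from __future__ import annotations

import re

DNA = "ACGT"
RNA = "ACGU"

_COMPLEMENT_DNA = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_COMPLEMENT_RNA = str.maketrans("ACGUNacgun", "UGCANugcan")

#: IUPAC nucleotide degeneracy codes (DNA convention).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def to_dna(seq: str) -> str:
    """Uppercase and map U->T; validate against the IUPAC alphabet."""
    s = seq.upper().replace("U", "T")
    bad = set(s) - set(IUPAC)
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s


def to_rna(seq: str) -> str:
    """Uppercase and map T->U."""
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGUN")
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    """Reverse complement (DNA in, DNA out; U treated as T)."""
    return to_dna(seq).translate(_COMPLEMENT_DNA)[::-1]


def revcomp_rna(seq: str) -> str:
    return to_rna(seq).translate(_COMPLEMENT_RNA)[::-1]


def gc_fraction(seq: str) -> float:
    """(G + C) / length of the sequence."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC degenerate string into a regex over A/C/G/T."""
    parts = []
    for ch in pattern.upper().replace("U", "T"):
        try:
            bases = IUPAC[ch]
        except KeyError:
            raise ValueError(f"non-IUPAC motif character: {ch!r}") from None
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("".join(parts))
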