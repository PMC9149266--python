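"""In-study reference data for the blueberry miR166 family.

These constants transcribe the published characterization of the three newly
identified *Vaccinium corymbosum* (highbush blueberry) miR166 precursors and
their six mature miRNAs, plus the promoter cis-element annotation of the nine
family members.  They serve as inputs to the pipeline (mature reference sets,
consistency checks for the MFEI arithmetic, the element-presence matrix) —
never as values the pipeline pretends to have computed.
"""

from __future__ import annotations

import pandas as pd

#: Mature miR166 sequences (RNA, 5'->3') with their arm of origin.
MATURE_MIR166: dict[str, str] = {
    "Vco-miR166g-3p": "UCUCGGACCAGGCUUCAUUCC",
    "Vco-miR166g-5p": "GGGAAUGCUGUCUGGUUCGAG",
    "Vco-miR166h-3p": "AUUUCGGACCAGGCUUCAUUCC",
    "Vco-miR166h-5p": "GGAAUGUUGUCUGGUUCGAGA",
    "Vco-miR166i-3p": "UCGGACCAGGCUUCAUUCCCC",
    "Vco-miR166i-5p": "GGGAUGUUGUCUGGCUCGAUG",
}

#: Published precursor characteristics: length (nt), arm-duplex mismatches
#: (NM), minimal folding free energy (kcal/mol) and MFE index.  Used for
#: algebraic round-trips of the MFEI formula, not as fold-model expectations.
PRECURSOR_CHARACTERISTICS = pd.DataFrame(
    [
        ("Vco-miR166g", 107, 3, -45.30, 0.85),
        ("Vco-miR166h", 114, 3, -51.70, 1.08),
        ("Vco-miR166i", 186, 4, -67.90, 0.89),
    ],
    columns=["locus_id", "length_nt", "nm", "mfe", "mfei"],
)

#: Cis-regulatory element categories, in published column order.
CIS_ELEMENT_CATEGORIES: list[str] = [
    "gibberellin responsive",
    "methyl jasmonate responsiveness",
    "salicylic acid responsiveness",
    "auxin responsiveness",
    "abscisic acid responsiveness",
    "defense and stress responsiveness",
    "drought inducibility",
    "low-temperature responsiveness",
    "anaerobic induction",
]

#: Element names observed per promoter and category for the nine Vco-miR166
#: promoters (1,600 bp upstream of the TSS).  Empty tuple = none detected.
PROMOTER_ELEMENTS: dict[str, dict[str, tuple[str, ...]]] = {
    "Vco-miR166a": {
        "gibberellin responsive": ("GARE-motif", "P-box"),
        "salicylic acid responsiveness": ("TCA-element",),
        "drought inducibility": ("MBS",),
        "low-temperature responsiveness": ("LTR",),
        "anaerobic induction": ("ARE",),
    },
    "Vco-miR166b": {
        "gibberellin responsive": ("P-box",),
        "methyl jasmonate responsiveness": ("TGACG-motif", "CGTCA-motif"),
        "auxin responsiveness": ("TGA-box", "TGA-element"),
        "abscisic acid responsiveness": ("ABRE",),
        "anaerobic induction": ("ARE",),
    },
    "Vco-miR166c": {
        "auxin responsiveness": ("AuxRR-core",),
        "abscisic acid responsiveness": ("ABRE",),
        "anaerobic induction": ("ARE",),
    },
    "Vco-miR166d": {
        "gibberellin responsive": ("P-box",),
        "auxin responsiveness": ("TGA-box",),
        "abscisic acid responsiveness": ("ABRE",),
        "defense and stress responsiveness": ("TC-rich",),
        "drought inducibility": ("MBS",),
        "anaerobic induction": ("ARE",),
    },
    "Vco-miR166e": {
        "gibberellin responsive": ("P-box",),
        "methyl jasmonate responsiveness": ("TGACG-motif", "CGTCA-motif"),
        "auxin responsiveness": ("TGA-box", "TGA-element"),
        "abscisic acid responsiveness": ("ABRE",),
        "anaerobic induction": ("ARE",),
    },
    "Vco-miR166f": {
        "gibberellin responsive": ("GARE-motif",),
        "methyl jasmonate responsiveness": ("TGACG-motif", "CGTCA-motif"),
        "abscisic acid responsiveness": ("ABRE",),
        "drought inducibility": ("MBS",),
        "anaerobic induction": ("ARE",),
    },
    "Vco-miR166g": {
        "gibberellin responsive": ("GARE-motif",),
        "methyl jasmonate responsiveness": ("TGACG-motif", "CGTCA-motif"),
        "auxin responsiveness": ("TGA-element", "AuxRR-core"),
        "abscisic acid responsiveness": ("ABRE",),
        "low-temperature responsiveness": ("LTR",),
        "anaerobic induction": ("ARE",),
    },
    "Vco-miR166h": {
        "methyl jasmonate responsiveness": ("TGACG-motif", "CGTCA-motif"),
        "salicylic acid responsiveness": ("TCA-element",),
        "auxin responsiveness": ("AuxRR-core",),
        "abscisic acid responsiveness": ("ABRE",),
        "drought inducibility": ("MBS",),
        "low-temperature responsiveness": ("LTR",),
        "anaerobic induction": ("ARE",),
    },
    "Vco-miR166i": {
        "gibberellin responsive": ("GARE-motif",),
        "methyl jasmonate responsiveness": ("TGACG-motif", "CGTCA-motif"),
        "defense and stress responsiveness": ("TC-rich",),
        "anaerobic induction": ("ARE",),
    },
}


def promoter_element_matrix() -> pd.DataFrame:
    """Boolean promoters x categories presence matrix for the nine family
    promoters, in published row/column order."""
    rows = {
        pid: {
            cat: bool(elements.get(cat)) for cat in CIS_ELEMENT_CATEGORIES
        }
        for pid, elements in PROMOTER_ELEMENTS.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df.loc[list(PROMOTER_ELEMENTS), CIS_ELEMENT_CATEGORIES]
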