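"""Fold candidates, compute MFE/GC/MFEI and arm-duplex NM, place matures,
and screen for miRNA-precursor-like stem-loops.

Writes a precursor characteristics table (length, NM, MFE, MFEI, decision),
mature annotations with best homolog and mismatch count, and the dot-bracket
structures in Vienna text layout.
"""

from common import OUTDIR, run_stage

if __name__ == "__main__":
    s = run_stage("fold")
    print(
        f"screened {s['n_candidates']} candidates; {s['n_accepted']} accepted "
        f"as miR166-like stem-loops: {', '.join(s['accepted'])} "
        f"-> {OUTDIR}/precursor_characteristics.tsv"
    )
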