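"""Homology scan: known pre-miR166 queries against both genome strands.

Local alignment (Smith-Waterman, affine gaps) at >= 85% identity and 80%
query coverage; overlapping loci merged keeping the best score.  Writes the
hit table and candidate FASTA.
"""

from common import OUTDIR, run_stage

if __name__ == "__main__":
    s = run_stage("discover")
    print(
        f"found {s['n_hits']} candidate loci ({s['n_candidates']} candidate "
        f"sequences) -> {OUTDIR}/hits.tsv, candidates.fasta"
    )
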