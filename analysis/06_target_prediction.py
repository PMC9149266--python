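"""Expectation-scored target prediction of the mature miRNAs against the
transcript set (cutoff 5.0, seed positions 2-13 doubled), with cleavage vs
translational-repression calls from central positions 9-11.
"""

from common import OUTDIR, run_stage

if __name__ == "__main__":
    s = run_stage("target")
    print(
        f"scanned {s['n_mirnas']} miRNAs; {s['n_sites']} target sites at "
        f"cutoff {s['params']['cutoff']} -> {OUTDIR}/target_sites.tsv"
    )
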