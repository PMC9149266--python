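"""Scan promoter windows for cis-regulatory elements and summarize
per-category prevalence.

On the synthetic promoters realizing the transcribed matrix this reproduces
the published arithmetic: gibberellin- and ABA-responsive elements in 77.8%
(7/9) of promoters, methyl jasmonate and auxin in 66.7% (6/9), anaerobic
induction elements in all nine.
"""

import pandas as pd

from common import OUTDIR, run_stage

if __name__ == "__main__":
    s = run_stage("promoter")
    prevalence = pd.read_csv(f"{OUTDIR}/prevalence.tsv", sep="\t")
    print(f"scanned {s['n_promoters']} promoters ({s['n_hits']} element hits)")
    print(prevalence.to_string(index=False))
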