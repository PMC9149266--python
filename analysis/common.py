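"""Shared configuration for the numbered analysis scripts.

Every script drives one pipeline stage with the same root seed and output
directory, so running them in order reproduces a full study-scale analysis
under results/analysis/.
"""

from pathlib import Path

from mir166kit import pipeline

SEED = 166
OUTDIR = str(Path(__file__).resolve().parent.parent / "results" / "analysis")


def config():
    cfg = pipeline.default_config(seed=SEED)
    cfg["outdir"] = OUTDIR
    return cfg


def run_stage(stage: str) -> dict:
    summary = pipeline.run(config(), only=[stage])
    return summary[stage]
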