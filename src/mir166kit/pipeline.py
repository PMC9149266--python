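"""End-to-end orchestration of the discovery/characterization pipeline.

Stages run in the order of the study's analyses: simulate (synthetic
inputs), discover (homology scan), fold (hairpin screen), phylo, promoter,
target, funcsim, qpcr.  One root seed is expanded deterministically into
per-stage seeds; identical config + seed gives byte-identical outputs.
Every stage writes its tables plus a machine-parseable JSON summary.
"""

from __future__ import annotations

import copy
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, references
from .funcsim import similarity_pipeline, triangular_table
from .hairpin import characterize, screen_candidates
from .homology import scan_genome
from .io import read_fasta, write_fasta, write_tsv, write_vienna
from .phylogeny import bootstrap_support, distance_matrix, star_align, to_newick
from .promoter import DEFAULT_MOTIFS, build_presence_matrix, prevalence_summary
from .qpcr import fold_change_table
from .synthetic import (
    QpcrDesign,
    block_function_matrix,
    default_reference_precursors,
    generate_ct_table,
    generate_genome,
    generate_promoters,
    generate_transcripts,
)
from .targets import PenaltyWeights, scan_transcripts

log = logging.getLogger("mir166kit")

STAGES = [
    "simulate", "discover", "fold", "phylo",
    "promoter", "target", "funcsim", "qpcr",
]

#: Default fold-change profile for the synthetic qPCR design; the magnitudes
#: emulate strong freezing induction alongside milder salt responses.
_DEFAULT_FOLD_PROFILE = {
    ("Vco-miR166h-3p", "freezing", 2.0): 18.6,
    ("Vco-miR166i-3p", "freezing", 2.0): 28.6,
    ("Vco-miR166g-3p", "freezing", 2.0): 6.0,
    ("Vco-miR166h-3p", "freezing", 6.0): 2.5,
    ("Vco-miR166i-3p", "freezing", 6.0): 3.0,
    ("Vco-miR166g-5p", "salt", 6.0): 6.9,
    ("Vco-miR166g-5p", "salt", 9.0): 6.0,
    ("Vco-miR166h-5p", "salt", 9.0): 0.4,
    ("Vco-miR166i-5p", "salt", 9.0): 0.5,
}


def default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "outdir": "results/pipeline",
        "stages": {s: True for s in STAGES},
        "paths": {
            "genome": None,
            "reference_precursors": None,
            "promoters": None,
            "transcripts": None,
            "function_matrix": None,
            "ct_table": None,
        },
        "simulate": {
            "n_scaffolds": 2,
            "scaffold_len": 3000,
            "n_implants": 3,
            "mutation_rate": 0.05,
            "promoter_len": 1600,
            "transcript_len": 300,
            "noise_sd": 0.2,
        },
        "discover": {"min_identity": 0.85, "min_coverage": 0.8, "flank": 0},
        "fold": {
            "max_nm": 4,
            "min_mfei": 0.85,
            "max_mfe": -15.0,
            "max_mismatch": 3,
        },
        "phylo": {"bootstrap": 100},
        "promoter": {"both_strands": True},
        "target": {"cutoff": 5.0},
        "qpcr": {"alpha": 0.05, "control_timepoint": 0.0},
    }


def load_config(path) -> dict:
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    for key, value in user.items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def validate(config: dict) -> list[str]:
    """Exhaustive field checks; returns a list of error strings (empty = ok)."""
    errors: list[str] = []
    cfg = config

    def _num(section, key, lo=None, hi=None, integer=False):
        try:
            v = cfg[section][key]
        except (KeyError, TypeError):
            errors.append(f"{section}.{key}: missing")
            return
        if isinstance(v, bool) or not isinstance(v, (int, float)):
            errors.append(f"{section}.{key}: not a number ({v!r})")
            return
        if integer and not isinstance(v, int):
            errors.append(f"{section}.{key}: not an integer ({v!r})")
            return
        if lo is not None and v < lo:
            errors.append(f"{section}.{key}: must be >= {lo} (got {v})")
        if hi is not None and v > hi:
            errors.append(f"{section}.{key}: must be <= {hi} (got {v})")

    if not isinstance(cfg.get("seed"), int) or isinstance(cfg.get("seed"), bool):
        errors.append("seed: must be an integer")
    stages = cfg.get("stages", {})
    for s in STAGES:
        if not isinstance(stages.get(s), bool):
            errors.append(f"stages.{s}: must be true or false")
    _num("simulate", "n_scaffolds", lo=1, integer=True)
    _num("simulate", "scaffold_len", lo=200, integer=True)
    _num("simulate", "n_implants", lo=0, integer=True)
    _num("simulate", "mutation_rate", lo=0.0, hi=0.999)
    _num("simulate", "promoter_len", lo=20, integer=True)
    _num("simulate", "transcript_len", lo=30, integer=True)
    _num("simulate", "noise_sd", lo=0.0)
    _num("discover", "min_identity", lo=0.0, hi=1.0)
    _num("discover", "min_coverage", lo=0.0, hi=1.0)
    _num("discover", "flank", lo=0, integer=True)
    _num("fold", "max_nm", lo=0, integer=True)
    _num("fold", "min_mfei", lo=0.0)
    _num("fold", "max_mfe", hi=0.0)
    _num("fold", "max_mismatch", lo=0, integer=True)
    _num("phylo", "bootstrap", lo=1, integer=True)
    _num("target", "cutoff", lo=0.0)
    _num("qpcr", "alpha", lo=0.0, hi=1.0)
    paths = cfg.get("paths", {})
    if isinstance(stages, dict):
        simulate_on = stages.get("simulate", False)
        needed_without_sim = {
            "discover": ["genome", "reference_precursors"],
            "promoter": ["promoters"],
            "target": ["transcripts"],
            "funcsim": ["function_matrix"],
            "qpcr": ["ct_table"],
        }
        for stage, keys in needed_without_sim.items():
            if not stages.get(stage):
                continue
            for key in keys:
                p = paths.get(key)
                if p is None and not simulate_on:
                    errors.append(
                        f"paths.{key}: required when stage {stage!r} is "
                        f"enabled without the simulate stage"
                    )
                elif p is not None and not Path(p).exists():
                    errors.append(f"paths.{key}: file not found ({p})")
    return errors


def _stage_seeds(root_seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(root_seed)
    children = ss.spawn(len(STAGES))
    return {
        stage: int(child.generate_state(1)[0] % (2**31))
        for stage, child in zip(STAGES, children)
    }


def _write_summary(outdir: Path, stage: str, payload: dict) -> None:
    payload = {"stage": stage, "version": __version__, **payload}
    with open(outdir / f"{stage}_summary.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run(config: dict, only: list[str] | None = None) -> dict:
    """Execute enabled stages in order; returns the run summary.

    Config validation errors abort before any stage runs; a stage failure
    aborts with the stage named in the raised error.
    """
    errors = validate(config)
    if errors:
        raise ValueError("invalid config: " + "; ".join(errors))
    cfg = copy.deepcopy(config)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg["seed"])
    summary: dict[str, dict] = {}
    enabled = [
        s
        for s in STAGES
        if cfg["stages"].get(s) and (only is None or s in only)
    ]
    for stage in enabled:
        log.info("stage %s: starting (seed %d)", stage, seeds[stage])
        try:
            payload = _STAGE_FUNCS[stage](cfg, outdir, seeds[stage])
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        payload["seed"] = seeds[stage]
        _write_summary(outdir, stage, payload)
        summary[stage] = payload
        log.info("stage %s: done", stage)
    with open(outdir / "run_summary.json", "w") as fh:
        json.dump(
            {"seed": cfg["seed"], "version": __version__, "stages": summary},
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")
    return summary


def _path(cfg, outdir: Path, key: str, default_name: str) -> Path:
    p = cfg["paths"].get(key)
    return Path(p) if p else outdir / default_name


def _stage_simulate(cfg, outdir: Path, seed: int) -> dict:
    p = cfg["simulate"]
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(2**31))  # noqa: E731
    refs = default_reference_precursors(seed=sub())
    genome, truths = generate_genome(
        refs,
        n_scaffolds=p["n_scaffolds"],
        scaffold_len=p["scaffold_len"],
        n_implants=p["n_implants"],
        mutation_rate=p["mutation_rate"],
        seed=sub(),
    )
    write_fasta(refs, outdir / "reference_precursors.fasta")
    write_fasta(genome, outdir / "genome.fasta")
    write_tsv(pd.DataFrame([vars(t) for t in truths]), outdir / "implant_truth.tsv")
    spec = references.promoter_element_matrix()
    promoters, planted = generate_promoters(
        spec, promoter_len=p["promoter_len"], seed=sub()
    )
    write_fasta(promoters, outdir / "promoters.fasta")
    write_tsv(
        pd.DataFrame([vars(t) for t in planted]), outdir / "promoter_truth.tsv"
    )
    mirnas = dict(references.MATURE_MIR166)
    penalties = [0.0, 1.0, 2.0, 3.0, 0.5, 1.5]
    site_spec = [
        (mid, f"transcript_{i % 3 + 1}", penalties[i % len(penalties)])
        for i, mid in enumerate(mirnas)
    ]
    transcripts, planted_sites = generate_transcripts(
        mirnas, site_spec, transcript_len=p["transcript_len"], seed=sub()
    )
    write_fasta(mirnas, outdir / "mature_mirnas.fasta")
    write_fasta(transcripts, outdir / "transcripts.fasta")
    write_tsv(
        pd.DataFrame([vars(t) for t in planted_sites]),
        outdir / "target_truth.tsv",
    )
    mirna_ids = list(mirnas)
    fm = block_function_matrix(
        [m for m in mirna_ids if m.endswith("3p")],
        [m for m in mirna_ids if m.endswith("5p")],
        seed=sub(),
    )
    fm.to_csv(outdir / "function_matrix.tsv", sep="\t")
    design = QpcrDesign(
        treatments={
            "freezing": [0.0, 0.5, 1.0, 2.0, 4.0, 6.0],
            "salt": [0.0, 1.0, 2.0, 6.0, 9.0, 12.0, 24.0],
        },
        fold_profile=dict(_DEFAULT_FOLD_PROFILE),
        genes=sorted(mirnas),
        noise_sd=p["noise_sd"],
    )
    ct = generate_ct_table(design, seed=sub())
    write_tsv(ct, outdir / "ct_table.tsv")
    return {
        "n_scaffolds": p["n_scaffolds"],
        "n_implants": len(truths),
        "n_promoters": len(promoters),
        "n_transcripts": len(transcripts),
        "n_ct_records": len(ct),
        "params": p,
    }


def _stage_discover(cfg, outdir: Path, seed: int) -> dict:
    p = cfg["discover"]
    genome = read_fasta(_path(cfg, outdir, "genome", "genome.fasta"))
    refs = read_fasta(
        _path(cfg, outdir, "reference_precursors", "reference_precursors.fasta")
    )
    hits, candidates = scan_genome(
        refs,
        genome,
        min_identity=p["min_identity"],
        min_coverage=p["min_coverage"],
        flank=p["flank"],
    )
    rows = [
        {
            "candidate_id": h.candidate_id,
            "query_id": h.query_id,
            "scaffold_id": h.scaffold_id,
            "start": h.scaffold_span[0],
            "end": h.scaffold_span[1],
            "strand": h.strand,
            "score": h.score,
            "identity": round(h.identity, 4),
            "coverage": round(h.coverage, 4),
        }
        for h in hits
    ]
    write_tsv(pd.DataFrame(rows), outdir / "hits.tsv")
    write_fasta(candidates, outdir / "candidates.fasta")
    return {"n_hits": len(hits), "n_candidates": len(candidates), "params": p}


def _stage_fold(cfg, outdir: Path, seed: int) -> dict:
    p = cfg["fold"]
    candidates = read_fasta(outdir / "candidates.fasta")
    mature_refs = dict(references.MATURE_MIR166)
    chars = [
        characterize(
            cid, seq, mature_refs=mature_refs, max_mismatch=p["max_mismatch"]
        )
        for cid, seq in candidates.items()
    ]
    decisions = screen_candidates(
        chars, max_nm=p["max_nm"], min_mfei=p["min_mfei"], max_mfe=p["max_mfe"]
    )
    table1 = pd.DataFrame(
        [
            {
                "locus_id": c.locus_id,
                "length_nt": c.length,
                "nm": c.nm,
                "mfe": round(c.fold.mfe, 2),
                "mfei": round(c.mfei, 3) if c.mfei is not None else None,
                "gc": round(c.gc, 3),
                "simple_stemloop": c.is_simple_stemloop,
                "accepted": d.accepted,
                "reason": d.reason,
            }
            for c, d in zip(chars, decisions)
        ]
    )
    write_tsv(table1, outdir / "precursor_characteristics.tsv")
    table2 = pd.DataFrame(
        [
            {
                "mature_id": m.mature_id,
                "arm": m.arm,
                "sequence": m.sequence,
                "length": m.length,
                "best_homolog": m.best_homolog,
                "nm_to_homolog": m.nm_to_homolog,
                "start": m.span[0],
                "end": m.span[1],
            }
            for c in chars
            for m in c.matures
        ]
    )
    write_tsv(table2, outdir / "mature_annotations.tsv")
    write_vienna([(c.locus_id, c.fold) for c in chars], outdir / "structures.vienna")
    accepted = [d.locus_id for d in decisions if d.accepted]
    return {
        "n_candidates": len(chars),
        "n_accepted": len(accepted),
        "accepted": accepted,
        "params": p,
    }


def _stage_phylo(cfg, outdir: Path, seed: int) -> dict:
    p = cfg["phylo"]
    accepted = pd.read_csv(outdir / "precursor_characteristics.tsv", sep="\t")
    candidates = read_fasta(outdir / "candidates.fasta")
    refs = read_fasta(
        _path(cfg, outdir, "reference_precursors", "reference_precursors.fasta")
    )
    keep = set(accepted.loc[accepted["accepted"], "locus_id"])
    seqs = {**refs, **{k: v for k, v in candidates.items() if k in keep}}
    if len(seqs) < 2:
        raise ValueError("fewer than two sequences for phylogeny")
    alignment = star_align(seqs)
    tree = bootstrap_support(alignment, n_replicates=p["bootstrap"], seed=seed)
    dm = distance_matrix(alignment)
    pd.DataFrame(dm.d, index=dm.labels, columns=dm.labels).to_csv(
        outdir / "distance_matrix.tsv", sep="\t"
    )
    newick = to_newick(tree, with_support=True)
    (outdir / "precursor_tree.nwk").write_text(newick + "\n")
    return {"n_taxa": len(seqs), "n_bootstrap": p["bootstrap"], "params": p}


def _stage_promoter(cfg, outdir: Path, seed: int) -> dict:
    p = cfg["promoter"]
    promoters = read_fasta(_path(cfg, outdir, "promoters", "promoters.fasta"))
    matrix, hits = build_presence_matrix(
        promoters, DEFAULT_MOTIFS, both_strands=p["both_strands"]
    )
    rows = [
        {
            "promoter": pid,
            "motif": h.motif,
            "category": h.category,
            "position": h.position,
            "strand": h.strand,
        }
        for pid, hlist in hits.items()
        for h in hlist
    ]
    write_tsv(pd.DataFrame(rows), outdir / "promoter_hits.tsv")
    matrix.to_csv(outdir / "presence_matrix.tsv", sep="\t")
    summary = prevalence_summary(matrix)
    write_tsv(summary, outdir / "prevalence.tsv")
    return {
        "n_promoters": len(promoters),
        "n_hits": len(rows),
        "params": p,
    }


def _stage_target(cfg, outdir: Path, seed: int) -> dict:
    p = cfg["target"]
    mirnas = read_fasta(outdir / "mature_mirnas.fasta")
    transcripts = read_fasta(_path(cfg, outdir, "transcripts", "transcripts.fasta"))
    weights = PenaltyWeights(cutoff=p["cutoff"])
    rows = []
    n_sites = 0
    for mid, mseq in mirnas.items():
        sites = scan_transcripts(
            mid, mseq, transcripts, cutoff=p["cutoff"], weights=weights
        )
        n_sites += len(sites)
        rows.extend(
            {
                "mirna_id": s.mirna_id,
                "transcript_id": s.transcript_id,
                "start": s.transcript_span[0],
                "end": s.transcript_span[1],
                "expectation": s.expectation,
                "inhibition": s.inhibition,
            }
            for s in sites
        )
    write_tsv(pd.DataFrame(rows), outdir / "target_sites.tsv")
    return {"n_mirnas": len(mirnas), "n_sites": n_sites, "params": p}


def _stage_funcsim(cfg, outdir: Path, seed: int) -> dict:
    fm = pd.read_csv(
        _path(cfg, outdir, "function_matrix", "function_matrix.tsv"),
        sep="\t",
        index_col=0,
    ).astype(bool)
    report = similarity_pipeline(fm)
    report.similarity.round(4).to_csv(outdir / "similarity.tsv", sep="\t")
    report.distance.round(4).to_csv(outdir / "nei_distance.tsv", sep="\t")
    triangular_table(report).to_csv(outdir / "similarity_distance_table.tsv", sep="\t")
    (outdir / "function_tree.nwk").write_text(
        to_newick(report.tree) + "\n"
    )
    return {
        "n_mirnas": len(fm),
        "max_similarity_pair": list(report.max_pair),
        "min_similarity_pair": list(report.min_pair),
    }


def _stage_qpcr(cfg, outdir: Path, seed: int) -> dict:
    p = cfg["qpcr"]
    ct = pd.read_csv(_path(cfg, outdir, "ct_table", "ct_table.tsv"), sep="\t")
    genes = sorted(g for g in ct["gene"].unique() if g != "U6")
    table = fold_change_table(
        ct,
        genes,
        control_timepoint=p["control_timepoint"],
        alpha=p["alpha"],
    )
    table = table.copy()
    table["mean_fold"] = table["mean_fold"].round(4)
    table["sd_fold"] = table["sd_fold"].round(4)
    write_tsv(table, outdir / "fold_changes.tsv")
    return {"n_genes": len(genes), "n_rows": len(table), "params": p}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "discover": _stage_discover,
    "fold": _stage_fold,
    "phylo": _stage_phylo,
    "promoter": _stage_promoter,
    "target": _stage_target,
    "funcsim": _stage_funcsim,
    "qpcr": _stage_qpcr,
}
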