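"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the study's input universe at desk scale: genome
scaffolds with implanted, point-mutated precursor hairpins; 1,600-bp promoter
windows with cis-elements planted per a specification matrix; transcripts
with miRNA target sites at chosen penalty scores; and Ct tables realizing
specified fold-change profiles under Gaussian Ct-scale noise.  Backgrounds
are i.i.d. uniform A/C/G/T — the simplest null that cannot systematically
mimic an implant.  All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import references
from .promoter import DEFAULT_MOTIFS, MotifDefinition, MotifHit, scan_promoter
from .seq import iupac_regex, revcomp, to_dna
from .targets import DEFAULT_WEIGHTS, PenaltyWeights

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ImplantTruth:
    scaffold_id: str
    start: int  # 1-based inclusive
    end: int
    source_precursor_id: str
    mutation_count: int
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class PlantedMotif:
    promoter_id: str
    motif: str
    category: str
    position: int  # 1-based, + strand
    strand: str


@dataclass(frozen=True)
class PlantedSite:
    mirna_id: str
    transcript_id: str
    start: int  # 1-based inclusive
    end: int
    penalty: float


@dataclass
class QpcrDesign:
    """Replicate structure and true fold-change profile of a qPCR experiment.

    ``fold_profile`` maps (gene, treatment, timepoint_h) -> true fold change
    relative to the 0-h control; unspecified cells default to 1.  Three
    biological x three technical replicates mirror the study design.
    """

    treatments: dict[str, list[float]]  # treatment -> timepoints (h)
    fold_profile: dict[tuple[str, str, float], float]
    genes: list[str] = field(default_factory=list)
    reference: str = "U6"
    n_bio: int = 3
    n_tech: int = 3
    noise_sd: float = 0.2  # Ct units, technical noise
    loading_sd: float = 0.5  # per-sample shift removed by dCt

    def __post_init__(self):
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for treatment, timepoints in self.treatments.items():
            if 0.0 not in timepoints:
                raise ValueError(
                    f"treatment {treatment!r} lacks the 0-h control timepoint"
                )
        for (gene, treatment, tp), fold in self.fold_profile.items():
            if fold <= 0:
                raise ValueError(f"fold must be > 0: {(gene, treatment, tp)}")
            if treatment not in self.treatments:
                raise ValueError(f"unknown treatment {treatment!r} in profile")
            if tp not in self.treatments[treatment]:
                raise ValueError(f"unknown timepoint {tp} for {treatment!r}")
        if not self.genes:
            self.genes = sorted({g for g, _, _ in self.fold_profile})


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _nonpairing_base(partner: str, rng: np.random.Generator) -> str:
    """A base from {A, C} that neither WC- nor wobble-pairs ``partner``."""
    if partner == "T":
        return "C"  # A would pair T
    if partner == "G":
        return "A"  # C would pair G
    return "A" if rng.random() < 0.5 else "C"


def synthesize_precursor(
    mature_3p: str,
    seed: int | np.random.Generator = 0,
    arm_mismatches: int = 2,
    stem_extension: int = 18,
    loop_len: int = 3,
) -> str:
    """Construct a hairpin-forming precursor (DNA) around a 3'-arm mature.

    Layout 5'->3': [rc(extension) rc(mature)] - loop - [mature extension].
    The engineered arm mismatches fall in the extension region, outside the
    mature duplex, so the NM statistic of a clean candidate is 0.

    The loop is all-A at the fold model's minimum size.  Under the flat
    pair-energy model any larger or mixed-composition loop can trade its
    bases into shallow-stem helices at zero energy cost, which scrambles the
    detected loop; with a minimal loop every such rearrangement must abandon
    designed stem pairs and is strictly suboptimal.  Unpaired flanking
    spacers are absent for the same reason.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mature = to_dna(mature_3p)
    ext = _random_seq(rng, stem_extension)
    arm5 = list(revcomp(mature + ext))  # = rc(ext) + rc(mature)
    mm_positions = rng.choice(
        stem_extension, size=min(arm_mismatches, stem_extension), replace=False
    )
    for p in sorted(int(x) for x in mm_positions):
        partner = ext[stem_extension - 1 - p]
        arm5[p] = _nonpairing_base(partner, rng)
    loop = "A" * loop_len
    return "".join(arm5) + loop + mature + ext


def default_reference_precursors(seed: int = 12) -> dict[str, str]:
    """Three hairpin-forming reference precursors built around the 3'-arm
    mature miR166 sequences of the study family."""
    rng = np.random.default_rng(seed)
    out = {}
    for mid in ("Vco-miR166g-3p", "Vco-miR166h-3p", "Vco-miR166i-3p"):
        locus = mid.removesuffix("-3p")
        out[f"{locus}-pre"] = synthesize_precursor(
            references.MATURE_MIR166[mid], seed=rng
        )
    return out


def generate_genome(
    reference_precursors: dict[str, str],
    n_scaffolds: int = 2,
    scaffold_len: int = 3000,
    n_implants: int = 5,
    mutation_rate: float = 0.05,
    seed: int = 0,
    max_retries: int = 200,
) -> tuple[dict[str, str], list[ImplantTruth]]:
    """Uniform-background scaffolds with implanted mutated precursors.

    Each implant copies one reference precursor (cycling through the set)
    with independent per-base substitution probability ``mutation_rate``,
    placed uniformly at random without overlapping other implants, on a
    random strand.  Placement failures after bounded retries raise.
    """
    if not reference_precursors:
        raise ValueError("need at least one reference precursor")
    if not 0 <= mutation_rate < 1:
        raise ValueError("mutation_rate must be in [0, 1)")
    max_len = max(len(s) for s in reference_precursors.values())
    if scaffold_len <= max_len:
        raise ValueError("scaffold_len must exceed the longest precursor")
    rng = np.random.default_rng(seed)
    scaffolds = {
        f"scaffold_{i + 1}": list(_random_seq(rng, scaffold_len))
        for i in range(n_scaffolds)
    }
    occupied: dict[str, list[tuple[int, int]]] = {sid: [] for sid in scaffolds}
    truths: list[ImplantTruth] = []
    ref_ids = list(reference_precursors)
    for idx in range(n_implants):
        ref_id = ref_ids[idx % len(ref_ids)]
        source = to_dna(reference_precursors[ref_id])
        bases = list(source)
        mutation_count = 0
        for p in range(len(bases)):
            if rng.random() < mutation_rate:
                options = [b for b in "ACGT" if b != bases[p]]
                bases[p] = options[int(rng.integers(len(options)))]
                mutation_count += 1
        implant = "".join(bases)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = "".join(implant) if strand == "+" else revcomp(implant)
        for attempt in range(max_retries):
            sid = f"scaffold_{int(rng.integers(n_scaffolds)) + 1}"
            start0 = int(rng.integers(scaffold_len - len(placed) + 1))
            span = (start0 + 1, start0 + len(placed))
            if all(
                span[1] < s or span[0] > e for s, e in occupied[sid]
            ):
                scaffolds[sid][start0 : start0 + len(placed)] = list(placed)
                occupied[sid].append(span)
                truths.append(
                    ImplantTruth(
                        scaffold_id=sid,
                        start=span[0],
                        end=span[1],
                        source_precursor_id=ref_id,
                        mutation_count=mutation_count,
                        strand=strand,
                    )
                )
                break
        else:
            raise RuntimeError(
                f"could not place implant {idx + 1} after {max_retries} retries"
            )
    return {sid: "".join(chars) for sid, chars in scaffolds.items()}, truths


def _site_violates(site: str, false_motifs) -> bool:
    """True when the realized site itself contains a FALSE-category motif on
    either strand (such a match cannot be scrubbed without destroying the
    planted element)."""
    rc = revcomp(site)
    for m in false_motifs:
        rex = iupac_regex(m.pattern)
        if rex.search(site) or rex.search(rc):
            return True
    return False


def generate_promoters(
    element_spec: pd.DataFrame,
    motifs: list[MotifDefinition] = DEFAULT_MOTIFS,
    promoter_len: int = 1600,
    seed: int = 0,
    max_scrub_rounds: int = 200,
) -> tuple[dict[str, str], list[PlantedMotif]]:
    """Promoter windows realizing a boolean promoters x categories spec.

    For each TRUE cell one motif of the category is planted at a recorded
    position and strand.  FALSE cells are guaranteed motif-free: after
    planting, any dictionary match of a FALSE category (either strand) is
    scrubbed by local resampling outside planted spans until the rescanned
    matrix equals the spec.
    """
    by_cat: dict[str, list[MotifDefinition]] = {}
    for m in motifs:
        by_cat.setdefault(m.category, []).append(m)
    for cat in element_spec.columns:
        if cat not in by_cat:
            raise ValueError(f"no motif in dictionary for category {cat!r}")
    longest = max(len(m.pattern) for m in motifs)
    if promoter_len < longest:
        raise ValueError("promoter_len shorter than the longest motif")
    rng = np.random.default_rng(seed)
    seqs: dict[str, str] = {}
    truth: list[PlantedMotif] = []
    for pid, row in element_spec.iterrows():
        false_cats = [c for c, v in row.items() if not v]
        false_motifs = [m for m in motifs if m.category in false_cats]
        seq = list(_random_seq(rng, promoter_len))
        planted_spans: list[tuple[int, int]] = []  # 0-based half-open
        planted: list[PlantedMotif] = []
        for cat, present in row.items():
            if not present:
                continue
            shuffled = list(by_cat[cat])
            rng.shuffle(shuffled)
            motif = site = None
            for cand in shuffled:
                for _ in range(20):  # degenerate patterns: retry realizations
                    realized = _realize_pattern(cand.pattern, rng)
                    if not _site_violates(realized, false_motifs):
                        motif, site = cand, realized
                        break
                if motif is not None:
                    break
            if motif is None:
                raise ValueError(
                    f"no motif of category {cat!r} can be planted in {pid!r} "
                    f"without violating a FALSE category"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            placed = site if strand == "+" else revcomp(site)
            for _ in range(200):
                start0 = int(rng.integers(promoter_len - len(placed) + 1))
                span = (start0, start0 + len(placed))
                if all(span[1] <= s or span[0] >= e for s, e in planted_spans):
                    break
            else:
                raise RuntimeError(f"could not place motif {motif.name} in {pid}")
            seq[span[0] : span[1]] = list(placed)
            planted_spans.append(span)
            planted.append(PlantedMotif(pid, motif.name, cat, span[0] + 1, strand))
        _scrub_false_matches(
            seq, false_motifs, planted_spans, rng, max_scrub_rounds, pid
        )
        seqs[pid] = "".join(seq)
        truth.extend(planted)
    return seqs, truth


def _realize_pattern(pattern: str, rng: np.random.Generator) -> str:
    from .seq import IUPAC

    return "".join(
        IUPAC[ch][int(rng.integers(len(IUPAC[ch])))]
        for ch in pattern.upper().replace("U", "T")
    )


def _scrub_false_matches(
    seq: list[str], false_motifs, planted_spans, rng, max_rounds: int, pid: str
) -> None:
    protected = set()
    for s, e in planted_spans:
        protected.update(range(s, e))
    for _ in range(max_rounds):
        violations = []
        text = "".join(seq)
        rc_text = revcomp(text)
        n = len(text)
        for m in false_motifs:
            rex = iupac_regex(m.pattern)
            for match in rex.finditer(text):
                violations.append((match.start(), match.end()))
            for match in rex.finditer(rc_text):
                violations.append((n - match.end(), n - match.start()))
        if not violations:
            return
        for s, e in violations:
            editable = [p for p in range(s, e) if p not in protected]
            if not editable:
                raise RuntimeError(
                    f"FALSE-category match inside planted motifs of {pid}"
                )
            p = editable[int(rng.integers(len(editable)))]
            options = [b for b in "ACGT" if b != seq[p]]
            seq[p] = options[int(rng.integers(len(options)))]
    raise RuntimeError(f"could not scrub FALSE-category matches in {pid}")


def rescan_matrix(
    seqs: dict[str, str],
    motifs: list[MotifDefinition] = DEFAULT_MOTIFS,
    categories=None,
) -> pd.DataFrame:
    """Presence matrix of generated promoters (round-trip convenience)."""
    from .promoter import presence_matrix

    cats = categories or references.CIS_ELEMENT_CATEGORIES
    hits: dict[str, list[MotifHit]] = {
        pid: scan_promoter(s, motifs) for pid, s in seqs.items()
    }
    return presence_matrix(hits, cats)


# --- transcripts with planted target sites ---------------------------------

_MISMATCH_BASE = {"A": "C", "C": "A", "G": "A", "U": "C"}
_GU_BASE = {"G": "T", "U": "G"}


def _penalty_edits(
    mirna: str, penalty: float, weights: PenaltyWeights
) -> list[tuple[int, str]]:
    """Decompose a penalty into per-position edits of the perfect site.

    Returns (miRNA position, kind) pairs, kind in {mismatch, gu}; uses seed
    mismatches (2x mismatch weight), then non-seed mismatches, then non-seed
    G:U wobbles for half-unit remainders.  Raises when the penalty is not
    achievable for this miRNA under the scoring scheme.
    """
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    if (weights.mismatch, weights.gu, weights.seed_factor) != (1.0, 0.5, 2.0):
        raise NotImplementedError(
            "penalty decomposition supports the default weight scheme only"
        )
    u = round(penalty * 2)
    if not math.isclose(u / 2.0, penalty, abs_tol=1e-9):
        raise ValueError("penalty must be a multiple of 0.5 under these weights")
    L = len(mirna)
    s0, s1 = weights.seed_span
    seed_all = list(range(s0, min(s1, L) + 1))
    # spread seed mismatches out (every third position first)
    seed_pos = seed_all[1::3] + [p for p in seed_all if p not in seed_all[1::3]]
    nonseed = sorted(
        (p for p in range(1, L + 1) if p not in seed_all), reverse=True
    )
    edits: list[tuple[int, str]] = []
    if u % 2 == 1:  # one 0.5 half-unit: a non-seed G:U wobble
        gu_ok = [p for p in nonseed if mirna[p - 1] in _GU_BASE]
        if not gu_ok:
            raise ValueError(
                f"penalty {penalty} not achievable: no non-seed G/U position"
            )
        nonseed.remove(gu_ok[0])
        edits.append((gu_ok[0], "gu"))
        u -= 1
    points = u // 2  # 1 point = 1.0 penalty
    n_seed_mm = min(points // 2, len(seed_pos))  # seed mismatch = 2 points
    for _ in range(n_seed_mm):
        edits.append((seed_pos.pop(0), "mismatch"))
        points -= 2
    while points > 0 and nonseed:  # non-seed mismatch = 1 point
        edits.append((nonseed.pop(0), "mismatch"))
        points -= 1
    while points > 0:  # seed G:U wobble = 1 point
        gu_ok = [p for p in seed_pos if mirna[p - 1] in _GU_BASE]
        if not gu_ok:
            raise ValueError(f"penalty {penalty} not achievable for this miRNA")
        seed_pos.remove(gu_ok[0])
        edits.append((gu_ok[0], "gu"))
        points -= 1
    return edits


def build_target_site(
    mirna: str, penalty: float, weights: PenaltyWeights = DEFAULT_WEIGHTS
) -> str:
    """Transcript-sense site (DNA) scoring exactly ``penalty`` against the
    miRNA: the reverse complement with controlled edits."""
    from .seq import to_rna

    m = to_rna(mirna)
    L = len(m)
    site = list(revcomp(m))  # perfect complement, transcript sense
    for pos, kind in _penalty_edits(m, penalty, weights):
        base = m[pos - 1]
        table = _MISMATCH_BASE if kind == "mismatch" else _GU_BASE
        site[L - pos] = table[base].replace("U", "T")
    return "".join(site)


def generate_transcripts(
    mirnas: dict[str, str],
    site_spec: list[tuple[str, str, float]],
    transcript_len: int = 300,
    seed: int = 0,
    weights: PenaltyWeights = DEFAULT_WEIGHTS,
) -> tuple[dict[str, str], list[PlantedSite]]:
    """Transcripts with target sites planted at requested penalties.

    ``site_spec`` lists (mirna_id, transcript_id, penalty); each planted site
    is the reverse complement of the miRNA with controlled edits realizing
    the penalty, at a recorded non-overlapping position.
    """
    rng = np.random.default_rng(seed)
    tids: list[str] = []
    for _, tid, _ in site_spec:
        if tid not in tids:
            tids.append(tid)
    seqs = {tid: list(_random_seq(rng, transcript_len)) for tid in tids}
    spans: dict[str, list[tuple[int, int]]] = {tid: [] for tid in tids}
    truth: list[PlantedSite] = []
    for mirna_id, tid, penalty in site_spec:
        if mirna_id not in mirnas:
            raise ValueError(f"unknown miRNA {mirna_id!r}")
        site = build_target_site(mirnas[mirna_id], penalty, weights)
        if transcript_len < len(site):
            raise ValueError("transcript_len shorter than a target site")
        for _ in range(200):
            start0 = int(rng.integers(transcript_len - len(site) + 1))
            # keep a one-site margin so collapsed scan loci stay distinct
            span = (start0 - len(site), start0 + 2 * len(site))
            if all(span[1] <= s or span[0] >= e for s, e in spans[tid]):
                break
        else:
            raise RuntimeError(f"could not place site on {tid}")
        seqs[tid][start0 : start0 + len(site)] = list(site)
        spans[tid].append(span)
        truth.append(
            PlantedSite(mirna_id, tid, start0 + 1, start0 + len(site), penalty)
        )
    return {tid: "".join(chars) for tid, chars in seqs.items()}, truth


# --- Ct tables --------------------------------------------------------------


def generate_ct_table(design: QpcrDesign, seed: int = 0) -> pd.DataFrame:
    """Ct records realizing the design's fold profile.

    Ct(target) = base Ct - log2(true fold) + sample shift + N(0, noise_sd);
    the reference gene shares the per-sample shift, so dCt removes it.
    """
    rng = np.random.default_rng(seed)
    base_ct = {g: 22.0 + 2.0 * rng.random() for g in design.genes}
    ref_ct = 18.0
    rows = []
    for treatment, timepoints in design.treatments.items():
        for tp in timepoints:
            for bio in range(1, design.n_bio + 1):
                shift = rng.normal(0.0, design.loading_sd)
                sample = f"{treatment}_{tp:g}h_b{bio}"
                for tech in range(1, design.n_tech + 1):
                    rows.append(
                        {
                            "sample": sample,
                            "treatment": treatment,
                            "timepoint_h": tp,
                            "gene": design.reference,
                            "replicate_bio": bio,
                            "replicate_tech": tech,
                            "ct": ref_ct
                            + shift
                            + rng.normal(0.0, design.noise_sd),
                        }
                    )
                for gene in design.genes:
                    fold = design.fold_profile.get((gene, treatment, tp), 1.0)
                    for tech in range(1, design.n_tech + 1):
                        rows.append(
                            {
                                "sample": sample,
                                "treatment": treatment,
                                "timepoint_h": tp,
                                "gene": gene,
                                "replicate_bio": bio,
                                "replicate_tech": tech,
                                "ct": base_ct[gene]
                                - math.log2(fold)
                                + shift
                                + rng.normal(0.0, design.noise_sd),
                            }
                        )
    return pd.DataFrame(rows)


def block_function_matrix(
    mirna_ids_a: list[str],
    mirna_ids_b: list[str],
    n_shared: int = 6,
    n_private: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary function matrix with two-block structure: members within a
    block share ``n_shared`` function labels plus ``n_private`` private ones;
    blocks share nothing.  Used to exercise DICE/Nei/UPGMA clustering."""
    rng = np.random.default_rng(seed)
    cols: list[str] = []
    rows: dict[str, set[str]] = {m: set() for m in mirna_ids_a + mirna_ids_b}
    for block, members in (("A", mirna_ids_a), ("B", mirna_ids_b)):
        shared = [f"fn_{block}_shared_{i}" for i in range(n_shared)]
        cols.extend(shared)
        for m in members:
            rows[m].update(shared)
            private = [f"fn_{block}_{m}_{i}" for i in range(n_private)]
            cols.extend(private)
            rows[m].update(private)
            # drop one shared label at random for within-block variation
            if n_shared > 1 and rng.random() < 0.5:
                rows[m].discard(shared[int(rng.integers(n_shared))])
    data = {
        m: {c: (c in fns) for c in cols} for m, fns in rows.items()
    }
    return pd.DataFrame.from_dict(data, orient="index")[cols]
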