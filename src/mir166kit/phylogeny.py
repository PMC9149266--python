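"""UPGMA phylogenetics with bootstrap support.

Distances are p-distances on a supplied alignment (gapped columns are
excluded pairwise); clustering is arithmetic-mean UPGMA, which yields rooted
ultrametric trees.  Bootstrap support of an internal node is the percentage
of column-resampled replicates whose UPGMA tree contains the same leaf set.
A small star-guided progressive aligner is provided for convenience; the
canonical input is an alignment produced elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .homology import DEFAULT_SCHEME, ScoringScheme
from .seq import to_dna

_EPS = 1e-12


@dataclass
class Clade:
    label: Optional[str] = None  # leaf name
    children: list["Clade"] = field(default_factory=list)
    height: float = 0.0  # distance-units above the leaves
    support: Optional[float] = None  # percent, internal nodes only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        return frozenset().union(*(c.leaves() for c in self.children))

    def internal_nodes(self):
        if not self.is_leaf:
            yield self
            for c in self.children:
                yield from c.internal_nodes()

    def leaf_depths(self):
        """Yield (label, root-to-leaf path length) summed over branch lengths."""

        def walk(node: "Clade", acc: float):
            if node.is_leaf:
                yield node.label, acc
                return
            for c in node.children:
                yield from walk(c, acc + (node.height - c.height))

        yield from walk(self, 0.0)


def p_distance(a: str, b: str) -> float:
    """Proportion of differing columns among columns where both sequences
    have a residue; gapped columns are excluded entirely."""
    if len(a) != len(b):
        raise ValueError("aligned sequences must have equal length")
    comparable = diff = 0
    for x, y in zip(a.upper(), b.upper()):
        if x in "-." or y in "-.":
            continue
        comparable += 1
        if x != y:
            diff += 1
    if comparable == 0:
        raise ValueError("no comparable (gap-free) columns")
    return diff / comparable


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix must be finite")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(self.d < 0):
            raise ValueError("distances must be non-negative")


def distance_matrix(alignment: dict[str, str]) -> DistanceMatrix:
    labels = list(alignment)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = p_distance(alignment[labels[i]], alignment[labels[j]])
    return DistanceMatrix(labels, d)


def upgma(dm: DistanceMatrix) -> Clade:
    """Arithmetic-mean UPGMA.

    The closest pair merges at height = d/2; merged distances are
    size-weighted averages.  Ties are broken by the lexicographically
    smallest pair of cluster labels (a cluster is labelled by its smallest
    leaf label).
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes = {i: Clade(label=lab) for i, lab in enumerate(dm.labels)}
    sizes = {i: 1 for i in range(n)}
    minlab = {i: lab for i, lab in enumerate(dm.labels)}
    d = {
        (i, j): dm.d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if i >= j:
                    continue
                key = (d[(i, j)], *sorted((minlab[i], minlab[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        (dist, *_), i, j = best
        children = sorted((nodes[i], nodes[j]), key=lambda c: min(c.leaves()))
        node = Clade(children=children, height=dist / 2.0)
        for k in sorted(active - {i, j}):
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            d[(k, next_id)] = (sizes[i] * dik + sizes[j] * djk) / (
                sizes[i] + sizes[j]
            )
        nodes[next_id] = node
        sizes[next_id] = sizes[i] + sizes[j]
        minlab[next_id] = min(minlab[i], minlab[j])
        active -= {i, j}
        active.add(next_id)
        next_id += 1
    return nodes[max(active)]


def _fmt(x: float) -> str:
    return f"{x + 0.0:.10g}"  # + 0.0 normalizes IEEE negative zero


def to_newick(tree: Clade, with_support: bool = False) -> str:
    def render(node: Clade, parent_height: float) -> str:
        bl = _fmt(parent_height - node.height)
        if node.is_leaf:
            return f"{node.label}:{bl}"
        inner = ",".join(render(c, node.height) for c in node.children)
        sup = ""
        if with_support and node.support is not None:
            sup = _fmt(node.support)
        return f"({inner}){sup}:{bl}"

    if tree.is_leaf:
        return f"{tree.label};"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    sup = _fmt(tree.support) if with_support and tree.support is not None else ""
    return f"({inner}){sup};"


def is_ultrametric(tree: Clade, tol: float = 1e-9) -> bool:
    depths = [depth for _, depth in tree.leaf_depths()]
    return max(depths) - min(depths) <= tol


def bootstrap_support(
    alignment: dict[str, str], n_replicates: int = 1000, seed: int = 0
) -> Clade:
    """UPGMA tree on the full alignment, with internal-node supports from
    column-resampled replicates (percent of replicates containing the same
    leaf set)."""
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    ncol = len(next(iter(alignment.values())))
    if ncol < 2:
        raise ValueError("alignment must have at least 2 columns")
    tree = upgma(distance_matrix(alignment))
    clade_sets = {node.leaves(): node for node in tree.internal_nodes()}
    counts = {leaves: 0 for leaves in clade_sets}
    rng = np.random.default_rng(seed)
    labels = list(alignment)
    cols = [list(alignment[lab]) for lab in labels]
    for _ in range(n_replicates):
        idx = rng.integers(0, ncol, size=ncol)
        rep = {
            lab: "".join(row[c] for c in idx) for lab, row in zip(labels, cols)
        }
        rep_tree = upgma(distance_matrix(rep))
        rep_clades = {node.leaves() for node in rep_tree.internal_nodes()}
        for leaves in counts:
            if leaves in rep_clades:
                counts[leaves] += 1
    for leaves, node in clade_sets.items():
        node.support = 100.0 * counts[leaves] / n_replicates
    return tree


def star_align(
    seqs: dict[str, str],
    guide: Optional[str] = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> dict[str, str]:
    """Progressive alignment of all sequences to a star guide.

    Each sequence is globally aligned to the guide (Needleman-Wunsch, affine
    gaps); gaps opened in the guide by any pairwise alignment are propagated
    to all rows.  Adequate for closely related precursor sets; a dedicated
    aligner should be preferred for divergent inputs.
    """
    from Bio import Align

    if guide is None:
        guide = max(seqs, key=lambda k: len(seqs[k]))
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scheme.match
    aligner.mismatch_score = scheme.mismatch
    aligner.open_gap_score = scheme.gap_open + scheme.gap_extend
    aligner.extend_gap_score = scheme.gap_extend
    gseq = to_dna(seqs[guide])
    glen = len(gseq)
    # per pairwise alignment: insertions relative to guide, keyed by guide pos
    pairwise = {}
    ins_before = [0] * (glen + 1)  # max insertion length before guide pos i
    for name, raw in seqs.items():
        s = to_dna(raw)
        if name == guide:
            pairwise[name] = {"ins": {}, "aln": [(i, s[i]) for i in range(glen)]}
            continue
        aln = aligner.align(gseq, s)[0]
        tsegs, qsegs = aln.aligned
        ins: dict[int, str] = {}
        cols: dict[int, str] = {}
        prev_t = prev_q = 0
        for (t0, t1), (q0, q1) in zip(tsegs, qsegs):
            if q0 > prev_q:  # insertion relative to guide, before guide pos t0
                ins[t0] = s[prev_q:q0]
            prev_q = q1
            for toff in range(t1 - t0):
                cols[t0 + toff] = s[q0 + toff]
            prev_t = t1
        if prev_q < len(s):
            ins[glen] = s[prev_q:]
        pairwise[name] = {"ins": ins, "cols": cols}
        for pos, frag in ins.items():
            ins_before[pos] = max(ins_before[pos], len(frag))
    out = {}
    for name in seqs:
        info = pairwise[name]
        row = []
        for pos in range(glen + 1):
            frag = info.get("ins", {}).get(pos, "") if name != guide else ""
            if name == guide:
                frag = ""
            row.append(frag.rjust(ins_before[pos], "-") if ins_before[pos] else "")
            if pos < glen:
                if name == guide:
                    row.append(gseq[pos])
                else:
                    row.append(info["cols"].get(pos, "-"))
        out[name] = "".join(row)
    return out
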