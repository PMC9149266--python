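"""DICE similarity and Nei-style distance over binary function profiles.

Each miRNA is described by the presence/absence of the functional classes of
its predicted target genes.  Pairwise DICE coefficients (2|A&B|/(|A|+|B|))
give a similarity matrix S; the genetic distance is D = -ln(S); UPGMA on D
clusters the family by target-function repertoire.  Zero-similarity pairs
have infinite Nei distance; UPGMA substitutes a configurable cap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylogeny import Clade, DistanceMatrix, upgma

INF_DISTANCE_CAP = 10.0


def dice(a, b) -> float:
    """DICE coefficient between two boolean vectors: 2|A&B| / (|A|+|B|)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("DICE undefined for two empty sets")
    return 2.0 * int((a & b).sum()) / (na + nb)


def nei_distance(s: float) -> float:
    """Nei's distance transform D = -ln(S); S = 0 maps to +inf."""
    if s < 0 or s > 1:
        raise ValueError("similarity must be in [0, 1]")
    if s == 0:
        return math.inf
    return -math.log(s)


@dataclass
class SimilarityReport:
    similarity: pd.DataFrame  # S, symmetric, unit diagonal
    distance: pd.DataFrame  # D = -ln(S), +inf where S = 0
    tree: Clade
    max_pair: tuple[str, str, float]  # most similar off-diagonal pair
    min_pair: tuple[str, str, float]
    has_infinite_distance: bool


def similarity_pipeline(
    matrix: pd.DataFrame, distance_cap: float = INF_DISTANCE_CAP
) -> SimilarityReport:
    """All pairwise DICE -> S; elementwise -ln -> D; UPGMA(D) -> tree.

    ``matrix`` is a boolean miRNAs x function-labels frame.  Rows with no
    TRUE entry make every DICE involving them undefined and raise, naming
    the row.  Infinite distances are capped (with a warning) for UPGMA only;
    the reported distance matrix keeps +inf.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two rows")
    mat = matrix.astype(bool)
    empties = [str(i) for i in mat.index[~mat.any(axis=1)]]
    if empties:
        raise ValueError(f"rows with no functions (DICE undefined): {empties}")
    ids = list(mat.index)
    n = len(ids)
    S = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            S[i, j] = S[j, i] = dice(mat.iloc[i].values, mat.iloc[j].values)
    D = np.array([[nei_distance(s) for s in row] for row in S])
    np.fill_diagonal(D, 0.0)
    has_inf = bool(np.isinf(D).any())
    D_tree = D.copy()
    if has_inf:
        warnings.warn(
            f"zero-similarity pairs: capping infinite Nei distances at "
            f"{distance_cap} for UPGMA",
            stacklevel=2,
        )
        D_tree[np.isinf(D_tree)] = distance_cap
    tree = upgma(DistanceMatrix(ids, D_tree))
    iu = np.triu_indices(n, k=1)
    off = S[iu]
    imax, imin = int(np.argmax(off)), int(np.argmin(off))
    max_pair = (ids[iu[0][imax]], ids[iu[1][imax]], float(off[imax]))
    min_pair = (ids[iu[0][imin]], ids[iu[1][imin]], float(off[imin]))
    return SimilarityReport(
        similarity=pd.DataFrame(S, index=ids, columns=ids),
        distance=pd.DataFrame(D, index=ids, columns=ids),
        tree=tree,
        max_pair=max_pair,
        min_pair=min_pair,
        has_infinite_distance=has_inf,
    )


def triangular_table(report: SimilarityReport) -> pd.DataFrame:
    """Combined table in the published layout: distances in the upper-right
    triangle, similarities in the lower-left, blank diagonal."""
    ids = list(report.similarity.index)
    out = pd.DataFrame("", index=ids, columns=ids, dtype=object)
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            if i < j:
                d = report.distance.loc[a, b]
                out.loc[a, b] = "inf" if math.isinf(d) else f"{d:.2f}"
            elif i > j:
                out.loc[a, b] = f"{report.similarity.loc[a, b]:.2f}"
    return out
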