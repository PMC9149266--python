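"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive enumeration or direct
recursion, sharing no code with the package implementations they check.
"""

from __future__ import annotations

from functools import lru_cache

PAIR_E = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


def enumerate_structures(s: str, min_loop: int = 3):
    """Yield every pseudoknot-free structure of ``s`` as a frozenset of
    0-based pairs, respecting the minimum hairpin loop."""

    def rec(i, j):
        if i >= j:
            yield frozenset()
            return
        yield from rec(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in PAIR_E:
                for left in rec(i + 1, k - 1):
                    for right in rec(k + 1, j):
                        yield left | right | {(i, k)}

    yield from rec(0, len(s) - 1)


def min_energy_bruteforce(s: str, min_loop: int = 3) -> float:
    """Minimum pair-energy sum over all enumerated nested structures."""
    best = 0.0
    for structure in enumerate_structures(s, min_loop):
        e = sum(PAIR_E[(s[i], s[k])] for i, k in structure)
        if e < best:
            best = e
    return best


def best_local_score(
    a: str,
    b: str,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -5.0,
    gap_extend: float = -1.0,
) -> float:
    """Maximum local alignment score; a gap of length k costs
    gap_open + k * gap_extend.  Memoized recursion over (i, j, last-op)
    exploring every extension, with the empty alignment scoring 0."""
    na, nb = len(a), len(b)

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, mode: int) -> float:
        best = 0.0  # stop here
        if i < na and j < nb:
            sub = match if a[i] == b[j] else mismatch
            best = max(best, sub + ext(i + 1, j + 1, 0))
        if i < na:
            cost = gap_extend + (gap_open if mode != 1 else 0.0)
            best = max(best, cost + ext(i + 1, j, 1))
        if j < nb:
            cost = gap_extend + (gap_open if mode != 2 else 0.0)
            best = max(best, cost + ext(i, j + 1, 2))
        return best

    best = 0.0
    for i in range(na + 1):
        for j in range(nb + 1):
            best = max(best, ext(i, j, 0))
    ext.cache_clear()
    return best


def best_window_expectation(mirna: str, transcript: str, weights) -> float:
    """Minimum expectation over every ungapped window of the transcript
    (no bulges), by direct evaluation."""
    from mir166kit.targets import align_window, score_duplex

    L = len(mirna)
    best = float("inf")
    for start in range(len(transcript) - L + 1):
        aln = align_window(mirna, transcript[start : start + L])
        best = min(best, score_duplex(aln, weights))
    return best
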