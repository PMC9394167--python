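"""Edit distances for aptamer sequence comparison.

The distance used for merging near-identical sequences is the restricted
Damerau-Levenshtein distance, also called the optimal string alignment
(OSA) distance: substitutions, insertions, deletions, and transpositions
of two *adjacent* characters each cost 1, and no substring may be edited
twice.  The restriction matters: for ("CA", "ABC") the unrestricted
Damerau-Levenshtein distance is 2, but OSA gives 3, and OSA is what the
common R/Python string-distance implementations compute by default.

A plain Levenshtein variant (no transpositions) is available through the
``variant`` argument for sensitivity analyses.
"""

from __future__ import annotations

import numpy as np


def osa_distance(a: str, b: str) -> int:
    """Restricted Damerau-Levenshtein (optimal string alignment) distance.

    Dynamic program over the standard three-way Levenshtein recurrence
    plus the adjacent-transposition case d[i-2][j-2] + 1 when
    a[i-1] == b[j-2] and a[i-2] == b[j-1].
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev2: list[int] = []
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ai == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                i > 1
                and j > 1
                and ai == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                d = min(d, prev2[j - 2] + 1)
            cur[j] = d
        prev2, prev = prev, cur
    return prev[lb]


def levenshtein_distance(a: str, b: str) -> int:
    """Plain Levenshtein distance (substitutions, insertions, deletions)."""
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    prev = list(range(lb + 1))
    for i in range(1, la + 1):
        cur = [i] + [0] * lb
        ai = a[i - 1]
        for j in range(1, lb + 1):
            cost = 0 if ai == b[j - 1] else 1
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
        prev = cur
    return prev[lb]


def edit_distance(a: str, b: str, variant: str = "osa") -> int:
    if variant == "osa":
        return osa_distance(a, b)
    if variant == "levenshtein":
        return levenshtein_distance(a, b)
    raise ValueError(f"unknown edit-distance variant: {variant!r}")


def bounded_edit_distance(a: str, b: str, max_dist: int, variant: str = "osa") -> int:
    """Edit distance capped at ``max_dist``; returns ``max_dist + 1`` beyond.

    Ukkonen-banded dynamic program: only cells within ``max_dist`` of
    the diagonal can lie on an alignment path of cost <= ``max_dist``,
    so the band has width 2*max_dist + 1 and the row is abandoned early
    once every band cell exceeds the cap.  Agrees with the full DP
    whenever the true distance is within the cap.
    """
    if variant not in ("osa", "levenshtein"):
        raise ValueError(f"unknown edit-distance variant: {variant!r}")
    transpositions = variant == "osa"
    la, lb = len(a), len(b)
    if abs(la - lb) > max_dist:
        return max_dist + 1
    if la == 0 or lb == 0:
        return max(la, lb)
    cap = max_dist + 1
    prev2: list[int] = []
    prev = [j if j <= max_dist else cap for j in range(lb + 1)]
    for i in range(1, la + 1):
        cur = [cap] * (lb + 1)
        if i <= max_dist:
            cur[0] = i
        lo = max(1, i - max_dist)
        hi = min(lb, i + max_dist)
        best = cap
        ai = a[i - 1]
        for j in range(lo, hi + 1):
            cost = 0 if ai == b[j - 1] else 1
            d = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + cost)
            if (
                transpositions
                and i > 1
                and j > 1
                and ai == b[j - 2]
                and a[i - 2] == b[j - 1]
            ):
                d = min(d, prev2[j - 2] + 1)
            if d > cap:
                d = cap
            cur[j] = d
            if d < best:
                best = d
        if best >= cap:
            return cap
        prev2, prev = prev, cur
    return min(prev[lb], cap)


_ALPHABET = "ACGT"


def composition_matrix(sequences: list[str]) -> np.ndarray:
    """Per-sequence base-composition counts, shape (n, 4).

    Used for a cheap edit-distance lower bound: one substitution changes
    two composition counts by one each, an insertion or deletion changes
    one count, and a transposition changes none, so

        dist(a, b) >= ceil( sum_c |n_c(a) - n_c(b)| / 2 )

    holds for both variants.  Candidates failing the bound can be
    skipped without running the dynamic program.
    """
    mat = np.zeros((len(sequences), len(_ALPHABET)), dtype=np.int32)
    for i, seq in enumerate(sequences):
        for k, base in enumerate(_ALPHABET):
            mat[i, k] = seq.count(base)
    return mat


def composition_lower_bounds(query_comp: np.ndarray, comps: np.ndarray) -> np.ndarray:
    """Vector of composition lower bounds between one query and many sequences."""
    diff = np.abs(comps - query_comp[None, :]).sum(axis=1)
    return (diff + 1) // 2
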