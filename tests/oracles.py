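"""Independent reference implementations used only to check the package.

Everything here is deliberately naive (sliding windows, exhaustive
enumeration, closed forms) and shares no code with the implementation paths
it validates.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def naive_motif_scan(sequence: str, pattern_sets: list[frozenset[str]]) -> list[int]:
    """All 1-based start positions where every window position is allowed."""
    m = len(pattern_sets)
    out = []
    for i in range(len(sequence) - m + 1):
        if all(sequence[i + k] in pattern_sets[k] for k in range(m)):
            out.append(i + 1)
    return out


def gotoh_score(
    a: str, b: str, matrix=BLOSUM62, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Affine-gap global score with free terminal gaps (three-state Gotoh).

    A gap run of length L costs open + (L-1)*extend; leading/trailing gap
    runs in either sequence cost nothing.
    """
    n, m = len(a), len(b)
    neg = float("-inf")
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (a-residue unmatched)
    Y = np.full((n + 1, m + 1), neg)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = 0.0  # leading gap in b: free
    for j in range(1, m + 1):
        Y[0, j] = 0.0  # leading gap in a: free
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(
                M[i - 1, j] - gap_open,
                X[i - 1, j] - gap_extend,
                Y[i - 1, j] - gap_open,
            )
            Y[i, j] = max(
                M[i, j - 1] - gap_open,
                Y[i, j - 1] - gap_extend,
                X[i, j - 1] - gap_open,
            )
    # trailing gaps free: best over last row and column
    best = max(M[n, m], X[n, m], Y[n, m])
    for i in range(n + 1):
        best = max(best, M[i, m], X[i, m], Y[i, m])
    for j in range(m + 1):
        best = max(best, M[n, j], X[n, j], Y[n, j])
    return float(best)


def enumerate_alignment_score(
    a: str, b: str, matrix=BLOSUM62, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Best score over every global alignment, by explicit enumeration."""

    best = float("-inf")

    def score(moves: list[str]) -> float:
        total = 0.0
        i = j = 0
        runs: list[tuple[int, int, int]] = []  # (col_start, col_end, kind)
        col = 0
        for mv in moves:
            if mv == "D":
                total += matrix[a[i], b[j]]
                i += 1
                j += 1
            else:
                if runs and runs[-1][1] == col - 1 and runs[-1][2] == (mv == "A"):
                    runs[-1] = (runs[-1][0], col, runs[-1][2])
                else:
                    runs.append((col, col, mv == "A"))
                if mv == "A":
                    i += 1
                else:
                    j += 1
            col += 1
        last = len(moves) - 1
        for start, end, _ in runs:
            if start == 0 or end == last:
                continue  # terminal gap run: free
            total -= gap_open + (end - start) * gap_extend
        return total

    def recurse(i: int, j: int, moves: list[str]) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score(moves))
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, moves + ["D"])
        if i < len(a):
            recurse(i + 1, j, moves + ["A"])
        if j < len(b):
            recurse(i, j + 1, moves + ["B"])

    recurse(0, 0, [])
    return best


def four_leaf_likelihood(
    leaf_states: dict[str, list[int]],
    lengths: dict[str, float],
    pi: np.ndarray,
    transition,
) -> float:
    """Log-likelihood of ((A,B),(C,D)) by summing over all internal states.

    ``lengths`` has keys A, B, C, D (pendant edges) and I (internal edge);
    ``transition(t)`` returns P(t). Sites are independent.
    """
    pa, pb = transition(lengths["A"]), transition(lengths["B"])
    pc, pd = transition(lengths["C"]), transition(lengths["D"])
    pint = transition(lengths["I"])
    nstates = len(pi)
    nsites = len(leaf_states["A"])
    total = 0.0
    for s in range(nsites):
        xa, xb = leaf_states["A"][s], leaf_states["B"][s]
        xc, xd = leaf_states["C"][s], leaf_states["D"][s]
        lik = 0.0
        for u in range(nstates):
            for v in range(nstates):
                lik += (
                    pi[u]
                    * pa[u, xa]
                    * pb[u, xb]
                    * pint[u, v]
                    * pc[v, xc]
                    * pd[v, xd]
                )
        total += np.log(lik)
    return float(total)
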