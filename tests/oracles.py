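"""Independent oracles used by the test suite.

``gotoh_global`` / ``gotoh_local`` are transparent three-state affine-gap
DPs written without reference to the package's alignment code (which goes
through Biopython). ``enumerate_global`` exhaustively recurses over every
alignment of two tiny sequences and is used to validate the Gotoh oracle
itself.

Scoring convention matches the package: a gap of length L costs
``gap_open + L * gap_extend`` (penalties are negative numbers).
"""

from __future__ import annotations

NEG = float("-inf")


def gotoh_global(a: str, b: str, match=1.0, mismatch=-1.0, gap_open=-2.0,
                 gap_extend=-1.0) -> float:
    n, m = len(a), len(b)
    open_cost = gap_open + gap_extend  # cost of the first gap base
    M = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in aligned pair
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in gap in b (a base)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # ends in gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + i * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + open_cost, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + open_cost)
            Y[i][j] = max(M[i][j - 1] + open_cost, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + open_cost)
    return max(M[n][m], X[n][m], Y[n][m])


def gotoh_local(a: str, b: str, match=1.0, mismatch=-1.0, gap_open=-2.0,
                gap_extend=-1.0) -> float:
    n, m = len(a), len(b)
    open_cost = gap_open + gap_extend
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(0.0, M[i - 1][j - 1] + s, X[i - 1][j - 1] + s,
                          Y[i - 1][j - 1] + s)
            X[i][j] = max(M[i - 1][j] + open_cost, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + open_cost, Y[i][j - 1] + gap_extend)
            best = max(best, M[i][j])
    return best


def enumerate_global(a: str, b: str, match=1.0, mismatch=-1.0, gap_open=-2.0,
                     gap_extend=-1.0) -> float:
    """Exhaustive recursion over all global alignments (tiny inputs only).

    State tracks whether the previous column was a gap in the same sequence
    so that gap opens and extends are charged correctly.
    """

    def rec(i: int, j: int, state: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + rec(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if state == "X" else gap_open + gap_extend
            options.append(cost + rec(i + 1, j, "X"))
        if j < len(b):
            cost = gap_extend if state == "Y" else gap_open + gap_extend
            options.append(cost + rec(i, j + 1, "Y"))
        return max(options)

    return rec(0, 0, "M")
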