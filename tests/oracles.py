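"""Independent brute-force reference implementations used only for testing.

These deliberately share no code with the package: the affine-gap aligner is a
plain three-matrix dynamic program with no optimizations, and the edit
distance is the textbook quadratic Levenshtein recurrence in pure Python.
"""

from __future__ import annotations

NEG_INF = float("-inf")


def affine_global_score(a: str, b: str, score, gap_open: float, gap_extend: float) -> float:
    """Optimal global alignment score with affine gaps.

    ``score(x, y)`` gives the substitution score; a length-L gap costs
    ``gap_open + (L - 1) * gap_extend``. Plain O(n*m*3) DP.
    """
    n, m = len(a), len(b)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # ends in substitution
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # ends in gap in b
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # ends in gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + (i - 1) * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + (j - 1) * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(a[i - 1], b[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] - gap_open,
                          X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open,
                          Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def levenshtein(a: list[str] | str, b: list[str] | str) -> int:
    """Textbook Levenshtein distance over arbitrary symbol sequences."""
    prev = list(range(len(b) + 1))
    for i, x in enumerate(a, 1):
        cur = [i]
        for j, y in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (x != y)))
        prev = cur
    return prev[len(b)]
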