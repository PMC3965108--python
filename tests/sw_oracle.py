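"""Independent exhaustive Smith-Waterman (Gotoh) oracle for tests.

Pure-Python affine-gap local alignment DP, written separately from the
package's search backend so the two can be compared on small sequences.
Scoring: BLOSUM62, 12 for the first position of a gap, 1 per additional
position (matching the backend's declared scheme).
"""

from Bio.Align import substitution_matrices

_M = substitution_matrices.load("BLOSUM62")
GAP_FIRST = 12
GAP_EXT = 1


def _score(a: str, b: str) -> float:
    return _M[a, b]


def sw_best_score(q: str, t: str):
    """Return (best score, set of (i, j) 1-based end cells attaining it)."""
    n, m = len(q), len(t)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (move in t)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in target (move in q)
    best, ends = 0.0, set()
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - GAP_FIRST, E[i][j - 1] - GAP_EXT)
            F[i][j] = max(H[i - 1][j] - GAP_FIRST, F[i - 1][j] - GAP_EXT)
            diag = H[i - 1][j - 1] + _score(q[i - 1], t[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best, ends = H[i][j], {(i, j)}
            elif H[i][j] == best and best > 0:
                ends.add((i, j))
    return best, ends
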