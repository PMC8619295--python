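"""Independent brute-force oracles used by the test suite.

These deliberately re-derive quantities by a different route than the
package (plain-Python dynamic programming with exhaustive traceback
enumeration, grid scans, naive loops) so agreement is evidence, not
tautology.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = 10.0
GAP_EXTEND = 1.0
NEG_INF = float("-inf")


def _sub(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


def max_identity_over_optimal_alignments(a: str, b: str) -> float:
    """Gotoh DP + exhaustive enumeration of all optimal tracebacks.

    Scoring mirrors the package convention: BLOSUM62, a gap of length L
    costs GAP_OPEN + GAP_EXTEND * L, end gaps penalized.  Returns the
    maximum percent identity (identical columns / columns excluding
    terminal gaps, X never a match) over every optimal alignment.
    Intended for short sequences only.
    """
    n, m = len(a), len(b)
    first = GAP_OPEN + GAP_EXTEND  # cost of opening a gap of length 1
    ext = GAP_EXTEND
    # M = align ending in substitution; X = gap in b (consumes a); Y = gap in a
    M = np.full((n + 1, m + 1), NEG_INF)
    X = np.full((n + 1, m + 1), NEG_INF)
    Y = np.full((n + 1, m + 1), NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(GAP_OPEN + ext * i)
    for j in range(1, m + 1):
        Y[0, j] = -(GAP_OPEN + ext * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _sub(a[i - 1], b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - first, X[i - 1, j] - ext, Y[i - 1, j] - first)
            Y[i, j] = max(M[i, j - 1] - first, Y[i, j - 1] - ext, X[i, j - 1] - first)
    best = max(M[n, m], X[n, m], Y[n, m])

    tol = 1e-9
    results: list[float] = []

    def identity_of(cols: list[tuple[str, str]]) -> float:
        lo = 0
        while lo < len(cols) and "-" in cols[lo]:
            lo += 1
        hi = len(cols)
        while hi > lo and "-" in cols[hi - 1]:
            hi -= 1
        region = cols[lo:hi]
        if not region:
            return 0.0
        matches = sum(1 for x, y in region if x == y and x != "-" and x != "X")
        return 100.0 * matches / len(region)

    def walk(i: int, j: int, state: str, suffix: list[tuple[str, str]]) -> None:
        # Only M[0,0] is finite at the origin, so every complete path
        # arrives here (predecessor checks against -inf always fail).
        if i == 0 and j == 0:
            results.append(identity_of(suffix[::-1]))
            return
        if state == "M":
            if i == 0 or j == 0:
                return
            s = _sub(a[i - 1], b[j - 1])
            target = M[i, j] - s
            col = (a[i - 1], b[j - 1])
            for prev, table in (("M", M), ("X", X), ("Y", Y)):
                if abs(table[i - 1, j - 1] - target) < tol:
                    walk(i - 1, j - 1, prev, suffix + [col])
        elif state == "X":
            col = (a[i - 1], "-")
            if abs(X[i, j] - (M[i - 1, j] - first)) < tol:
                walk(i - 1, j, "M", suffix + [col])
            if abs(X[i, j] - (X[i - 1, j] - ext)) < tol:
                walk(i - 1, j, "X", suffix + [col])
            if abs(X[i, j] - (Y[i - 1, j] - first)) < tol:
                walk(i - 1, j, "Y", suffix + [col])
        else:
            col = ("-", b[j - 1])
            if abs(Y[i, j] - (M[i, j - 1] - first)) < tol:
                walk(i, j - 1, "M", suffix + [col])
            if abs(Y[i, j] - (Y[i, j - 1] - ext)) < tol:
                walk(i, j - 1, "Y", suffix + [col])
            if abs(Y[i, j] - (X[i, j - 1] - first)) < tol:
                walk(i, j - 1, "X", suffix + [col])

    for state, table in (("M", M), ("X", X), ("Y", Y)):
        if abs(table[n, m] - best) < tol:
            walk(n, m, state, [])
    return max(results) if results else 0.0


def grid_scan_pi(charge_fn, step: float = 1e-4) -> float:
    """pH grid scan minimizing |net charge| — independent pI oracle."""
    phs = np.arange(0.0, 14.0 + step, step)
    charges = np.array([abs(charge_fn(ph)) for ph in phs])
    return float(phs[int(np.argmin(charges))])


def genorm_m_bruteforce(logq: dict[str, list[float]]) -> dict[str, float]:
    """Naive geNorm M: plain loops over pairwise log-ratio SDs."""
    refs = list(logq)
    out = {}
    for j in refs:
        sds = []
        for k in refs:
            if k == j:
                continue
            ratios = [x - y for x, y in zip(logq[j], logq[k])]
            mean = sum(ratios) / len(ratios)
            var = sum((r - mean) ** 2 for r in ratios) / (len(ratios) - 1)
            sds.append(var**0.5)
        out[j] = sum(sds) / len(sds)
    return out
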