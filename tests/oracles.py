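"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (full dynamic programming, exhaustive
enumeration) and shares no code with the package internals it checks.
"""

from __future__ import annotations

import itertools
from math import comb

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def nw_identity_ref(a: str, b: str) -> tuple[int, int, int]:
    """Full Needleman-Wunsch (match +1, mismatch -1, gap -2), returning
    (score, matches, columns) of the tie-broken optimal path.

    Tie preference at every cell: diagonal, then gap in ``a``, then gap in
    ``b`` — the package's stated convention.
    """
    ca = [_CODE[c] for c in a]
    cb = [_CODE[c] for c in b]
    n, m = len(ca), len(cb)
    S = [[0] * (m + 1) for _ in range(n + 1)]
    M = [[0] * (m + 1) for _ in range(n + 1)]
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for j in range(1, m + 1):
        S[0][j] = -2 * j
    for i in range(1, n + 1):
        S[i][0] = -2 * i
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            ismatch = ca[i - 1] == cb[j - 1] and ca[i - 1] != 4
            best = S[i - 1][j - 1] + (1 if ismatch else -1)
            bm, bd = M[i - 1][j - 1] + ismatch, D[i - 1][j - 1] + 1
            if S[i][j - 1] - 2 > best:
                best, bm, bd = S[i][j - 1] - 2, M[i][j - 1], D[i][j - 1]
            if S[i - 1][j] - 2 > best:
                best, bm, bd = S[i - 1][j] - 2, M[i - 1][j], D[i - 1][j]
            S[i][j], M[i][j], D[i][j] = best, bm, bd
    return S[n][m], M[n][m], n + m - D[n][m]


def identity_ref(a: str, b: str) -> float:
    _, matches, cols = nw_identity_ref(a, b)
    return matches / cols


def naive_greedy(seqs: list[str], threshold: float, cache: dict | None = None) -> list[list[int]]:
    """Reference greedy clustering: first-acceptable-seed rule over the
    naive full-DP identity.  Returns clusters as lists of read indices."""
    if cache is None:
        cache = {}
    clusters: list[list[int]] = []
    seeds: list[int] = []
    for i, s in enumerate(seqs):
        for c, j in enumerate(seeds):
            # identity of the incoming sequence TO the seed (member first:
            # on score ties the gap-in-first-argument preference applies)
            key = (s, seqs[j])
            if key not in cache:
                cache[key] = identity_ref(s, seqs[j])
            if cache[key] >= threshold:
                clusters[c].append(i)
                break
        else:
            seeds.append(i)
            clusters.append([i])
    return clusters


def midranks(values: list[float]) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        r = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


def mwu_exact_ref(x: list[float], y: list[float], sides: str = "two") -> tuple[float, float]:
    """Exact Mann-Whitney U by brute-force enumeration of all labelings."""
    nx, ny = len(x), len(y)
    pooled = list(x) + list(y)
    ranks = midranks(pooled)
    rx = sum(ranks[:nx])
    ux = rx - nx * (nx + 1) / 2
    sums = [sum(ranks[i] for i in combo) for combo in itertools.combinations(range(nx + ny), nx)]
    total = comb(nx + ny, nx)
    eps = 1e-9
    le = sum(s <= rx + eps for s in sums) / total
    ge = sum(s >= rx - eps for s in sums) / total
    if sides == "greater":
        return ux, ge
    return ux, min(1.0, 2 * min(le, ge))
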