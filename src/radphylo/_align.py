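"""Global-alignment kernels shared by the clustering and assembly stages.

Scoring is fixed across the package: match +1, mismatch -1, gap -2, no free
end gaps.  Identity of a pair is the fraction of identical-residue columns in
the score-optimal global alignment, with score ties broken by preferring a
match/mismatch column, then a gap in the first sequence, then a gap in the
second.  N is treated as matching nothing (always a mismatch).

Two accelerations are used for equal-length sequences; both are exact, not
heuristic (see docs/methods.md for the arguments):

* if the ungapped (Hamming) identity already reaches the threshold, so does
  the DP identity, because under this scoring a gapped alignment can only
  beat the ungapped score by also raising identity;
* the optimal alignment never drifts more than ``2*(L - M0)/5`` cells off the
  main diagonal (M0 = ungapped match count), because an alignment with g gap
  columns scores at most ``L - 5g/2`` which must beat the ungapped score
  ``2*M0 - L``; a banded DP with that half-width plus one is therefore exact.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP = -2

_NEG = -(10**7)

# A=0 C=1 G=2 T=3 N=4; anything else also maps to N
_LUT = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _LUT[ord(_c)] = _i
    _LUT[ord(_c.lower())] = _i


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (N and unknowns -> 4)."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_matrix(seqs: list[str]) -> np.ndarray:
    """Encode equal-length sequences as an (n, L) uint8 matrix."""
    n = len(seqs)
    L = len(seqs[0])
    out = np.empty((n, L), dtype=np.uint8)
    for i, s in enumerate(seqs):
        if len(s) != L:
            raise ValueError("sequences must be equal-length for encode_matrix")
        out[i] = encode(s)
    return out


@njit(cache=True)
def _nw_identity_banded(a, b, band):  # pragma: no cover - numba
    """(score, matches, columns) of the tie-broken optimal global alignment.

    ``band`` is the half-width around the main diagonal; with
    ``band >= max(len(a), len(b))`` this is a full DP.  The hot loop fills a
    score-only matrix in diagonal-offset storage (cell (i, j) lives at
    column j - i + band, so the diagonal predecessor keeps its offset); the
    tie-broken path's match and column counts are recovered afterwards by an
    O(n + m) traceback over the stored scores.  Off-band cells hold a large
    negative sentinel, which can never beat a real path, so the inner loop
    needs no validity branches.
    """
    n = a.shape[0]
    m = b.shape[0]
    mx = n if n > m else m
    if band > mx:
        band = mx
    w = 2 * band + 3  # offsets -band..band at +1, plus sentinel edges
    S = np.full((n + 1) * w, _NEG, np.int64)
    # row i, sequence-b position j -> flat index i*w + (j - i + band + 1)
    for j in range(min(m, band) + 1):  # row 0: leading gaps in a
        S[j + band + 1] = GAP * j
    for i in range(1, n + 1):
        base = i * w
        pbase = base - w
        lo = i - band
        if lo < 0:
            lo = 0
        hi = i + band
        if hi > m:
            hi = m
        if lo == 0:
            S[base + band + 1 - i] = GAP * i  # leading gaps in b
            lo = 1
        ai = a[i - 1]
        off = band + 1 - i
        for j in range(lo, hi + 1):
            k = base + off + j
            pk = pbase + off + j  # same offset in the previous row
            sub = MATCH if (ai == b[j - 1] and ai != 4) else MISMATCH
            best = S[pk] + sub  # diagonal
            s_left = S[k - 1] + GAP  # gap in a: (i, j-1)
            if s_left > best:
                best = s_left
            s_up = S[pk + 1] + GAP  # gap in b: (i-1, j)
            if s_up > best:
                best = s_up
            S[k] = best
    score = S[n * w + (m - n + band + 1)]

    # traceback with the preference diag > gap-in-a > gap-in-b
    i = n
    j = m
    matches = 0
    diag = 0
    while i > 0 and j > 0:
        k = i * w + (j - i + band + 1)
        cur = S[k]
        ismatch = a[i - 1] == b[j - 1] and a[i - 1] != 4
        sub = MATCH if ismatch else MISMATCH
        if S[k - w] + sub == cur:  # diagonal predecessor (same offset)
            diag += 1
            if ismatch:
                matches += 1
            i -= 1
            j -= 1
        elif S[k - 1] + GAP == cur:  # gap in a
            j -= 1
        else:  # gap in b
            i -= 1
    cols = n + m - diag
    return score, matches, cols


@njit(cache=True)
def _hamming_matches(a, b):  # pragma: no cover - numba
    n = a.shape[0]
    c = 0
    for k in range(n):
        if a[k] == b[k] and a[k] != 4:
            c += 1
    return c


@njit(cache=True)
def _identity_codes(a, b):  # pragma: no cover - numba
    """Identity fraction for two encoded sequences (exact, banded if possible)."""
    n = a.shape[0]
    m = b.shape[0]
    if n == m:
        m0 = _hamming_matches(a, b)
        band = (2 * (n - m0)) // 5 + 1
    else:
        band = n + m  # full DP
    _, matches, cols = _nw_identity_banded(a, b, band)
    return matches / cols


def identity(a: str | np.ndarray, b: str | np.ndarray) -> float:
    """Pairwise identity of two sequences under the package scoring."""
    ea = encode(a) if isinstance(a, str) else a
    eb = encode(b) if isinstance(b, str) else b
    return float(_identity_codes(ea, eb))


@njit(cache=True)
def greedy_assign(reads, T):  # pragma: no cover - numba
    """Greedy first-acceptable-seed clustering over an (n, L) code matrix.

    Reads are processed in row order; each is compared to existing seeds in
    seed-creation order and joins the first with identity >= T, else becomes
    a new seed.  Returns (cluster index per read, seed read-index per cluster).

    Exact accelerations (see module docstring): ungapped identity >= T
    accepts without DP, and the DP band is clipped to the largest diagonal
    drift an alignment of identity >= T can have — any alignment with g gap
    columns scores at most L - 5g/2, while identity >= T forces score >=
    L(6T-4)/(1+T); lower-scoring alignments cannot reach identity T, so
    clipped-away paths are rejections either way.
    """
    n, L = reads.shape
    assign = np.empty(n, np.int64)
    seed_idx = np.empty(n, np.int64)
    n_seeds = 0
    # diagonal drift limit for alignments that could still reach identity T
    s_req = L * (6.0 * T - 4.0) / (1.0 + T)
    d_t = int((L - s_req) // 5.0)
    if d_t < 1:
        d_t = 1
    for i in range(n):
        placed = False
        for s in range(n_seeds):
            j = seed_idx[s]
            m0 = _hamming_matches(reads[i], reads[j])
            if m0 / L >= T:
                assign[i] = s
                placed = True
                break
            band = (2 * (L - m0)) // 5 + 1
            if band > d_t:
                band = d_t
            _, matches, cols = _nw_identity_banded(reads[i], reads[j], band)
            if matches / cols >= T:
                assign[i] = s
                placed = True
                break
        if not placed:
            assign[i] = n_seeds
            seed_idx[n_seeds] = i
            n_seeds += 1
    return assign, seed_idx[:n_seeds]


@njit(cache=True)
def _nw_pointers(a, b):  # pragma: no cover - numba
    """Full DP returning the pointer matrix (0 diag, 1 gap-in-a, 2 gap-in-b)."""
    n = a.shape[0]
    m = b.shape[0]
    score = np.empty((n + 1, m + 1), np.int64)
    ptr = np.zeros((n + 1, m + 1), np.uint8)
    score[0, 0] = 0
    for j in range(1, m + 1):
        score[0, j] = GAP * j
        ptr[0, j] = 1
    for i in range(1, n + 1):
        score[i, 0] = GAP * i
        ptr[i, 0] = 2
        for j in range(1, m + 1):
            ismatch = a[i - 1] == b[j - 1] and a[i - 1] != 4
            best = score[i - 1, j - 1] + (MATCH if ismatch else MISMATCH)
            p = 0
            if score[i, j - 1] + GAP > best:
                best = score[i, j - 1] + GAP
                p = 1
            if score[i - 1, j] + GAP > best:
                best = score[i - 1, j] + GAP
                p = 2
            score[i, j] = best
            ptr[i, j] = p
    return ptr


def align_pair(a: str, b: str) -> tuple[str, str]:
    """Globally align two sequences; returns the two gapped strings."""
    ea, eb = encode(a), encode(b)
    ptr = _nw_pointers(ea, eb)
    i, j = len(a), len(b)
    out_a: list[str] = []
    out_b: list[str] = []
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif p == 1:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
        else:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))
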