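"""Score-based global alignment with affine gaps (Gotoh).

Used where per-column correctness matters (the mismatch track): an
edit-distance path can explain a cluster of substitutions with a cheaper
compensating insertion/deletion pair, which would fabricate indels in the
reported SNP pattern.  Scoring here (match +2, mismatch -3, gap open -5,
gap extend -2) makes two substitutions cheaper than any gap pair, so
gap-free histories realign gap-free.

The row recurrences are numpy-vectorized; the within-row horizontal-gap
dependence is solved as a prefix-maximum scan.
"""

from __future__ import annotations

import numpy as np

NEG = -1.0e18


def global_affine(a: str, b: str, match: int = 2, mismatch: int = -3,
                  gap_open: int = -5, gap_extend: int = -2):
    """Align a (query) against b (target) globally.

    Returns (score, cigar) with an extended CIGAR over {=, X, I, D}:
    I consumes only the query, D only the target (edlib convention).
    """
    if not a or not b:
        raise ValueError("both sequences must be nonempty")
    ac = np.frombuffer(a.upper().encode(), dtype=np.uint8)
    bc = np.frombuffer(b.upper().encode(), dtype=np.uint8)
    n, m = len(ac), len(bc)
    go_ge = gap_open + gap_extend
    cols = np.arange(m + 1, dtype=np.float64)

    ptrM = np.zeros((n + 1, m + 1), dtype=np.uint8)   # 0=M 1=X 2=Y at i-1,j-1
    ptrX = np.zeros((n + 1, m + 1), dtype=np.uint8)   # 0=M 1=Y 2=X at i-1,j
    ptrY = np.zeros((n + 1, m + 1), dtype=np.uint8)   # 0=M 1=X 2=Y at i,j-1

    M = np.full(m + 1, NEG)
    X = np.full(m + 1, NEG)
    Y = np.full(m + 1, NEG)
    M[0] = 0.0
    Y[1:] = gap_open + gap_extend * cols[1:]
    ptrY[0, 1:] = 2
    ptrY[0, 1] = 0

    for i in range(1, n + 1):
        s_row = np.where(bc == ac[i - 1], float(match), float(mismatch))
        prevM, prevX, prevY = M, X, Y
        # vertical gap (consumes query base i)
        open_v = np.maximum(prevM, prevY) + go_ge
        ext_v = prevX + gap_extend
        newX = np.maximum(open_v, ext_v)
        ptrX[i] = np.where(ext_v >= open_v, 2,
                           np.where(prevM >= prevY, 0, 1))
        # match/mismatch
        stacked = np.vstack([prevM[:-1], prevX[:-1], prevY[:-1]])
        choice = np.argmax(stacked, axis=0)
        newM = np.full(m + 1, NEG)
        newM[1:] = stacked[choice, np.arange(m)] + s_row
        ptrM[i, 1:] = choice
        # horizontal gap (consumes target base j): prefix-max scan
        opener = np.maximum(newM, newX)
        ptr_open = np.where(newM >= newX, 0, 1)
        adj = opener + gap_open - gap_extend * cols
        run = np.maximum.accumulate(adj[:-1])
        newY = np.full(m + 1, NEG)
        newY[1:] = run + gap_extend * cols[1:]
        ext_h = np.empty(m + 1)
        ext_h[0] = NEG
        ext_h[1:] = adj[:-1] + gap_extend * cols[1:]      # open at j-1 exactly
        ptrY[i, 1:] = np.where(np.isclose(newY[1:], ext_h[1:]),
                               ptr_open[:-1], 2)
        M, X, Y = newM, newX, newY

    finals = (M[m], X[m], Y[m])
    state = int(np.argmax(finals))
    score = float(finals[state])

    ops: list[str] = []
    i, j = n, m
    names = "MXY"
    st = names[state]
    while i > 0 or j > 0:
        if st == "M":
            ops.append("=" if ac[i - 1] == bc[j - 1] else "X")
            st = names[ptrM[i, j]]
            i, j = i - 1, j - 1
        elif st == "X":
            ops.append("I")
            nxt = ptrX[i, j]
            st = "M" if nxt == 0 else ("Y" if nxt == 1 else "X")
            i -= 1
        else:
            ops.append("D")
            nxt = ptrY[i, j]
            st = "M" if nxt == 0 else ("X" if nxt == 1 else "Y")
            j -= 1
    ops.reverse()
    # run-length encode
    cigar = []
    k = 0
    while k < len(ops):
        r = k
        while r < len(ops) and ops[r] == ops[k]:
            r += 1
        cigar.append(f"{r - k}{ops[k]}")
        k = r
    return score, "".join(cigar)
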