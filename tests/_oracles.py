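"""Independent reference implementations used only by the test suite.

These are deliberately naive: a pure-Python three-state affine-gap DP with
explicit alignment-string traceback, an exhaustive alignment enumerator for
tiny sequences, and a sort-based median/MAD.  They share the package's
conventions (gap of length g costs open + g*extend; traceback ties resolved
diagonal > vertical > horizontal; X never matches) but none of its code.
"""

from __future__ import annotations

from synologs.alphabet import ALPHABET, load_matrix

_BLOSUM = load_matrix("BLOSUM62")
_IDX = {aa: i for i, aa in enumerate(ALPHABET)}

NEG = float("-inf")


def _score(a: str, b: str) -> int:
    return int(_BLOSUM[_IDX[a], _IDX[b]])


def gotoh_global(a, b, gap_open=11, gap_extend=1):
    """Optimal global affine-gap alignment.

    Returns (score, n_matches, n_res_cols, n_cols).
    """
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) \
                + _score(a[i - 1], b[j - 1])
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend)
    score = max(M[n][m], X[n][m], Y[n][m])
    # traceback with priority M > X > Y
    i, j = n, m
    if M[i][j] == score:
        state = "M"
    elif X[i][j] == score:
        state = "X"
    else:
        state = "Y"
    n_matches = n_res = n_cols = 0
    while i > 0 or j > 0:
        n_cols += 1
        if state == "M":
            n_res += 1
            if a[i - 1] == b[j - 1] and a[i - 1] != "X":
                n_matches += 1
            target = M[i][j] - _score(a[i - 1], b[j - 1])
            i, j = i - 1, j - 1
            if M[i][j] == target:
                state = "M"
            elif X[i][j] == target:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            if M[i - 1][j] - gap_open - gap_extend == X[i][j]:
                state = "M"
            else:
                state = "X"
            i -= 1
        else:
            if M[i][j - 1] - gap_open - gap_extend == Y[i][j]:
                state = "M"
            else:
                state = "Y"
            j -= 1
    return int(score), n_matches, n_res, n_cols


def gotoh_local(a, b, gap_open=11, gap_extend=1):
    """Optimal local affine-gap alignment.

    Returns (score, n_matches, n_res_cols, n_cols, aligned_len_a,
    aligned_len_b); zeros when no positive-scoring pair exists.
    """
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0.0, 0, 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i][j] = max(
                0.0,
                max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
                + _score(a[i - 1], b[j - 1]),
            )
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend)
            if M[i][j] > best:
                best, bi, bj = M[i][j], i, j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0
    i, j, state = bi, bj, "M"
    n_matches = n_res = n_cols = 0
    while True:
        if state == "M":
            if i == 0 or j == 0:
                break
            raw = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) \
                + _score(a[i - 1], b[j - 1])
            if M[i][j] == 0 and raw < 0:
                break  # floored cell: the alignment starts here
            n_cols += 1
            n_res += 1
            if a[i - 1] == b[j - 1] and a[i - 1] != "X":
                n_matches += 1
            target = M[i][j] - _score(a[i - 1], b[j - 1])
            i, j = i - 1, j - 1
            if M[i][j] == target:
                state = "M"
            elif X[i][j] == target:
                state = "X"
            else:
                state = "Y"
        elif state == "X":
            n_cols += 1
            if M[i - 1][j] - gap_open - gap_extend == X[i][j]:
                state = "M"
            else:
                state = "X"
            i -= 1
        else:
            n_cols += 1
            if M[i][j - 1] - gap_open - gap_extend == Y[i][j]:
                state = "M"
            else:
                state = "Y"
            j -= 1
    return int(best), n_matches, n_res, n_cols, bi - i, bj - j


def enumerate_global(a, b, gap_open=11, gap_extend=1):
    """Exhaustively enumerate every global alignment of two tiny sequences.

    Returns (best score, set of (n_matches, n_res_cols) over all optimal
    alignments).  Alignments are built column by column; affine gap costs
    are charged per maximal gap run.
    """
    assert len(a) <= 6 and len(b) <= 6, "enumeration oracle is for tiny inputs"
    results = []

    def rec(i, j, cols):
        if i == len(a) and j == len(b):
            results.append(list(cols))
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, cols + [("M", a[i], b[j])])
        if i < len(a):
            rec(i + 1, j, cols + [("X", a[i], "-")])
        if j < len(b):
            rec(i, j + 1, cols + [("Y", "-", b[j])])

    rec(0, 0, [])
    best = None
    stats = set()
    for cols in results:
        score = 0
        prev = None
        for state, ca, cb in cols:
            if state == "M":
                score += _score(ca, cb)
            else:
                score -= gap_extend
                if state != prev:
                    score -= gap_open
            prev = state
        n_matches = sum(
            1 for s, ca, cb in cols if s == "M" and ca == cb and ca != "X"
        )
        n_res = sum(1 for s, _, _ in cols if s == "M")
        if best is None or score > best:
            best = score
            stats = {(n_matches, n_res)}
        elif score == best:
            stats.add((n_matches, n_res))
    return best, stats


def sorted_median_mad(values):
    """Median and unscaled MAD via explicit sorting, no numpy."""
    vals = sorted(values)
    n = len(vals)
    if n == 0:
        raise ValueError("empty")

    def med(xs):
        k = len(xs) // 2
        return xs[k] if len(xs) % 2 else (xs[k - 1] + xs[k]) / 2

    m = med(vals)
    return m, med(sorted(abs(v - m) for v in vals))


def pearson_r2(x, y):
    """Closed-form squared Pearson correlation, no numpy/scipy."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return (sxy * sxy) / (sxx * syy)
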