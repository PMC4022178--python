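"""Pairwise protein alignment and the synolog criterion.

Both aligners are exhaustive affine-gap dynamic programs (Gotoh's three-state
recurrence), jit-compiled with numba.  No heuristics: every requested pair is
aligned optimally.  A gap of length g costs ``gap_open + g * gap_extend``
(the blastp convention; defaults 11/1 give 11 + g).

Identity conventions differ by detection mode and are produced by the
matching aligner:

* :func:`local_align` (de novo mode, blast-style): identity is
  matches / all columns of the local alignment, gap columns included;
  coverage of each sequence is the fraction of its full length inside the
  local alignment.
* :func:`global_align` (family mode, Protdist-similarity style): identity is
  matches / residue-pair columns (columns where both sequences place a
  residue); coverage is 1 by construction.

Traceback ties are broken with the fixed priority diagonal > vertical
(gap in the second sequence) > horizontal, so outputs are bit-reproducible.
``X`` never counts as a match and scores as a worst-case mismatch.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Optional

import numpy as np
from numba import njit

from .alphabet import X_CODE, encode, load_matrix
from .records import DetectionConfig, PairwiseHit

_NEG = -(10**9)

# traceback state codes
_M, _IX, _IY, _STOP = 0, 1, 2, 3


@lru_cache(maxsize=4)
def _matrix(name: str) -> np.ndarray:
    return load_matrix(name)


@njit(cache=True)
def _gotoh_fill(a, b, sub, gap_open, gap_extend, local):  # pragma: no cover - jit
    """Fill the three Gotoh state matrices plus per-state predecessor codes.

    Returns (M, Ix, Iy, pM, pX, pY) where Ix consumes a residue of `a`
    (vertical move) and Iy consumes a residue of `b` (horizontal move).
    """
    n = a.shape[0]
    m = b.shape[0]
    M = np.full((n + 1, m + 1), _NEG, np.int64)
    Ix = np.full((n + 1, m + 1), _NEG, np.int64)
    Iy = np.full((n + 1, m + 1), _NEG, np.int64)
    pM = np.full((n + 1, m + 1), _STOP, np.int8)
    pX = np.full((n + 1, m + 1), _STOP, np.int8)
    pY = np.full((n + 1, m + 1), _STOP, np.int8)

    M[0, 0] = 0
    if not local:
        for i in range(1, n + 1):
            Ix[i, 0] = -(gap_open + i * gap_extend)
            pX[i, 0] = _M if i == 1 else _IX
        for j in range(1, m + 1):
            Iy[0, j] = -(gap_open + j * gap_extend)
            pY[0, j] = _M if j == 1 else _IY
    else:
        for i in range(1, n + 1):
            M[i, 0] = 0
        for j in range(1, m + 1):
            M[0, j] = 0

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            # match/mismatch state: tie priority M > Ix > Iy via strict >
            best = M[i - 1, j - 1]
            p = _M
            if Ix[i - 1, j - 1] > best:
                best = Ix[i - 1, j - 1]
                p = _IX
            if Iy[i - 1, j - 1] > best:
                best = Iy[i - 1, j - 1]
                p = _IY
            s = best + sub[ai, b[j - 1]]
            if local and s < 0:
                s = 0
                p = _STOP
            M[i, j] = s
            pM[i, j] = p

            # vertical gap (consume a[i])
            o = M[i - 1, j] - gap_open - gap_extend
            e = Ix[i - 1, j] - gap_extend
            if o >= e:
                Ix[i, j] = o
                pX[i, j] = _M
            else:
                Ix[i, j] = e
                pX[i, j] = _IX

            # horizontal gap (consume b[j])
            o = M[i, j - 1] - gap_open - gap_extend
            e = Iy[i, j - 1] - gap_extend
            if o >= e:
                Iy[i, j] = o
                pY[i, j] = _M
            else:
                Iy[i, j] = e
                pY[i, j] = _IY
    return M, Ix, Iy, pM, pX, pY


@njit(cache=True)
def _traceback(a, b, M, Ix, Iy, pM, pX, pY, i, j, state, local):  # pragma: no cover
    """Walk pointers from (i, j, state); returns counts and start coords.

    Returns (n_matches, n_res_cols, n_cols, i_start, j_start): 1-based
    inclusive alignment span start in each sequence.
    """
    n_matches = 0
    n_res = 0
    n_cols = 0
    while True:
        if local and state == _M and M[i, j] == 0 and pM[i, j] == _STOP:
            break
        if i == 0 and j == 0:
            break
        if state == _M:
            prev = pM[i, j]
            n_cols += 1
            n_res += 1
            if a[i - 1] == b[j - 1] and a[i - 1] != X_CODE:
                n_matches += 1
            if local and prev == _STOP:
                i -= 1
                j -= 1
                break
            i -= 1
            j -= 1
            state = prev
        elif state == _IX:
            prev = pX[i, j]
            n_cols += 1
            i -= 1
            state = prev
        else:
            prev = pY[i, j]
            n_cols += 1
            j -= 1
            state = prev
    return n_matches, n_res, n_cols, i + 1, j + 1


@njit(cache=True)
def _global_kernel(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jit
    M, Ix, Iy, pM, pX, pY = _gotoh_fill(a, b, sub, gap_open, gap_extend, False)
    n = a.shape[0]
    m = b.shape[0]
    score = M[n, m]
    state = _M
    if Ix[n, m] > score:
        score = Ix[n, m]
        state = _IX
    if Iy[n, m] > score:
        score = Iy[n, m]
        state = _IY
    n_matches, n_res, n_cols, _, _ = _traceback(
        a, b, M, Ix, Iy, pM, pX, pY, n, m, state, False
    )
    return score, n_matches, n_res, n_cols


@njit(cache=True)
def _local_kernel(a, b, sub, gap_open, gap_extend):  # pragma: no cover - jit
    M, Ix, Iy, pM, pX, pY = _gotoh_fill(a, b, sub, gap_open, gap_extend, True)
    n = a.shape[0]
    m = b.shape[0]
    best = 0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i, j] > best:
                best = M[i, j]
                bi = i
                bj = j
    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0, 0
    n_matches, n_res, n_cols, i0, j0 = _traceback(
        a, b, M, Ix, Iy, pM, pX, pY, bi, bj, _M, True
    )
    return best, n_matches, n_res, n_cols, i0, bi, j0, bj


def _check(a: str, b: str) -> None:
    if not a or not b:
        raise ValueError("alignment requires two non-empty sequences")


def global_align(
    a: str,
    b: str,
    matrix: Optional[np.ndarray] = None,
    gap_open: int = 11,
    gap_extend: int = 1,
    gene_a: str = "a",
    gene_b: str = "b",
) -> PairwiseHit:
    """Optimal global (Needleman-Wunsch) alignment of two proteins.

    Identity is matches over residue-pair columns; both coverages are 1
    because a global alignment spans both sequences end to end.
    """
    _check(a, b)
    sub = matrix if matrix is not None else _matrix("BLOSUM62")
    score, n_matches, n_res, n_cols = _global_kernel(
        encode(a), encode(b), sub, gap_open, gap_extend
    )
    identity = n_matches / n_res if n_res else 0.0
    return PairwiseHit(
        gene_a=gene_a,
        gene_b=gene_b,
        identity=identity,
        coverage_a=1.0,
        coverage_b=1.0,
        n_matches=int(n_matches),
        n_columns=int(n_cols),
        aligned_len_a=len(a),
        aligned_len_b=len(b),
        score=float(score),
    )


def local_align(
    a: str,
    b: str,
    matrix: Optional[np.ndarray] = None,
    gap_open: int = 11,
    gap_extend: int = 1,
    gene_a: str = "a",
    gene_b: str = "b",
) -> PairwiseHit:
    """Optimal local (Smith-Waterman) alignment of two proteins.

    Identity is matches over all columns of the local alignment, gap columns
    included (blast-style percent identity); coverage of each sequence is the
    aligned span divided by its full length.  When no positive-scoring pair
    exists the hit has identity 0 and coverage 0.
    """
    _check(a, b)
    sub = matrix if matrix is not None else _matrix("BLOSUM62")
    score, n_matches, n_res, n_cols, i0, i1, j0, j1 = _local_kernel(
        encode(a), encode(b), sub, gap_open, gap_extend
    )
    if n_cols == 0:
        return PairwiseHit(
            gene_a=gene_a, gene_b=gene_b, identity=0.0,
            coverage_a=0.0, coverage_b=0.0, n_matches=0, n_columns=0,
            aligned_len_a=0, aligned_len_b=0, score=0.0,
        )
    len_a = i1 - i0 + 1
    len_b = j1 - j0 + 1
    return PairwiseHit(
        gene_a=gene_a,
        gene_b=gene_b,
        identity=n_matches / n_cols,
        coverage_a=len_a / len(a),
        coverage_b=len_b / len(b),
        n_matches=int(n_matches),
        n_columns=int(n_cols),
        aligned_len_a=int(len_a),
        aligned_len_b=int(len_b),
        score=float(score),
    )


def align_pair(a: str, b: str, config: DetectionConfig, **kw) -> PairwiseHit:
    """Mode-appropriate alignment: local for de novo, global for family."""
    sub = _matrix(config.matrix_name)
    fn = local_align if config.mode == "denovo" else global_align
    return fn(a, b, matrix=sub, gap_open=config.gap_open,
              gap_extend=config.gap_extend, **kw)


def synolog_criterion(
    hit: PairwiseHit,
    config: DetectionConfig,
    family_a: Optional[str] = None,
    family_b: Optional[str] = None,
) -> bool:
    """Decide whether one pair counts as synologs.

    De novo mode: identity >= identity_threshold and both coverages >=
    coverage_threshold.  Family mode: same (non-empty) family label; identity
    is additionally thresholded only when an identity cutoff is configured —
    the family definition itself carries no length or identity requirement.

    Fractions are rounded to 6 decimals before the >= comparison so that
    boundary cases do not flip with platform floating-point noise.
    """
    if config.mode == "family":
        if family_a is None or family_b is None or family_a != family_b:
            return False
        if config.identity_threshold is None:
            return True
        return round(hit.identity, 6) >= config.identity_threshold
    return (
        round(hit.identity, 6) >= config.identity_threshold
        and round(hit.coverage_a, 6) >= config.coverage_threshold
        and round(hit.coverage_b, 6) >= config.coverage_threshold
    )
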