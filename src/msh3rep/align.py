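"""Glocal (semi-global) affine-gap pairwise alignment.

Amplicon reads should map end-to-end: the read is aligned in full while the
reference may be entered and left for free at either end. Local alignment is
deliberately avoided because soft-clipping would hide the repeat-length
evidence that distinguishes alleles of this locus.

The dynamic program is Gotoh's three-state recursion (aligned / gap-in-
reference a.k.a. insertion / gap-in-read a.k.a. deletion) with gap cost
``gap_open + L * gap_extend`` for a gap of length L. Traceback is
deterministic: at co-optimal cells the aligned (diagonal) move is preferred
over an insertion (up), which is preferred over a deletion (left); among
co-optimal end columns the leftmost is taken.

An optional band restricts the explored diagonals to a corridor around the
read/reference length difference, which is exact for substitution-only reads
with at most ``band`` bases of unexpected indel drift and is what makes
bank-wide read classification affordable; ``band=None`` explores the full
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from numba import njit

from .errors import AlignmentError

_NEG = -(1 << 40)


@dataclass(frozen=True)
class Scoring:
    """Integer alignment scores; gap of length L costs gap_open + L*gap_extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -12
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()
#: Effectively forbids gaps: misalignment across repeat lengths is forced to
#: surface as substitutions (how an apparent SNP such as rs557874766 arises).
SUBSTITUTION_FAVORING = Scoring(match=2, mismatch=-3, gap_open=-100_000, gap_extend=-1)
#: Cheap gaps relative to mismatches: the same misalignment surfaces as a
#: unit-multiple deletion instead.
INDEL_FAVORING = Scoring(match=2, mismatch=-6, gap_open=-4, gap_extend=-1)


@dataclass(frozen=True)
class AlignmentResult:
    """One read aligned glocally to one reference.

    ``ops`` is a run-length list over {'M','I','D'} ('M' = aligned pair,
    'I' = read base against a gap, 'D' = reference base skipped inside the
    alignment). ``start``/``end`` are 1-based inclusive reference coordinates
    of the aligned span. Site lists hold 1-based reference positions:
    mismatches and deletions the position itself, insertions the position
    after which the inserted bases sit.
    """

    reference_id: str
    score: int
    ops: tuple[tuple[str, int], ...]
    start: int
    end: int
    query_length: int
    mismatch_sites: tuple[int, ...] = ()
    insertion_sites: tuple[int, ...] = ()
    deletion_sites: tuple[int, ...] = ()

    def __post_init__(self):
        q = sum(n for op, n in self.ops if op in "MI")
        r = sum(n for op, n in self.ops if op in "MD")
        if q != self.query_length:
            raise AlignmentError(f"query-consuming ops sum to {q}, read length {self.query_length}")
        if r != self.end - self.start + 1:
            raise AlignmentError(f"reference-consuming ops sum to {r} != span {self.start}..{self.end}")

    def query_index_at(self, ref_pos: int) -> int | None:
        """0-based read index aligned to 1-based ``ref_pos``; None if outside/deleted."""
        qi, rp = 0, self.start - 1
        for op, n in self.ops:
            if op == "M":
                if rp < ref_pos <= rp + n:
                    return qi + (ref_pos - rp - 1)
                qi += n
                rp += n
            elif op == "I":
                qi += n
            else:  # D
                if rp < ref_pos <= rp + n:
                    return None
                rp += n
        return None

    def cigar(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.ops)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _band_limits(m: int, n: int, band: int | None) -> tuple[int, int]:
    if band is None:
        return -m, n
    d = n - m
    return min(0, d) - band, max(0, d) + band


@njit(cache=True)
def _score_band(q, r, sc_match, sc_mis, go, ge, lo, W):  # pragma: no cover - jitted
    m = q.shape[0]
    n = r.shape[0]
    NEG = _NEG
    Mp = np.full(W, NEG, np.int64)
    Xp = np.full(W, NEG, np.int64)
    Yp = np.full(W, NEG, np.int64)
    Mc = np.empty(W, np.int64)
    Xc = np.empty(W, np.int64)
    Yc = np.empty(W, np.int64)
    for k in range(W):
        j = lo + k
        if 0 <= j <= n:
            Mp[k] = 0
    for i in range(1, m + 1):
        for k in range(W):
            Mc[k] = NEG
            Xc[k] = NEG
            Yc[k] = NEG
            j = i + lo + k
            if j < 0 or j > n:
                continue
            if j == 0:
                Xc[k] = go + ge * i
                continue
            bp = Mp[k]
            if Xp[k] > bp:
                bp = Xp[k]
            if Yp[k] > bp:
                bp = Yp[k]
            if bp > NEG // 2:
                s = sc_match if q[i - 1] == r[j - 1] else sc_mis
                Mc[k] = bp + s
            if k + 1 < W:
                v = Mp[k + 1] + go + ge
                b = Xp[k + 1] + ge
                if b > v:
                    v = b
                b = Yp[k + 1] + go + ge
                if b > v:
                    v = b
                if v > NEG // 2:
                    Xc[k] = v
            if k >= 1:
                v = Mc[k - 1] + go + ge
                b = Yc[k - 1] + ge
                if b > v:
                    v = b
                b = Xc[k - 1] + go + ge
                if b > v:
                    v = b
                if v > NEG // 2:
                    Yc[k] = v
        Mp, Mc = Mc, Mp
        Xp, Xc = Xc, Xp
        Yp, Yc = Yc, Yp
    best = NEG
    for k in range(W):
        j = m + lo + k
        if j < 0 or j > n:
            continue
        if Mp[k] > best:
            best = Mp[k]
        if Xp[k] > best:
            best = Xp[k]
    return best


@njit(cache=True)
def _fill_band(q, r, sc_match, sc_mis, go, ge, lo, W):  # pragma: no cover - jitted
    m = q.shape[0]
    n = r.shape[0]
    NEG = _NEG
    M = np.full((m + 1, W), NEG, np.int64)
    X = np.full((m + 1, W), NEG, np.int64)
    Y = np.full((m + 1, W), NEG, np.int64)
    for k in range(W):
        j = lo + k
        if 0 <= j <= n:
            M[0, k] = 0
    for i in range(1, m + 1):
        for k in range(W):
            j = i + lo + k
            if j < 0 or j > n:
                continue
            if j == 0:
                X[i, k] = go + ge * i
                continue
            bp = M[i - 1, k]
            if X[i - 1, k] > bp:
                bp = X[i - 1, k]
            if Y[i - 1, k] > bp:
                bp = Y[i - 1, k]
            if bp > NEG // 2:
                s = sc_match if q[i - 1] == r[j - 1] else sc_mis
                M[i, k] = bp + s
            if k + 1 < W:
                v = M[i - 1, k + 1] + go + ge
                b = X[i - 1, k + 1] + ge
                if b > v:
                    v = b
                b = Y[i - 1, k + 1] + go + ge
                if b > v:
                    v = b
                if v > NEG // 2:
                    X[i, k] = v
            if k >= 1:
                v = M[i, k - 1] + go + ge
                b = Y[i, k - 1] + ge
                if b > v:
                    v = b
                b = X[i, k - 1] + go + ge
                if b > v:
                    v = b
                if v > NEG // 2:
                    Y[i, k] = v
    return M, X, Y


@njit(cache=True)
def _traceback(M, X, Y, q, r, sc_match, sc_mis, go, ge, lo, i, j, state):  # pragma: no cover
    ops = np.empty(q.shape[0] + r.shape[0] + 2, np.int8)
    p = 0
    while i > 0:
        k = j - i - lo
        if state == 0:
            ops[p] = 0
            p += 1
            s = sc_match if q[i - 1] == r[j - 1] else sc_mis
            target = M[i, k] - s
            if M[i - 1, k] == target:
                state = 0
            elif X[i - 1, k] == target:
                state = 1
            else:
                state = 2
            i -= 1
            j -= 1
        elif state == 1:
            ops[p] = 1
            p += 1
            if j == 0:
                i -= 1
                continue
            k1 = k + 1
            if M[i - 1, k1] + go + ge == X[i, k]:
                state = 0
            elif X[i - 1, k1] + ge == X[i, k]:
                state = 1
            else:
                state = 2
            i -= 1
        else:
            ops[p] = 2
            p += 1
            k1 = k - 1
            if M[i, k1] + go + ge == Y[i, k]:
                state = 0
            elif Y[i, k1] + ge == Y[i, k]:
                state = 2
            else:
                state = 1
            j -= 1
    return ops[:p][::-1].copy(), j


def alignment_score(
    read: str, reference: str, scoring: Scoring = DEFAULT_SCORING, band: int | None = None
) -> int:
    """Optimal glocal alignment score only (no traceback)."""
    if not read:
        raise AlignmentError("empty read")
    if not reference:
        raise AlignmentError("empty reference")
    q, r = _encode(read), _encode(reference)
    lo, hi = _band_limits(len(q), len(r), band)
    return int(
        _score_band(
            q, r, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
            lo, hi - lo + 1,
        )
    )


def align_to_reference(
    read: str,
    reference: str,
    scoring: Scoring = DEFAULT_SCORING,
    reference_id: str = "ref",
    band: int | None = None,
) -> AlignmentResult:
    """Optimal glocal alignment of ``read`` against ``reference`` with traceback."""
    if not read:
        raise AlignmentError("empty read")
    if not reference:
        raise AlignmentError("empty reference")
    q, r = _encode(read), _encode(reference)
    m, n = len(q), len(r)
    lo, hi = _band_limits(m, n, band)
    W = hi - lo + 1
    M, X, Y = _fill_band(
        q, r, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend, lo, W
    )
    best, bj, bstate = _NEG, -1, 0
    for k in range(W):
        j = m + lo + k
        if j < 0 or j > n:
            continue
        if M[m, k] > best:
            best, bj, bstate = int(M[m, k]), j, 0
        if X[m, k] > best:
            best, bj, bstate = int(X[m, k]), j, 1
    ops_arr, start0 = _traceback(
        M, X, Y, q, r, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend,
        lo, m, bj, bstate,
    )
    return _build_result(read, reference, reference_id, best, ops_arr, int(start0))


def _build_result(
    read: str, reference: str, reference_id: str, score: int, ops_arr: np.ndarray, start0: int
) -> AlignmentResult:
    runs: list[tuple[str, int]] = []
    mismatches: list[int] = []
    insertions: list[int] = []
    deletions: list[int] = []
    sym = "MID"
    qi, rp = 0, start0  # rp = 0-based count of reference consumed so far
    for code in ops_arr:
        op = sym[code]
        if runs and runs[-1][0] == op:
            runs[-1] = (op, runs[-1][1] + 1)
        else:
            runs.append((op, 1))
        if op == "M":
            if read[qi] != reference[rp]:
                mismatches.append(rp + 1)
            qi += 1
            rp += 1
        elif op == "I":
            insertions.append(rp)
        else:
            deletions.append(rp + 1)
            rp += 1
    return AlignmentResult(
        reference_id=reference_id,
        score=score,
        ops=tuple(runs),
        start=start0 + 1,
        end=rp,
        query_length=len(read),
        mismatch_sites=tuple(mismatches),
        insertion_sites=tuple(insertions),
        deletion_sites=tuple(deletions),
    )


def score_against_bank(
    read: str,
    bank: Sequence[tuple[str, str]],
    scoring: Scoring = DEFAULT_SCORING,
    band: int | None = None,
) -> dict[str, int]:
    """Glocal score of one read against every (id, sequence) reference in a bank."""
    return {rid: alignment_score(read, seq, scoring, band=band) for rid, seq in bank}
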