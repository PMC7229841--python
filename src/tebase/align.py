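"""Pairwise alignment of amplicon reads to their reference.

Implements Gotoh's affine-gap dynamic programme in two modes:

* ``mode="global"`` — classical Needleman–Wunsch over both full
  sequences, used by the test-suite oracle comparisons;
* ``mode="fit"`` — the read must be fully aligned but may start and end
  anywhere on the reference (free reference end gaps). This is the right
  model for a 150 nt sequencing read that is an infix of a longer
  amplicon, and is what the read-processing pipeline uses.

Default scoring: match +2, mismatch −4, gap open −10 (cost of the first
gap base), gap extension −1 per additional base. Ties are resolved
deterministically and indels are then left-shifted through homopolymer
runs, matching the common aligner convention so that the same molecule
always yields the same CIGAR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .sequences import encode, revcomp

DEFAULT_SCORING = {
    "match": 2.0,
    "mismatch": -4.0,
    "gap_open": -10.0,
    "gap_extend": -1.0,
}

_NEG = -1e18


@njit(cache=False)
def _gotoh_fill(read, ref, match, mismatch, gap_open, gap_extend, fit):
    n = read.shape[0]
    m = ref.shape[0]
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)  # gap in ref (read insertion, I)
    Y = np.full((n + 1, m + 1), _NEG)  # gap in read (deletion, D)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for j in range(1, m + 1):
        if fit:
            M[0, j] = 0.0
        else:
            Y[0, j] = gap_open + (j - 1) * gap_extend
            pY[0, j] = 2
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        pX[i, 0] = 1
        for j in range(1, m + 1):
            s = match if (read[i - 1] == ref[j - 1] and read[i - 1] != 4) \
                else mismatch
            best = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                p = 2
            M[i, j] = best + s
            pM[i, j] = p

            a = M[i - 1, j] + gap_open
            b = X[i - 1, j] + gap_extend
            c = Y[i - 1, j] + gap_open
            if a >= b and a >= c:
                X[i, j] = a
                pX[i, j] = 0
            elif b >= c:
                X[i, j] = b
                pX[i, j] = 1
            else:
                X[i, j] = c
                pX[i, j] = 2

            a = M[i, j - 1] + gap_open
            b = Y[i, j - 1] + gap_extend
            c = X[i, j - 1] + gap_open
            if a >= b and a >= c:
                Y[i, j] = a
                pY[i, j] = 0
            elif b >= c:
                Y[i, j] = b
                pY[i, j] = 2
            else:
                Y[i, j] = c
                pY[i, j] = 1
    return M, X, Y, pM, pX, pY


@dataclass
class Alignment:
    """One read aligned to the reference (0-based half-open coords)."""

    score: float
    ref_start: int
    cigar: list[tuple[str, int]]
    reverse_complemented: bool = False

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(
            length for op, length in self.cigar if op in "MD"
        )


def _traceback(pM, pX, pY, M, X, Y, n, m, fit):
    if fit:
        # end anywhere on the reference; prefer smaller j, M over X
        end_j, end_state, best = 0, 0, _NEG
        for j in range(m + 1):
            if M[n, j] > best:
                best, end_j, end_state = M[n, j], j, 0
            if X[n, j] > best:
                best, end_j, end_state = X[n, j], j, 1
        score = best
        i, j, state = n, end_j, end_state
    else:
        vals = (M[n, m], X[n, m], Y[n, m])
        state = int(np.argmax(vals))
        score = vals[state]
        i, j = n, m

    ops: list[str] = []
    while i > 0 or (not fit and j > 0):
        if fit and i == 0:
            break
        if state == 0:
            state = pM[i, j]
            ops.append("M")
            i -= 1
            j -= 1
        elif state == 1:
            state = pX[i, j]
            ops.append("I")
            i -= 1
        else:
            state = pY[i, j]
            ops.append("D")
            j -= 1
    ops.reverse()
    cigar: list[tuple[str, int]] = []
    for op in ops:
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + 1)
        else:
            cigar.append((op, 1))
    return score, j, cigar


def _left_shift_indels(read: str, ref: str, ref_start: int,
                       cigar: list[tuple[str, int]]) -> list[tuple[str, int]]:
    """Shift each indel leftward through homopolymer runs (score-neutral)."""
    cigar = [list(c) for c in cigar]
    changed = True
    while changed:
        changed = False
        r = ref_start  # ref cursor
        q = 0          # read cursor
        for idx, (op, length) in enumerate(cigar):
            if op == "M":
                r += length
                q += length
                continue
            prev = cigar[idx - 1] if idx > 0 else None
            shiftable = prev is not None and prev[0] == "M" and prev[1] >= 1
            if op == "D" and shiftable and ref[r - 1] == ref[r + length - 1]:
                nxt_ok = idx + 1 < len(cigar) and cigar[idx + 1][0] == "M"
                # read base formerly matched at ref[r-1] must still match
                if nxt_ok and read[q - 1] == ref[r + length - 1]:
                    prev[1] -= 1
                    cigar[idx + 1][1] += 1
                    if prev[1] == 0:
                        del cigar[idx - 1]
                    changed = True
                    break
            if op == "I" and shiftable and read[q - 1] == read[q + length - 1]:
                nxt_ok = idx + 1 < len(cigar) and cigar[idx + 1][0] == "M"
                if nxt_ok and read[q - 1] == ref[r - 1]:
                    prev[1] -= 1
                    cigar[idx + 1][1] += 1
                    if prev[1] == 0:
                        del cigar[idx - 1]
                    changed = True
                    break
            if op == "D":
                r += length
            else:
                q += length
    return [(op, length) for op, length in cigar]


def align(read: str, ref: str, mode: str = "fit",
          scoring: dict | None = None) -> Alignment:
    """Align *read* to *ref*; see module docstring for modes and scoring."""
    p = dict(DEFAULT_SCORING, **(scoring or {}))
    fit = mode == "fit"
    if mode not in ("fit", "global"):
        raise ValueError(f"unknown alignment mode {mode!r}")
    rc, qc = encode(ref.upper()), encode(read.upper())
    M, X, Y, pM, pX, pY = _gotoh_fill(
        qc, rc, p["match"], p["mismatch"], p["gap_open"], p["gap_extend"], fit
    )
    score, ref_start, cigar = _traceback(
        pM, pX, pY, M, X, Y, len(read), len(ref), fit
    )
    cigar = _left_shift_indels(read.upper(), ref.upper(), ref_start, cigar)
    return Alignment(score=float(score), ref_start=ref_start, cigar=cigar)


def align_score(read: str, ref: str, mode: str = "global",
                scoring: dict | None = None) -> float:
    return align(read, ref, mode=mode, scoring=scoring).score


@dataclass
class AlignedRead:
    """A read placed on the amplicon reference.

    ``aligned_bases`` maps each reference position covered by the read to
    the called base ('-' where the read carries a deletion); inserted
    bases appear only in the CIGAR/indel catalogue.
    """

    read_id: str
    mate: str  # 'fwd' or 'rev'
    cigar: list[tuple[str, int]]
    ref_start: int
    aligned_bases: dict[int, str] = field(default_factory=dict)
    score: float = 0.0
    identity: float = 0.0
    aligned: bool = True

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(
            length for op, length in self.cigar if op in "MD"
        )

    def spans(self, start: int, end: int) -> bool:
        return self.aligned and self.ref_start <= start and self.ref_end >= end

    def indels(self) -> list[tuple[int, int, str]]:
        """(ref_position, size, type) for every I/D in the CIGAR."""
        out = []
        r = self.ref_start
        for op, length in self.cigar:
            if op == "I":
                out.append((r, length, "I"))
            elif op == "D":
                out.append((r, length, "D"))
                r += length
            else:
                r += length
        return out


def _mate_from_id(read_id: str) -> tuple[str, str]:
    if read_id.endswith("/1"):
        return read_id[:-2], "fwd"
    if read_id.endswith("/2"):
        return read_id[:-2], "rev"
    return read_id, "fwd"


def align_read_to_amplicon(
    read_id: str,
    sequence: str,
    reference: str,
    mate: str | None = None,
    scoring: dict | None = None,
    min_identity: float = 0.5,
) -> AlignedRead:
    """Fit-align one read, auto-detecting its sequencing orientation.

    Both the read and its reverse complement are aligned and the better
    score kept, so the caller never needs to know which strand was
    sequenced. Reads below *min_identity* (matched fraction of read
    length) are flagged unaligned and excluded from all denominators.
    """
    sequence = sequence.upper()
    base_id, inferred_mate = _mate_from_id(read_id)
    mate = mate or inferred_mate

    fwd = align(sequence, reference, mode="fit", scoring=scoring)
    rev = align(revcomp(sequence), reference, mode="fit", scoring=scoring)
    if rev.score > fwd.score:
        aln, seq_used = rev, revcomp(sequence)
        aln.reverse_complemented = True
    else:
        aln, seq_used = fwd, sequence

    aligned_bases: dict[int, str] = {}
    matches = 0
    r, q = aln.ref_start, 0
    for op, length in aln.cigar:
        if op == "M":
            for k in range(length):
                base = seq_used[q + k]
                aligned_bases[r + k] = base
                if base == reference[r + k].upper():
                    matches += 1
            r += length
            q += length
        elif op == "D":
            for k in range(length):
                aligned_bases[r + k] = "-"
            r += length
        else:
            q += length
    identity = matches / max(len(sequence), 1)
    return AlignedRead(
        read_id=base_id,
        mate=mate,
        cigar=aln.cigar,
        ref_start=aln.ref_start,
        aligned_bases=aligned_bases,
        score=aln.score,
        identity=identity,
        aligned=identity >= min_identity,
    )
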