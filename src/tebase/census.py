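"""Genome-wide protospacer target-site census.

Counts every position, on both strands of a (multi-record) genome, whose
20-mer is within a Hamming distance budget of a protospacer, and
classifies the adjacent PAM (NGG / NAG / other). For a high-copy
repetitive element this census is the bioinformatic counterpart of a
qPCR copy-number estimate: the per-mismatch × per-PAM table shows how
many genomic loci a single guide can in principle address.

The scan is vectorised with numpy sliding windows; a position containing
N always counts as a mismatch (an unknown base cannot be claimed to
match the guide). Matching is over the protospacer only — the PAM is
classified, and optionally required, but never contributes mismatches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import encode, matches_pattern, revcomp, validate_reference

PAM_CLASSES = ("NGG", "NAG", "other")


@dataclass(frozen=True)
class CensusHit:
    """One genomic match of a protospacer.

    ``pos`` is the leftmost coordinate of the matched 20-mer on the
    forward strand (0-based, half-open interval semantics); for a −
    strand hit the protospacer reads 5'→3' on the reverse strand.
    """

    chrom: str
    pos: int
    strand: str
    mismatches: int
    pam_class: str
    matched_sequence: str


@dataclass
class CensusSummary:
    per_chrom_counts: dict[str, int] = field(default_factory=dict)
    mismatch_pam_table: pd.DataFrame | None = None
    total: int = 0


def _natural_key(chrom: str):
    return [
        int(part) if part.isdigit() else part
        for part in re.split(r"(\d+)", chrom)
    ]


def _pam_class(pam: str) -> str:
    if len(pam) == 3:
        if matches_pattern(pam, "NGG"):
            return "NGG"
        if matches_pattern(pam, "NAG"):
            return "NAG"
    return "other"


def _scan_one_strand(codes: np.ndarray, guide_codes: np.ndarray,
                     max_mismatches: int) -> tuple[np.ndarray, np.ndarray]:
    """Positions and mismatch counts of windows within the budget."""
    k = len(guide_codes)
    if len(codes) < k:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    # N (code 4) in the genome never matches any guide base
    mm = ((windows != guide_codes) | (windows == 4)).sum(axis=1)
    keep = np.flatnonzero(mm <= max_mismatches)
    return keep, mm[keep]


def enumerate_matches(
    genome: dict[str, str],
    protospacer: str,
    max_mismatches: int = 2,
    require_pam: bool = False,
) -> list[CensusHit]:
    """All hits of *protospacer* in *genome* within the mismatch budget.

    *genome* maps chromosome name → forward-strand sequence. Both strands
    are scanned; overlapping and self-similar matches are all reported.
    With ``require_pam=True`` hits whose PAM class is "other" are dropped.
    """
    protospacer = validate_reference(protospacer, "protospacer").upper()
    if len(protospacer) < 10:
        raise ValueError("protospacer must be at least 10 nt")
    if max_mismatches >= len(protospacer) / 2:
        raise ValueError("max_mismatches must be < half the guide length")
    if "N" in protospacer:
        raise ValueError("protospacer may not contain N")

    k = len(protospacer)
    fwd_codes = encode(protospacer)
    rev_codes = encode(revcomp(protospacer))

    hits: list[CensusHit] = []
    for chrom, seq in genome.items():
        seq = validate_reference(seq, chrom)
        codes = encode(seq)
        # + strand: genome window equals protospacer; PAM 3' to the right
        pos, mm = _scan_one_strand(codes, fwd_codes, max_mismatches)
        for p, m in zip(pos.tolist(), mm.tolist()):
            pam = seq[p + k : p + k + 3]
            hits.append(
                CensusHit(chrom, p, "+", m, _pam_class(pam), seq[p : p + k])
            )
        # − strand: genome window equals revcomp(protospacer); the hit
        # strand PAM is the revcomp of the 3 nt to the LEFT of the window
        pos, mm = _scan_one_strand(codes, rev_codes, max_mismatches)
        for p, m in zip(pos.tolist(), mm.tolist()):
            pam = revcomp(seq[max(p - 3, 0) : p]) if p >= 3 else ""
            hits.append(
                CensusHit(
                    chrom, p, "-", m, _pam_class(pam),
                    revcomp(seq[p : p + k]),
                )
            )
    if require_pam:
        hits = [h for h in hits if h.pam_class != "other"]
    hits.sort(key=lambda h: (_natural_key(h.chrom), h.pos, h.strand))
    return hits


def summarize_census(
    hits: list[CensusHit], max_mismatches: int | None = None
) -> CensusSummary:
    """Per-chromosome counts and the mismatch × PAM-class table."""
    n_mm = (
        max_mismatches
        if max_mismatches is not None
        else max((h.mismatches for h in hits), default=0)
    )
    table = pd.DataFrame(
        0,
        index=pd.Index(range(n_mm + 1), name="mismatches"),
        columns=pd.Index(PAM_CLASSES, name="pam_class"),
    )
    per_chrom: dict[str, int] = {}
    for h in hits:
        table.loc[h.mismatches, h.pam_class] += 1
        per_chrom[h.chrom] = per_chrom.get(h.chrom, 0) + 1
    per_chrom = dict(
        sorted(per_chrom.items(), key=lambda kv: _natural_key(kv[0]))
    )
    return CensusSummary(
        per_chrom_counts=per_chrom,
        mismatch_pam_table=table,
        total=len(hits),
    )


def hits_to_bed(hits: list[CensusHit], guide_length: int = 20) -> pd.DataFrame:
    """BED6-style table of hits (0-based half-open)."""
    return pd.DataFrame(
        {
            "chrom": [h.chrom for h in hits],
            "start": [h.pos for h in hits],
            "end": [h.pos + guide_length for h in hits],
            "name": [f"mm{h.mismatches}_{h.pam_class}" for h in hits],
            "score": [h.mismatches for h in hits],
            "strand": [h.strand for h in hits],
        }
    )
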