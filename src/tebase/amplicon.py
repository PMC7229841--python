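"""Editing-outcome quantification from amplicon deep-sequencing reads.

Three read-level assays over a sequenced amplicon carrying one or two
guide target sites:

* **Indel frequency** — fraction of read pairs with at least one
  insertion or deletion overlapping the 30 nt analysis window (the
  protospacer, its PAM, plus 7 nt beyond — for a 20 nt guide), with
  mate-concordance required by default.
* **Deamination report** — per-position base composition over the same
  window for reads fully spanning it, from which the intended-conversion
  frequency (C→T for a cytidine editor, A→G for an adenine editor) and
  the editing purity at each editable position are derived.
* **Dual-guide deletion frequency** — classification of reads into
  wild-type versus cut-to-cut deletion alleles by exact containment of
  two diagnostic k-mers: one from the centre of the inter-guide region
  (present only in unedited molecules) and one spanning the predicted
  deletion junction.

All frequencies use reads (or pairs) that fully span the relevant window
as the denominator; partially overlapping reads are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import AlignedRead, align_read_to_amplicon
from .guides import GuideRNA
from .sequences import revcomp, validate_reference

WINDOW_EXTENSION = 7  # nt beyond the PAM included in the analysis window
CUT_OFFSET = 3        # blunt SpCas9 cut site, nt 5' of the PAM

BASE_COLUMNS = ("A", "C", "G", "T", "other")


@dataclass
class AmpliconDesign:
    """An amplicon reference with guides placed on it.

    The per-guide analysis window runs from the protospacer 5' start
    through the PAM and ``WINDOW_EXTENSION`` nt further (30 nt for a
    20 nt guide); for a − strand guide the window is mirrored on the
    forward strand so that it still extends past the PAM in the guide's
    own 3' direction.
    """

    reference: str
    guides: list[GuideRNA]
    name: str = "amplicon"

    def __post_init__(self) -> None:
        self.reference = validate_reference(self.reference, "amplicon")
        for g in self.guides:
            start, end = self.analysis_window(g)
            if start < 0 or end > len(self.reference):
                raise ValueError(
                    f"analysis window [{start},{end}) of guide {g.name!r} "
                    "falls outside the amplicon"
                )
            if self._extract(g) != g.protospacer:
                raise ValueError(
                    f"guide {g.name!r} protospacer does not match the "
                    "amplicon at its stated placement"
                )

    def _extract(self, g: GuideRNA) -> str:
        n = len(g.protospacer)
        seg = self.reference[g.target_start : g.target_start + n]
        return seg if g.strand == "+" else revcomp(seg)

    def analysis_window(self, guide: GuideRNA) -> tuple[int, int]:
        """Forward-strand half-open window ``[start, end)`` for *guide*."""
        n = len(guide.protospacer)
        length = n + len(guide.pam) + WINDOW_EXTENSION
        if guide.strand == "+":
            return guide.target_start, guide.target_start + length
        end = guide.target_start + n
        return end - length, end

    def cut_site(self, guide: GuideRNA) -> int:
        """Reference coordinate of the blunt cut (between two bases)."""
        n = len(guide.protospacer)
        if guide.strand == "+":
            return guide.target_start + n - CUT_OFFSET
        return guide.target_start + CUT_OFFSET

    def deletion_allele(self) -> str:
        """Predicted cut-to-cut fusion sequence for a two-guide design."""
        if len(self.guides) != 2:
            raise ValueError("deletion allele requires exactly two guides")
        cuts = sorted(self.cut_site(g) for g in self.guides)
        return self.reference[: cuts[0]] + self.reference[cuts[1] :]


def align_reads(
    reads,
    design: AmpliconDesign,
    scoring: dict | None = None,
    min_identity: float = 0.5,
) -> list[AlignedRead]:
    """Fit-align FASTQ records (or (id, seq) pairs) to the amplicon.

    Accepts Biopython ``SeqRecord`` objects or plain ``(read_id, seq)``
    tuples; mates are inferred from ``/1``/``/2`` id suffixes. Reads
    below *min_identity* are flagged unaligned.
    """
    out = []
    for rec in reads:
        if isinstance(rec, tuple):
            read_id, seq = rec
        else:
            read_id, seq = rec.id, str(rec.seq)
        out.append(
            align_read_to_amplicon(
                read_id, seq, design.reference,
                scoring=scoring, min_identity=min_identity,
            )
        )
    return out


@dataclass
class IndelSummary:
    total_read_pairs: int
    indel_read_pairs: int
    frequency: float | None
    indel_catalog: dict[tuple[int, int, str], int] = field(default_factory=dict)


def _indel_overlaps_window(indel: tuple[int, int, str],
                           window: tuple[int, int]) -> bool:
    pos, size, kind = indel
    w0, w1 = window
    if kind == "I":
        # insertion sits between pos-1 and pos; junction touches = overlap
        return w0 <= pos <= w1
    return pos < w1 and pos + size > w0


def indel_frequency(
    alignments: list[AlignedRead],
    design: AmpliconDesign,
    require_both_mates: bool = True,
) -> IndelSummary:
    """Windowed indel frequency over read pairs.

    A pair enters the denominator when at least one aligned mate fully
    spans an analysis window. It is counted as edited when an indel
    overlaps a window in every spanning mate (``require_both_mates=True``,
    the mate-concordance filter) or in any spanning mate (``False``).
    The catalogue records each distinct (position, size, type) event once
    per pair that carries it.
    """
    windows = [design.analysis_window(g) for g in design.guides]
    by_pair: dict[str, list[AlignedRead]] = {}
    for a in alignments:
        if a.aligned:
            by_pair.setdefault(a.read_id, []).append(a)

    total = edited = 0
    catalog: dict[tuple[int, int, str], int] = {}
    for mates in by_pair.values():
        spanning = [
            m for m in mates
            if any(m.spans(w0, w1) for w0, w1 in windows)
        ]
        if not spanning:
            continue
        total += 1
        per_mate_hits = []
        pair_events: set[tuple[int, int, str]] = set()
        for m in spanning:
            hits = [
                ind for ind in m.indels()
                if any(_indel_overlaps_window(ind, w) for w in windows)
            ]
            per_mate_hits.append(bool(hits))
            pair_events.update(hits)
        is_edited = all(per_mate_hits) if require_both_mates \
            else any(per_mate_hits)
        if is_edited:
            edited += 1
            for ev in pair_events:
                catalog[ev] = catalog.get(ev, 0) + 1

    if total == 0:
        warnings.warn(
            "no read pairs span the analysis window; "
            "indel frequency is undefined"
        )
        return IndelSummary(0, 0, None, {})
    return IndelSummary(total, edited, edited / total, catalog)


@dataclass
class WindowReport:
    """Per-position editing report over the 30 nt analysis window.

    Positions and bases are expressed on the protospacer strand (window
    position 1 = protospacer 5' base) regardless of sequencing strand.
    ``per_position_counts`` rows sum to ``coverage``. Frequencies with an
    empty denominator are NaN.
    """

    per_position_counts: pd.DataFrame
    target_positions: list[int]
    conversion_by_position: pd.Series
    purity_by_position: pd.Series
    target_conversion_frequency: float
    max_position_conversion: float
    read_level_purity: float
    coverage: int

    def conversion_at(self, window_position: int) -> float:
        return float(self.conversion_by_position.loc[window_position])


EDITOR_RULES = {"CBE": ("C", "T"), "ABE": ("A", "G")}


def deamination_report(
    alignments: list[AlignedRead],
    design: AmpliconDesign,
    editor: str = "CBE",
    guide: GuideRNA | None = None,
    dedupe_pairs: bool = True,
) -> WindowReport:
    """Base-composition and conversion/purity report over the window.

    Only reads fully spanning the window contribute; with
    ``dedupe_pairs=True`` one mate per read pair is used (the first
    spanning mate) so overlapping mates are not double counted.

    * conversion at an editable position = intended-base reads / coverage
    * purity at an editable position = intended-base reads / all
      non-reference reads there (NaN when nothing is non-reference)
    * headline ``target_conversion_frequency`` = mean conversion over
      editable positions; the maximum-position value is also reported
    * ``read_level_purity`` = among reads carrying ≥1 intended
      conversion, the fraction whose window deviations from reference
      are all intended conversions.
    """
    if editor not in EDITOR_RULES:
        raise ValueError(f"editor must be one of {sorted(EDITOR_RULES)}")
    src, dst = EDITOR_RULES[editor]
    if guide is None:
        guide = design.guides[0]
    w0, w1 = design.analysis_window(guide)
    width = w1 - w0

    # reference window on the protospacer strand
    ref_window = design.reference[w0:w1]
    if guide.strand == "-":
        ref_window = revcomp(ref_window)

    spanning: list[AlignedRead] = []
    seen: set[str] = set()
    for a in alignments:
        if not a.spans(w0, w1):
            continue
        if dedupe_pairs:
            if a.read_id in seen:
                continue
            seen.add(a.read_id)
        spanning.append(a)

    counts = np.zeros((width, len(BASE_COLUMNS)), dtype=np.int64)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    n_intended_only = 0
    n_any_intended = 0
    target_cols = [i for i in range(width) if ref_window[i] == src]
    for a in spanning:
        calls = []
        for k in range(width):
            b = a.aligned_bases.get(w0 + k, "other")
            calls.append(b)
        if guide.strand == "-":
            calls = [revcomp(b) if b in "ACGT" else b for b in reversed(calls)]
        intended = 0
        unintended = 0
        for k, b in enumerate(calls):
            counts[k, base_idx.get(b, 4)] += 1
            if b != ref_window[k] :
                if k in target_cols and b == dst:
                    intended += 1
                else:
                    unintended += 1
        if intended:
            n_any_intended += 1
            if unintended == 0:
                n_intended_only += 1

    coverage = len(spanning)
    if coverage == 0:
        warnings.warn("no reads fully span the analysis window")
    positions = pd.Index(range(1, width + 1), name="window_position")
    table = pd.DataFrame(counts, index=positions, columns=BASE_COLUMNS)
    table.insert(0, "ref", list(ref_window))

    target_positions = [k + 1 for k in target_cols]
    conv = pd.Series(np.nan, index=positions, dtype=float)
    purity = pd.Series(np.nan, index=positions, dtype=float)
    for k in target_cols:
        intended_n = counts[k, base_idx[dst]]
        ref_n = counts[k, base_idx[ref_window[k]]]
        nonref = coverage - ref_n
        if coverage:
            conv.iloc[k] = intended_n / coverage
        if nonref > 0:
            purity.iloc[k] = intended_n / nonref

    target_conv = conv.loc[target_positions]
    return WindowReport(
        per_position_counts=table,
        target_positions=target_positions,
        conversion_by_position=conv,
        purity_by_position=purity,
        target_conversion_frequency=(
            float(target_conv.mean()) if len(target_conv) else float("nan")
        ),
        max_position_conversion=(
            float(target_conv.max()) if len(target_conv) else float("nan")
        ),
        read_level_purity=(
            n_intended_only / n_any_intended if n_any_intended else float("nan")
        ),
        coverage=coverage,
    )


@dataclass
class DeletionCall:
    wt_probe: str
    del_probe: str
    wt_reads: int
    del_reads: int
    unclassified: int
    deletion_frequency: float | None


def _contains(read_seq: str, probe: str) -> bool:
    return probe in read_seq or probe in revcomp(read_seq)


def design_deletion_probes(
    design: AmpliconDesign, probe_length: int = 20
) -> tuple[str, str]:
    """Diagnostic k-mers for the wild-type and deletion alleles.

    The wild-type probe is taken from the centre of the inter-guide
    region (excised by the dual cut, so absent from deletion reads); the
    deletion probe spans the predicted cut-to-cut junction and therefore
    exists only in deletion molecules. Both must be unique in their
    allele and absent from the other.
    """
    if len(design.guides) != 2:
        raise ValueError("dual-guide analysis requires exactly two guides")
    cuts = sorted(design.cut_site(g) for g in design.guides)
    if cuts[1] - cuts[0] <= probe_length:
        raise ValueError("inter-guide distance must exceed probe_length")
    mid = (cuts[0] + cuts[1]) // 2
    wt_probe = design.reference[
        mid - probe_length // 2 : mid - probe_length // 2 + probe_length
    ]
    fusion = design.deletion_allele()
    half = probe_length // 2
    del_probe = fusion[cuts[0] - half : cuts[0] - half + probe_length]

    ref, rc = design.reference, revcomp(design.reference)
    for label, probe in (("wt", wt_probe), ("del", del_probe)):
        occurrences = ref.count(probe) + rc.count(probe)
        limit = 1 if label == "wt" else 0
        if occurrences != limit:
            raise ValueError(
                f"auto-derived {label} probe {probe!r} is not diagnostic in "
                "this amplicon; supply probes manually"
            )
    if wt_probe in fusion or revcomp(wt_probe) in fusion:
        raise ValueError(
            "wt probe survives in the deletion allele; supply probes manually"
        )
    return wt_probe, del_probe


def dual_deletion_frequency(
    reads,
    design: AmpliconDesign,
    probe_length: int = 20,
    probes: tuple[str, str] | None = None,
) -> DeletionCall:
    """Classify raw reads as wild-type or dual-guide deletion molecules.

    Classification is by exact probe containment (either orientation);
    reads matching neither or both probes are left unclassified and
    excluded from the frequency denominator.
    """
    wt_probe, del_probe = (
        probes if probes is not None
        else design_deletion_probes(design, probe_length)
    )
    wt = dl = un = 0
    for rec in reads:
        seq = rec[1] if isinstance(rec, tuple) else str(rec.seq)
        seq = seq.upper()
        has_wt = _contains(seq, wt_probe)
        has_del = _contains(seq, del_probe)
        if has_wt and not has_del:
            wt += 1
        elif has_del and not has_wt:
            dl += 1
        else:
            un += 1
    freq = dl / (dl + wt) if (dl + wt) else None
    if freq is None:
        warnings.warn("no reads matched either probe; frequency undefined")
    return DeletionCall(wt_probe, del_probe, wt, dl, un, freq)
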