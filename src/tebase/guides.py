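"""Guide design against transposable-element consensus sequences.

Enumerates protospacers adjacent to a PAM on both strands of a consensus
and annotates each guide for two base-editing use cases:

* CBE stop-codon introduction — C→T deamination inside the editing window
  (protospacer positions 3–9 from the PAM-distal end by default) that
  converts a sense codon into TAA/TAG/TGA, knocking out the element's ORF.
* ABE compatibility — at least one adenine inside the editing window, so
  the same protospacer can be reused with an A→G editor.

Coordinates: guides are stored with the leftmost reference coordinate of
the protospacer (0-based, forward-strand coordinates, half-open interval
``[target_start, target_start + len(protospacer))``) regardless of strand.
The protospacer and PAM strings are always reported 5'→3' on the guide's
own strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .sequences import (
    IUPAC,
    STOP_CODONS,
    matches_pattern,
    revcomp,
    validate_reference,
)

DEFAULT_WINDOW = (3, 9)


@dataclass(frozen=True)
class GuideRNA:
    """A protospacer with its PAM and placement on a reference.

    ``editing_window`` is inclusive and 1-based, counted from the 5'
    (PAM-distal) end of the protospacer.
    """

    protospacer: str
    pam: str
    target_start: int
    strand: str
    editing_window: tuple[int, int] = DEFAULT_WINDOW
    name: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.editing_window
        if not (1 <= lo <= hi <= len(self.protospacer)):
            raise ValueError(f"invalid editing window {self.editing_window}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def window_sequence(self) -> str:
        lo, hi = self.editing_window
        return self.protospacer[lo - 1 : hi]

    def window_reference_positions(self) -> list[int]:
        """Forward-strand reference coordinates of the editing-window bases.

        Returned in protospacer 5'→3' order (descending coordinates for a
        − strand guide).
        """
        n = len(self.protospacer)
        lo, hi = self.editing_window
        if self.strand == "+":
            return [self.target_start + w - 1 for w in range(lo, hi + 1)]
        return [self.target_start + n - w for w in range(lo, hi + 1)]


@dataclass
class StopGuideAnnotation:
    """Stop-codon and ABE annotations for one guide."""

    guide: GuideRNA
    edited_codons: list[tuple[int, str, str]] = field(default_factory=list)
    creates_stop: bool = False
    window_adenine_count: int = 0


def scan_pams(
    reference: str,
    pam_pattern: str = "NGG",
    guide_length: int = 20,
    editing_window: tuple[int, int] = DEFAULT_WINDOW,
    name_prefix: str = "g",
) -> list[GuideRNA]:
    """Enumerate all protospacer+PAM sites on both strands of *reference*.

    A site is reported when a full-length protospacer is followed 3' by a
    PAM matching *pam_pattern* (IUPAC semantics; reference N satisfies
    only pattern N). Guides whose protospacer would run past either
    reference end are discarded, and protospacers containing N are
    skipped because their sequence is not fully determined.
    """
    reference = validate_reference(reference)
    for code in pam_pattern.upper():
        if code not in IUPAC:
            raise ValueError(f"invalid IUPAC code {code!r} in PAM pattern")
    pam_pattern = pam_pattern.upper()
    plen = len(pam_pattern)
    if plen == 0:
        raise ValueError("pam_pattern must be nonempty")

    guides: list[GuideRNA] = []
    n = len(reference)
    for start in range(0, n - guide_length - plen + 1):
        # + strand: protospacer then PAM reading left to right
        proto = reference[start : start + guide_length]
        pam = reference[start + guide_length : start + guide_length + plen]
        if "N" not in proto and matches_pattern(pam, pam_pattern):
            guides.append(
                GuideRNA(proto, pam, start, "+", editing_window)
            )
    for start in range(plen, n - guide_length + 1):
        # − strand: PAM lies immediately left of the protospacer interval
        proto = revcomp(reference[start : start + guide_length])
        pam = revcomp(reference[start - plen : start])
        if "N" not in proto and matches_pattern(pam, pam_pattern):
            guides.append(
                GuideRNA(proto, pam, start, "-", editing_window)
            )
    guides.sort(key=lambda g: (g.target_start, g.strand))
    return [
        GuideRNA(
            g.protospacer, g.pam, g.target_start, g.strand,
            g.editing_window, f"{name_prefix}{i + 1}",
        )
        for i, g in enumerate(guides)
    ]


def abe_compatible(guide: GuideRNA) -> bool:
    """True if the editing window contains at least one adenine."""
    return "A" in guide.window_sequence


def window_adenine_count(guide: GuideRNA) -> int:
    return guide.window_sequence.count("A")


def _edited_reference(reference: str, guide: GuideRNA, positions=None) -> str:
    """Apply C→T edits (protospacer strand) at window positions.

    For a − strand guide a protospacer C is a reference G, so the
    forward-strand reference receives G→A at the mirrored coordinate.
    *positions* optionally restricts editing to a subset of window
    positions (1-based protospacer coordinates) for per-C analysis.
    """
    lo, hi = guide.editing_window
    wanted = set(range(lo, hi + 1)) if positions is None else set(positions)
    seq = list(reference)
    n = len(guide.protospacer)
    for w in wanted:
        if guide.strand == "+":
            r = guide.target_start + w - 1
            if 0 <= r < len(seq) and seq[r] == "C":
                seq[r] = "T"
        else:
            r = guide.target_start + n - w
            if 0 <= r < len(seq) and seq[r] == "G":
                seq[r] = "A"
    return "".join(seq)


def annotate_stop_guides(
    guides: list[GuideRNA],
    cds: str,
    cds_offset: int,
    reference: str | None = None,
    per_c: bool = False,
) -> list[StopGuideAnnotation]:
    """Test each guide for stop-codon introduction by window C→T editing.

    The CDS occupies reference interval ``[cds_offset, cds_offset+len(cds))``
    on the forward strand and must be in frame. By default all editable Cs
    in the window are converted simultaneously (efficient co-editing of
    adjacent Cs is the norm for CBEs); ``per_c=True`` instead reports a
    codon change if any single-C edit creates one.

    If *reference* is omitted, the CDS itself (shifted by ``cds_offset``)
    is used as the reference the guides were designed on.
    """
    if len(cds) % 3 != 0:
        raise ValueError("cds length must be divisible by 3")
    cds = validate_reference(cds, "cds")
    if reference is None:
        reference = "N" * cds_offset + cds
    reference = validate_reference(reference)

    out: list[StopGuideAnnotation] = []
    for guide in guides:
        edit_sets: list[list[int] | None]
        if per_c:
            lo, hi = guide.editing_window
            edit_sets = [[w] for w in range(lo, hi + 1)]
        else:
            edit_sets = [None]

        edited_codons: dict[int, tuple[str, str]] = {}
        creates_stop = False
        for positions in edit_sets:
            mutated = _edited_reference(reference, guide, positions)
            for ci in range(len(cds) // 3):
                r0 = cds_offset + 3 * ci
                ref_codon = reference[r0 : r0 + 3]
                new_codon = mutated[r0 : r0 + 3]
                if new_codon != ref_codon:
                    edited_codons[ci] = (ref_codon, new_codon)
                    if (
                        new_codon in STOP_CODONS
                        and ref_codon not in STOP_CODONS
                    ):
                        creates_stop = True
        out.append(
            StopGuideAnnotation(
                guide=guide,
                edited_codons=[
                    (ci, rc, nc)
                    for ci, (rc, nc) in sorted(edited_codons.items())
                ],
                creates_stop=creates_stop,
                window_adenine_count=window_adenine_count(guide),
            )
        )
    return out


def guides_to_frame(annotations: list[StopGuideAnnotation]) -> pd.DataFrame:
    """Tabulate annotated guides for TSV export."""
    rows = []
    for a in annotations:
        g = a.guide
        rows.append(
            {
                "name": g.name,
                "protospacer": g.protospacer,
                "pam": g.pam,
                "target_start": g.target_start,
                "strand": g.strand,
                "creates_stop": a.creates_stop,
                "window_adenine_count": a.window_adenine_count,
                "abe_compatible": a.window_adenine_count >= 1,
                "edited_codons": ";".join(
                    f"{ci}:{rc}>{nc}" for ci, rc, nc in a.edited_codons
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "name", "protospacer", "pam", "target_start", "strand",
            "creates_stop", "window_adenine_count", "abe_compatible",
            "edited_codons",
        ],
    )
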