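"""Guide design: PAM scanning, stop-codon annotation, ABE screening."""

from __future__ import annotations

import numpy as np
import pytest

from tebase import (
    GuideRNA,
    abe_compatible,
    annotate_stop_guides,
    guides_to_frame,
    scan_pams,
)
from tebase.sequences import revcomp, translate


class TestScanPams:
    def test_no_pam_possible(self):
        assert scan_pams("A" * 30) == []

    def test_plus_strand_site(self):
        guides = scan_pams("A" * 20 + "TGG")
        assert len(guides) == 1
        g = guides[0]
        assert (g.protospacer, g.pam, g.target_start, g.strand) == (
            "A" * 20, "TGG", 0, "+",
        )

    def test_minus_strand_site(self):
        guides = scan_pams("CCA" + "T" * 20)
        assert len(guides) == 1
        g = guides[0]
        assert (g.protospacer, g.pam, g.strand) == ("A" * 20, "TGG", "-")

    def test_too_short_reference(self):
        assert scan_pams("ACGTGG") == []

    def test_rejects_non_iupac_reference(self):
        with pytest.raises(ValueError):
            scan_pams("ACGTX" + "A" * 30)

    def test_reference_n_matches_only_pattern_n(self):
        # PAM "NGG" needs concrete G/G; an N in the genome is unknown
        assert scan_pams("A" * 20 + "TNG") == []
        # but an N at the pattern-N slot is fine
        guides = scan_pams("A" * 19 + "C" + "NGG")
        assert [g.strand for g in guides] == ["+"]

    def test_sacas9_style_pattern_is_configurable(self):
        ref = "A" * 20 + "TTGAAT"
        assert scan_pams(ref, pam_pattern="NNGRRT") != []
        assert scan_pams(ref, pam_pattern="NGG") == []

    @pytest.mark.parametrize("seed", range(5))
    def test_roundtrip_reextraction(self, seed):
        """Every reported guide re-extracts exactly from the reference."""
        rng = np.random.default_rng(seed)
        ref = "".join(rng.choice(list("ACGT"), 300))
        for g in scan_pams(ref):
            n = len(g.protospacer)
            seg = ref[g.target_start : g.target_start + n]
            if g.strand == "+":
                assert seg == g.protospacer
                assert ref[g.target_start + n : g.target_start + n + 3] == g.pam
            else:
                assert revcomp(seg) == g.protospacer
                assert revcomp(ref[g.target_start - 3 : g.target_start]) == g.pam

    @pytest.mark.parametrize("seed", range(5))
    def test_revcomp_reference_mirrors_guides(self, seed):
        """Scanning the reverse complement swaps strands and mirrors coords."""
        rng = np.random.default_rng(100 + seed)
        ref = "".join(rng.choice(list("ACGT"), 250))
        fwd = scan_pams(ref)
        rev = scan_pams(revcomp(ref))
        n = len(ref)

        def key(g):
            # mirror: interval [s, s+20) on ref maps to [n-s-20, n-s)
            return (g.protospacer, g.pam)

        mirrored = {
            (n - g.target_start - len(g.protospacer),
             "-" if g.strand == "+" else "+", key(g))
            for g in rev
        }
        original = {(g.target_start, g.strand, key(g)) for g in fwd}
        assert original == mirrored


class TestStopAnnotation:
    def _guide_on(self, ref: str, start: int, strand: str = "+") -> GuideRNA:
        seg = ref[start : start + 20]
        proto = seg if strand == "+" else revcomp(seg)
        return GuideRNA(proto, "NGG", start, strand)

    def test_caa_to_taa(self):
        # codon CAA in frame; window C converts to T -> TAA stop
        cds = "ATG" + "CAA" + "GGT" * 6  # 8 codons, 24 nt
        ref = cds
        g = self._guide_on(ref, 1)  # window pos 3 hits the C of CAA
        (ann,) = annotate_stop_guides([g], cds, 0, ref)
        assert ann.creates_stop
        assert (1, "CAA", "TAA") in ann.edited_codons

    @pytest.mark.parametrize("codon,stop", [("CGA", "TGA"), ("CAG", "TAG")])
    def test_other_sense_strand_conversions(self, codon, stop):
        cds = "ATG" + codon + "GGT" * 6
        g = self._guide_on(cds, 1)
        (ann,) = annotate_stop_guides([g], cds, 0, cds)
        assert ann.creates_stop
        assert (1, codon, stop) in ann.edited_codons

    def test_no_c_in_window_means_no_edit(self):
        cds = "ATG" + "GGT" * 7
        g = self._guide_on(cds, 1)
        (ann,) = annotate_stop_guides([g], cds, 0, cds)
        assert not ann.creates_stop
        assert ann.edited_codons == []

    def test_guide_outside_cds_is_inert(self):
        ref = "C" * 40 + "ATGGGTTAA"
        g = self._guide_on(ref, 0)
        (ann,) = annotate_stop_guides([g], ref[40:], 40, ref)
        assert not ann.creates_stop
        assert ann.edited_codons == []

    def test_existing_stop_not_counted_as_novel(self):
        # TGA is already a stop; C->T elsewhere must not claim it
        cds = "ATG" + "TGA" + "CAT" * 6
        g = self._guide_on(cds, 1)
        (ann,) = annotate_stop_guides([g], cds, 0, cds)
        stops = [c for c in ann.edited_codons if c[2] in ("TAA", "TAG", "TGA")]
        for _, ref_codon, _ in stops:
            assert ref_codon not in ("TAA", "TAG", "TGA")

    def test_brute_force_oracle_on_random_cds(self):
        """Agreement with translate-the-whole-CDS stop search, 1000 cases.

        Oracle: mutate every window C (protospacer strand) in the
        reference, translate the full CDS before and after, and call a
        stop created iff a '*' appears at a codon that was not '*'.
        """
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n_codons = int(rng.integers(8, 15))
            cds = "".join(rng.choice(list("ACGT"), 3 * n_codons))
            start = int(rng.integers(0, len(cds) - 20 + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            g = self._guide_on(cds, start, strand)
            (ann,) = annotate_stop_guides([g], cds, 0, cds)

            mutated = list(cds)
            lo, hi = g.editing_window
            for w in range(lo, hi + 1):
                if strand == "+":
                    r = start + w - 1
                    if mutated[r] == "C":
                        mutated[r] = "T"
                else:
                    r = start + 20 - w
                    if mutated[r] == "G":
                        mutated[r] = "A"
            before = translate(cds)
            after = translate("".join(mutated))
            oracle = any(
                b != "*" and a == "*" for b, a in zip(before, after)
            )
            assert ann.creates_stop == oracle


class TestAbeCompatibility:
    def test_adenine_in_window(self):
        g = GuideRNA("GGAGGTTTTTTTTTTTTTTT", "AGG", 0, "+")
        assert abe_compatible(g)  # A at window position 3

    def test_no_adenine_in_window(self):
        g = GuideRNA("AATGCGTGCGTTTTTTTTTT", "AGG", 0, "+")
        assert not abe_compatible(g)  # window (3..9) = TGCGTGC

    def test_single_window_adenine_counted(self):
        g = GuideRNA("GGTTATTTTTTTTTTTTTTT", "AGG", 0, "+")
        (ann,) = annotate_stop_guides([g], "GGT" * 7, 0, None)
        assert abe_compatible(g)
        assert ann.window_adenine_count == 1


def test_guides_to_frame_columns(single_guide_design):
    g = single_guide_design.guides[0]
    ann = annotate_stop_guides(
        [g], single_guide_design.reference[:198], 0,
        single_guide_design.reference,
    )
    frame = guides_to_frame(ann)
    assert list(frame.columns)[:5] == [
        "name", "protospacer", "pam", "target_start", "strand",
    ]
    assert frame.loc[0, "name"] == "gC"
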