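"""Amplicon quantification: indel window counting, deamination, dual deletions."""

from __future__ import annotations

import numpy as np
import pytest

from fixtures import (
    build_deamination_fixture,
    build_indel_fixture,
    paired_reads_from_molecule,
)
from tebase import (
    AmpliconDesign,
    EditProfile,
    align_reads,
    deamination_report,
    design_deletion_probes,
    dual_deletion_frequency,
    indel_frequency,
    simulate_amplicon_reads,
)
from tebase.sequences import revcomp


class TestAnalysisWindow:
    def test_plus_strand_window_is_30nt_from_protospacer_start(
        self, single_guide_design
    ):
        g = single_guide_design.guides[0]
        w0, w1 = single_guide_design.analysis_window(g)
        assert (w0, w1) == (85, 115)
        assert w1 - w0 == len(g.protospacer) + len(g.pam) + 7

    def test_minus_strand_window_is_mirrored(self, dual_guide_design):
        g = dual_guide_design.guides[1]
        w0, w1 = dual_guide_design.analysis_window(g)
        # protospacer interval [150, 170); window extends 10 nt left
        # (PAM + 7) past the protospacer on the forward strand
        assert (w0, w1) == (140, 170)

    def test_cut_sites_flank_the_excised_segment(self, dual_guide_design):
        g1, g2 = dual_guide_design.guides
        assert dual_guide_design.cut_site(g1) == 85 + 17
        assert dual_guide_design.cut_site(g2) == 150 + 3
        fused = dual_guide_design.deletion_allele()
        assert fused == (
            dual_guide_design.reference[:102] + dual_guide_design.reference[153:]
        )

    def test_misplaced_guide_rejected(self, single_guide_design):
        from tebase import GuideRNA

        bad = GuideRNA("A" * 20, "TGG", 85, "+")
        with pytest.raises(ValueError):
            AmpliconDesign(single_guide_design.reference, [bad])


class TestIndelFrequency:
    def test_constructed_fixture_hand_counts(self, single_guide_design):
        reads = build_indel_fixture(single_guide_design)
        alns = align_reads(reads, single_guide_design)
        concordant = indel_frequency(
            alns, single_guide_design, require_both_mates=True
        )
        assert concordant.total_read_pairs == 100
        assert concordant.indel_read_pairs == 10
        assert concordant.frequency == pytest.approx(0.10)
        relaxed = indel_frequency(
            alns, single_guide_design, require_both_mates=False
        )
        assert relaxed.frequency == pytest.approx(0.15)

    def test_no_indels_means_zero(self, single_guide_design):
        amp = single_guide_design.reference
        reads = []
        for i in range(20):
            reads += paired_reads_from_molecule(f"p{i}", amp)
        summ = indel_frequency(
            align_reads(reads, single_guide_design), single_guide_design
        )
        assert summ.frequency == 0.0
        assert summ.indel_catalog == {}

    def test_zero_covering_pairs_warns(self, single_guide_design):
        reads = [("short/1", single_guide_design.reference[:40])]
        alns = align_reads(reads, single_guide_design)
        with pytest.warns(UserWarning):
            summ = indel_frequency(alns, single_guide_design)
        assert summ.frequency is None

    def test_concordance_filter_monotonicity(self, single_guide_design):
        profile = EditProfile(
            indel_rate=0.2, indel_size_distribution={-2: 0.5, 1: 0.5},
            sequencing_error_rate=0.002, seed=91,
        )
        reads, _ = simulate_amplicon_reads(
            single_guide_design, profile, 300
        )
        alns = align_reads(reads, single_guide_design)
        strict = indel_frequency(alns, single_guide_design, True).frequency
        loose = indel_frequency(alns, single_guide_design, False).frequency
        assert loose >= strict

    def test_matches_simulator_truth_recount(self, single_guide_design):
        profile = EditProfile(
            indel_rate=0.1, indel_size_distribution={-2: 1.0}, seed=3
        )
        reads, truth = simulate_amplicon_reads(
            single_guide_design, profile, 400
        )
        alns = align_reads(reads, single_guide_design)
        summ = indel_frequency(alns, single_guide_design)
        assert summ.total_read_pairs == 400
        assert summ.frequency == pytest.approx(
            (truth.indel_size != 0).mean()
        )


class TestDeaminationReport:
    def test_all_reference_reads(self, single_guide_design):
        reads = build_deamination_fixture(
            single_guide_design, 6, n_total=50, n_converted=0
        )
        rep = deamination_report(
            align_reads(reads, single_guide_design), single_guide_design
        )
        assert rep.coverage == 50
        assert (rep.conversion_by_position.dropna() == 0).all()
        assert rep.purity_by_position.dropna().empty
        assert np.isnan(rep.read_level_purity)

    def test_quarter_conversion_at_one_position(self, single_guide_design):
        reads = build_deamination_fixture(
            single_guide_design, 6, n_total=200, n_converted=50
        )
        rep = deamination_report(
            align_reads(reads, single_guide_design), single_guide_design
        )
        assert rep.conversion_at(6) == pytest.approx(0.25)
        assert rep.purity_by_position.loc[6] == pytest.approx(1.0)
        assert rep.max_position_conversion == pytest.approx(0.25)

    def test_purity_with_unintended_base(self, single_guide_design):
        # 30 C->T and 10 C->G at the same target position
        reads = build_deamination_fixture(
            single_guide_design, 4, n_total=200, n_converted=30,
            n_other=10, other_base="G",
        )
        rep = deamination_report(
            align_reads(reads, single_guide_design), single_guide_design
        )
        assert rep.purity_by_position.loc[4] == pytest.approx(30 / 40)
        assert rep.conversion_at(4) == pytest.approx(30 / 200)

    def test_counts_sum_to_coverage(self, single_guide_design):
        profile = EditProfile(
            per_position_conversion={6: 0.3, 7: 0.1},
            sequencing_error_rate=0.01, seed=8,
        )
        reads, _ = simulate_amplicon_reads(single_guide_design, profile, 200)
        rep = deamination_report(
            align_reads(reads, single_guide_design), single_guide_design
        )
        base_counts = rep.per_position_counts.drop(columns="ref")
        assert (base_counts.sum(axis=1) == rep.coverage).all()

    def test_target_positions_are_window_cs(self, single_guide_design):
        reads = build_deamination_fixture(
            single_guide_design, 6, n_total=10, n_converted=0
        )
        rep = deamination_report(
            align_reads(reads, single_guide_design), single_guide_design
        )
        window = single_guide_design.reference[85:115]
        assert rep.target_positions == [
            i + 1 for i, b in enumerate(window) if b == "C"
        ]

    def test_revcomp_read_set_gives_identical_report(
        self, single_guide_design
    ):
        reads = build_deamination_fixture(
            single_guide_design, 6, n_total=120, n_converted=30
        )
        flipped = [(rid, revcomp(seq)) for rid, seq in reads]
        rep = deamination_report(
            align_reads(reads, single_guide_design), single_guide_design
        )
        rep_rc = deamination_report(
            align_reads(flipped, single_guide_design), single_guide_design
        )
        assert rep.per_position_counts.equals(rep_rc.per_position_counts)
        assert rep.target_conversion_frequency == pytest.approx(
            rep_rc.target_conversion_frequency
        )

    def test_binomial_recovery_of_programmed_conversion(
        self, single_guide_design
    ):
        p, n = 0.3, 1000
        profile = EditProfile(per_position_conversion={6: p}, seed=44)
        reads, _ = simulate_amplicon_reads(single_guide_design, profile, n)
        rep = deamination_report(
            align_reads(reads, single_guide_design), single_guide_design
        )
        tol = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(rep.conversion_at(6) - p) <= tol

    def test_no_spanning_reads_warns(self, single_guide_design):
        with pytest.warns(UserWarning):
            rep = deamination_report([], single_guide_design)
        assert rep.coverage == 0

    def test_abe_mode_counts_a_to_g(self, single_guide_design):
        profile = EditProfile(
            editor="ABE", per_position_conversion={5: 0.5}, seed=21
        )
        reads, truth = simulate_amplicon_reads(
            single_guide_design, profile, 400
        )
        rep = deamination_report(
            align_reads(reads, single_guide_design),
            single_guide_design, editor="ABE",
        )
        window = single_guide_design.reference[85:115]
        assert rep.target_positions == [
            i + 1 for i, b in enumerate(window) if b == "A"
        ]
        truth_frac = truth.conversions.str.split(",").apply(
            lambda v: "5" in v
        ).mean()
        assert rep.conversion_at(5) == pytest.approx(truth_frac)


class TestDualDeletion:
    def test_probe_autoderivation(self, dual_guide_design):
        wt_probe, del_probe = design_deletion_probes(dual_guide_design)
        ref = dual_guide_design.reference
        fused = dual_guide_design.deletion_allele()
        assert wt_probe in ref and wt_probe not in fused
        assert del_probe in fused and del_probe not in ref

    def test_all_wildtype_reads(self, dual_guide_design):
        amp = dual_guide_design.reference
        reads = [(f"r{i}", amp[:150]) for i in range(50)]
        call = dual_deletion_frequency(reads, dual_guide_design)
        assert call.deletion_frequency == 0.0
        assert call.wt_reads == 50

    def test_hand_counted_mixture(self, dual_guide_design):
        amp = dual_guide_design.reference
        fused = dual_guide_design.deletion_allele()
        rng = np.random.default_rng(17)
        reads = [(f"wt{i}", amp[:150]) for i in range(60)]
        reads += [(f"del{i}", fused) for i in range(20)]
        reads += [
            (f"junk{i}", "".join(rng.choice(list("ACGT"), 150)))
            for i in range(20)
        ]
        call = dual_deletion_frequency(reads, dual_guide_design)
        assert (call.wt_reads, call.del_reads, call.unclassified) == (
            60, 20, 20,
        )
        assert call.deletion_frequency == pytest.approx(0.25)

    def test_simulated_recovery_within_binomial_tolerance(
        self, dual_guide_design
    ):
        p, n = 0.4, 2000
        profile = EditProfile(deletion_fraction=p, seed=13)
        reads, truth = simulate_amplicon_reads(dual_guide_design, profile, n)
        call = dual_deletion_frequency(reads, dual_guide_design)
        tol = 3 * np.sqrt(p * (1 - p) / n)
        assert abs(call.deletion_frequency - p) <= tol
        # with zero sequencing error classification matches truth exactly
        assert call.del_reads == 2 * (truth.allele == "del").sum()

    def test_nonunique_probe_rejected(self, dual_guide_design):
        wt_probe, _ = design_deletion_probes(dual_guide_design)
        duped = AmpliconDesign(
            dual_guide_design.reference + wt_probe,
            dual_guide_design.guides,
        )
        with pytest.raises(ValueError, match="probe"):
            design_deletion_probes(duped)

    def test_close_guides_rejected(self, single_guide_design):
        from tebase import GuideRNA

        amp = single_guide_design.reference
        g1 = single_guide_design.guides[0]
        g2 = GuideRNA(revcomp(amp[108:128]), revcomp(amp[105:108]),
                      108, "-", name="near")
        design = AmpliconDesign(amp, [g1, g2])
        with pytest.raises(ValueError, match="inter-guide"):
            design_deletion_probes(design)
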