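"""Hand-constructed read fixtures shared by unit and acceptance tests."""

from __future__ import annotations

from tebase import AmpliconDesign
from tebase.sequences import revcomp


def paired_reads_from_molecule(read_id: str, molecule: str,
                               read_length: int = 150):
    """MiSeq-style pair: 5' prefix and reverse-complemented 3' suffix."""
    return [
        (f"{read_id}/1", molecule[:read_length]),
        (f"{read_id}/2", revcomp(molecule)[:read_length]),
    ]


def build_indel_fixture(design: AmpliconDesign):
    """100 read pairs with a known indel composition.

    * 80 clean pairs;
    * 10 pairs with a 2 nt deletion inside the analysis window,
      present in both mates (concordant);
    * 5 pairs with a 2 nt deletion outside the window (both mates);
    * 5 pairs whose forward mate carries the in-window deletion but
      whose reverse mate is wild type (discordant).

    Expected window indel frequency: 0.10 with mate concordance
    required, 0.15 without.
    """
    amp = design.reference
    w0, w1 = design.analysis_window(design.guides[0])
    in_window = (w0 + w1) // 2
    out_window = w0 - 25  # covered by both mates, outside the window
    assert out_window > 0

    del_mol = amp[:in_window] + amp[in_window + 2 :]
    far_mol = amp[:out_window] + amp[out_window + 2 :]

    reads = []
    i = 0
    for _ in range(80):
        reads += paired_reads_from_molecule(f"clean{i}", amp)
        i += 1
    for _ in range(10):
        reads += paired_reads_from_molecule(f"concordant{i}", del_mol)
        i += 1
    for _ in range(5):
        reads += paired_reads_from_molecule(f"outside{i}", far_mol)
        i += 1
    for _ in range(5):
        fwd, _ = paired_reads_from_molecule(f"discordant{i}", del_mol)
        _, rev = paired_reads_from_molecule(f"discordant{i}", amp)
        reads += [fwd, rev]
        i += 1
    return reads


def build_deamination_fixture(design: AmpliconDesign, window_position: int,
                              n_total: int = 200, n_converted: int = 50,
                              to_base: str = "T", n_other: int = 0,
                              other_base: str = "G"):
    """Spanning single-end reads with programmed substitutions.

    *n_converted* reads carry ``C→to_base`` and *n_other* reads carry
    ``C→other_base`` at the given (1-based, protospacer-strand) window
    position of guide 1; the remainder match the reference.
    """
    amp = design.reference
    guide = design.guides[0]
    w0, w1 = design.analysis_window(guide)
    ref_pos = w0 + window_position - 1 if guide.strand == "+" \
        else w1 - window_position

    def substituted(base: str) -> str:
        b = base if guide.strand == "+" else revcomp(base)
        return amp[:ref_pos] + b + amp[ref_pos + 1 :]

    reads = []
    for i in range(n_converted):
        reads.append((f"conv{i}", substituted(to_base)[:150]))
    for i in range(n_other):
        reads.append((f"other{i}", substituted(other_base)[:150]))
    for i in range(n_total - n_converted - n_other):
        reads.append((f"ref{i}", amp[:150]))
    return reads
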