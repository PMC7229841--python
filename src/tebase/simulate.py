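"""Seeded generators for every input the pipeline consumes.

Three simulators with recorded ground truth:

* amplicon read pairs (150 nt paired-end by default) carrying programmed
  per-position base conversions, bystander substitutions, window indels,
  dual-guide deletion alleles and uniform sequencing error;
* toy genomes with transposable-element consensus copies planted at
  recorded coordinates and divergence;
* qPCR Ct tables generated from a known copy number under the ΔCt model.

Every simulator takes an explicit seed and is byte-deterministic: the
same seed yields the same FASTQ/FASTA/table. Sequencing error is modeled
as uniform substitution only — enough to stress the estimators without a
quality-aware error model. Defaults mirror the experimental scales this
pipeline targets: 30 nt analysis windows, 150 nt paired-end reads, and
conversion frequencies in the 0.01–0.55 range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import EDITOR_RULES, AmpliconDesign
from .guides import GuideRNA
from .sequences import revcomp, validate_reference

BASES = np.array(list("ACGT"))


@dataclass
class EditProfile:
    """Programmed editing outcomes for one simulated sample.

    Positions are 1-based coordinates inside the 30 nt analysis window of
    the profiled guide, on the protospacer strand. Indel sizes are
    signed: negative = deletion, positive = insertion.
    """

    editor: str = "CBE"
    per_position_conversion: dict[int, float] = field(default_factory=dict)
    bystander: dict[int, dict[str, float]] = field(default_factory=dict)
    indel_rate: float = 0.0
    indel_size_distribution: dict[int, float] = field(
        default_factory=lambda: {-1: 1.0}
    )
    deletion_fraction: float = 0.0
    sequencing_error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        probs = list(self.per_position_conversion.values())
        probs += [self.indel_rate, self.deletion_fraction,
                  self.sequencing_error_rate]
        for d in self.bystander.values():
            probs += list(d.values())
            if sum(d.values()) > 1.0 + 1e-9:
                raise ValueError("bystander probabilities at one position "
                                 "exceed 1")
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all profile probabilities must be in [0, 1]")
        if self.editor not in EDITOR_RULES:
            raise ValueError(f"unknown editor {self.editor!r}")
        if self.indel_size_distribution:
            total = sum(self.indel_size_distribution.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError("indel size distribution must sum to 1")
            if 0 in self.indel_size_distribution:
                raise ValueError("indel size 0 is not an indel")


def _window_to_ref(design: AmpliconDesign, guide: GuideRNA, w: int) -> int:
    """Reference coordinate of window position *w* (1-based, proto strand)."""
    w0, w1 = design.analysis_window(guide)
    return w0 + w - 1 if guide.strand == "+" else w1 - w


def _apply_base(seq: list[str], design: AmpliconDesign, guide: GuideRNA,
                w: int, base: str) -> None:
    r = _window_to_ref(design, guide, w)
    seq[r] = base if guide.strand == "+" else revcomp(base)


def _sequencing_errors(seq: str, rate: float, rng) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return "".join(arr), len(hits)


def simulate_amplicon_reads(
    design: AmpliconDesign,
    profile: EditProfile,
    n_reads: int,
    read_length: int = 150,
    paired: bool = True,
    guide: GuideRNA | None = None,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Simulate *n_reads* molecules (read pairs when paired) with truth.

    Each molecule independently draws its allele (dual-guide deletion
    with probability ``deletion_fraction``, requiring a two-guide
    design), programmed conversions/bystanders at window positions,
    at most one window indel, and per-base sequencing error. The forward
    read covers the molecule 5' end, the reverse read the 3' end
    (reverse-complemented), MiSeq style. Returns FASTQ-ready records and
    a one-row-per-molecule truth table.
    """
    profile.validate()
    if profile.deletion_fraction > 0 and len(design.guides) != 2:
        raise ValueError("deletion_fraction needs a two-guide design")
    if read_length > len(design.reference):
        raise ValueError("read_length exceeds the wild-type amplicon")
    if guide is None:
        guide = design.guides[0]
    src, dst = EDITOR_RULES[profile.editor]
    rng = np.random.default_rng(profile.seed)
    w0, w1 = design.analysis_window(guide)

    records: list[SeqRecord] = []
    truth_rows = []
    for i in range(n_reads):
        read_id = f"read{i:06d}"
        allele = "del" if (
            profile.deletion_fraction > 0
            and rng.random() < profile.deletion_fraction
        ) else "wt"
        conversions: list[int] = []
        bystanders: list[str] = []
        indel_pos, indel_size = -1, 0
        if allele == "del":
            molecule = design.deletion_allele()
        else:
            seq = list(design.reference)
            for w, p in sorted(profile.per_position_conversion.items()):
                r = _window_to_ref(design, guide, w)
                ref_base = design.reference[r]
                proto_base = ref_base if guide.strand == "+" \
                    else revcomp(ref_base)
                if proto_base == src and rng.random() < p:
                    _apply_base(seq, design, guide, w, dst)
                    conversions.append(w)
            for w, dist in sorted(profile.bystander.items()):
                u = rng.random()
                acc = 0.0
                for base, p in sorted(dist.items()):
                    acc += p
                    if u < acc:
                        _apply_base(seq, design, guide, w, base)
                        bystanders.append(f"{w}>{base}")
                        break
            molecule = "".join(seq)
            if profile.indel_rate > 0 and rng.random() < profile.indel_rate:
                sizes = sorted(profile.indel_size_distribution)
                probs = [profile.indel_size_distribution[s] for s in sizes]
                indel_size = int(rng.choice(sizes, p=probs))
                indel_pos = int(rng.integers(w0, w1))
                if indel_size < 0:
                    molecule = (
                        molecule[:indel_pos]
                        + molecule[indel_pos - indel_size :]
                    )
                else:
                    ins = "".join(rng.choice(BASES, indel_size))
                    molecule = (
                        molecule[:indel_pos] + ins + molecule[indel_pos:]
                    )

        fwd = molecule[:read_length]
        fwd, err_f = _sequencing_errors(
            fwd, profile.sequencing_error_rate, rng
        )
        n_err = err_f
        records.append(_fastq_record(f"{read_id}/1", fwd))
        if paired:
            rev = revcomp(molecule)[:read_length]
            rev, err_r = _sequencing_errors(
                rev, profile.sequencing_error_rate, rng
            )
            n_err += err_r
            records.append(_fastq_record(f"{read_id}/2", rev))
        truth_rows.append(
            {
                "read_id": read_id,
                "allele": allele,
                "conversions": ",".join(map(str, conversions)),
                "bystanders": ",".join(bystanders),
                "indel_pos": indel_pos,
                "indel_size": indel_size,
                "n_sequencing_errors": n_err,
            }
        )
    return records, pd.DataFrame(truth_rows)


def _fastq_record(read_id: str, seq: str) -> SeqRecord:
    rec = SeqRecord(Seq(seq), id=read_id, description="")
    rec.letter_annotations["phred_quality"] = [40] * len(seq)
    return rec


def simulate_te_genome(
    n_chrom: int,
    consensus: str,
    copies: dict[str, int] | int,
    divergence: float = 0.0,
    seed: int = 0,
    chrom_length: int = 50_000,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Toy genome with consensus copies planted at known positions.

    Copies are placed in non-overlapping slots at random offsets, on a
    random strand, with i.i.d. substitutions at rate *divergence*;
    background sequence is uniform random. *copies* may be a per-chrom
    map or a single count used for every chromosome. Raises when a
    chromosome cannot host its requested copies without overlap.
    """
    consensus = validate_reference(consensus, "consensus")
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    chrom_names = [f"chr{i + 1}" for i in range(n_chrom)]
    if isinstance(copies, int):
        copies = {c: copies for c in chrom_names}
    rng = np.random.default_rng(seed)
    stride = len(consensus) + 20
    genome: dict[str, str] = {}
    rows = []
    for chrom in chrom_names:
        n_copies = copies.get(chrom, 0)
        n_slots = chrom_length // stride
        if n_copies > n_slots:
            raise ValueError(
                f"{chrom}: {n_copies} copies do not fit in "
                f"{chrom_length} nt without overlap"
            )
        seq = rng.choice(BASES, chrom_length)
        slots = rng.choice(n_slots, size=n_copies, replace=False)
        for slot in sorted(slots.tolist()):
            offset = int(rng.integers(0, 20))
            start = slot * stride + offset
            strand = "+" if rng.random() < 0.5 else "-"
            copy = np.array(
                list(consensus if strand == "+" else revcomp(consensus))
            )
            n_subs = 0
            if divergence > 0:
                mask = rng.random(len(copy)) < divergence
                for j in np.flatnonzero(mask):
                    alts = [b for b in "ACGT" if b != copy[j]]
                    copy[j] = alts[rng.integers(0, 3)]
                n_subs = int(mask.sum())
            seq[start : start + len(copy)] = copy
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": start + len(consensus),
                    "strand": strand,
                    "n_substitutions": n_subs,
                }
            )
        genome[chrom] = "".join(seq)
    return genome, pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "n_substitutions"],
    )


def simulate_qpcr(
    copies: float,
    ct_reference: float = 28.0,
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
    sample: str = "sample",
    target_primer: str = "target",
    reference_primer: str = "reference",
) -> pd.DataFrame:
    """Ct table for a target of known copy number plus its control.

    Target Ct = reference Ct − log_E(copies), plus Gaussian replicate
    noise on both primer pairs.
    """
    if copies <= 0:
        raise ValueError("copies must be positive")
    rng = np.random.default_rng(seed)
    ct_target = ct_reference - np.log(copies) / np.log(efficiency)
    rows = []
    for primer, ct in ((target_primer, ct_target),
                       (reference_primer, ct_reference)):
        for rep in range(1, n_replicates + 1):
            noise = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
            rows.append(
                {
                    "sample": sample,
                    "primer_pair": primer,
                    "ct": ct + noise,
                    "replicate": rep,
                }
            )
    return pd.DataFrame(rows)


def roundtrip_copy_number(table: pd.DataFrame, efficiency: float = 2.0,
                          reference_primer: str = "reference") -> float:
    """Convenience: estimate copies back from a simulated Ct table."""
    from .qpcr import estimate_from_table

    est = estimate_from_table(
        table, reference_primer=reference_primer, efficiency=efficiency
    )
    return float(est["copies_per_haploid"].iloc[0])
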