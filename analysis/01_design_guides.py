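#!/usr/bin/env python
"""Design stop-codon-generating guides on a synthetic TE consensus.

Builds a LINE-1-style consensus carrying a long ORF, enumerates every
NGG protospacer on both strands, and annotates which guides knock the
ORF out via C→T editing in the 3–9 window (CBE) and which are reusable
with an ABE (≥1 window adenine). Writes the consensus FASTA and the
annotated guide table under results/.
"""

import numpy as np

from tebase import annotate_stop_guides, guides_to_frame, scan_pams
from tebase.io import write_fasta, write_tsv

SEED = 2026
ORF_CODONS = 220
UTR = 60


def synthetic_consensus(rng: np.random.Generator) -> tuple[str, int]:
    """Random consensus with an in-frame, stop-free ORF after a 5' UTR."""
    codons = []
    while len(codons) < ORF_CODONS - 2:
        c = "".join(rng.choice(list("ACGT"), 3))
        if c not in ("TAA", "TAG", "TGA", "ATG"):
            codons.append(c)
    cds = "ATG" + "".join(codons) + "TAA"
    utr5 = "".join(rng.choice(list("ACGT"), UTR))
    utr3 = "".join(rng.choice(list("ACGT"), UTR))
    return utr5 + cds + utr3, UTR


def main() -> None:
    rng = np.random.default_rng(SEED)
    consensus, cds_offset = synthetic_consensus(rng)
    cds_len = (len(consensus) - 2 * UTR)
    cds = consensus[cds_offset : cds_offset + cds_len]

    guides = scan_pams(consensus, "NGG", 20, name_prefix="sTEg")
    annotated = annotate_stop_guides(guides, cds, cds_offset, consensus)
    frame = guides_to_frame(annotated)

    write_fasta({"synthetic_TE_consensus": consensus},
                "results/consensus.fasta")
    write_tsv(frame, "results/guides.tsv")

    n_stop = int(frame.creates_stop.sum())
    n_abe = int(frame.abe_compatible.sum())
    print(f"consensus: {len(consensus)} nt, ORF {cds_len} nt "
          f"at offset {cds_offset}")
    print(f"{len(frame)} NGG guides; {n_stop} create a stop codon "
          f"({n_stop / len(frame):.1%}); {n_abe} ABE-compatible")
    best = frame[frame.creates_stop & frame.abe_compatible]
    print(f"{len(best)} guides usable with both editor classes; first:")
    if len(best):
        print(best.head(3).to_string(index=False))


if __name__ == "__main__":
    main()
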