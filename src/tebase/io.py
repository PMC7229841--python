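"""File-format helpers: FASTA/FASTQ via Biopython, tables via pandas, YAML configs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .amplicon import AmpliconDesign
from .guides import GuideRNA


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA file → ordered {name: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: str | Path) -> list[SeqRecord]:
    return list(SeqIO.parse(str(path), "fastq"))


def write_fastq(records, path: str | Path) -> None:
    SeqIO.write(records, str(path), "fastq")


def write_tsv(frame: pd.DataFrame, path: str | Path, **kwargs) -> None:
    frame.to_csv(path, sep="\t", index=kwargs.pop("index", False), **kwargs)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def load_design(path: str | Path) -> AmpliconDesign:
    """Load an amplicon design from YAML.

    Expected keys: ``reference`` (sequence string) and ``guides``, a list
    of mappings with ``protospacer``, ``pam``, ``target_start``,
    ``strand`` and optional ``name``/``editing_window``.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    guides = [
        GuideRNA(
            protospacer=g["protospacer"].upper(),
            pam=g["pam"].upper(),
            target_start=int(g["target_start"]),
            strand=g["strand"],
            editing_window=tuple(g.get("editing_window", (3, 9))),
            name=g.get("name", f"g{i + 1}"),
        )
        for i, g in enumerate(cfg["guides"])
    ]
    return AmpliconDesign(
        reference=cfg["reference"],
        guides=guides,
        name=cfg.get("name", "amplicon"),
    )


def save_design(design: AmpliconDesign, path: str | Path) -> None:
    cfg = {
        "name": design.name,
        "reference": design.reference,
        "guides": [
            {
                "name": g.name,
                "protospacer": g.protospacer,
                "pam": g.pam,
                "target_start": g.target_start,
                "strand": g.strand,
                "editing_window": list(g.editing_window),
            }
            for g in design.guides
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
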