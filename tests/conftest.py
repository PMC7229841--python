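"""Shared fixtures: a deterministic amplicon design with one or two guides."""

from __future__ import annotations

import numpy as np
import pytest

from tebase import AmpliconDesign, GuideRNA
from tebase.sequences import revcomp


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def single_guide_design(rng) -> AmpliconDesign:
    """200 nt amplicon, one + strand guide at position 85.

    The protospacer carries Cs at positions 4, 6 and 7 (inside the 3–9
    editing window) and spans window positions such that both 150 nt
    mates of a pair fully cover the 30 nt analysis window [85, 115).
    """
    local = np.random.default_rng(42)
    left = random_dna(local, 85)
    proto = "GATCACCTACGTGCAATGCA"
    pam = "TGG"
    right = random_dna(local, 200 - 85 - len(proto) - len(pam))
    amp = left + proto + pam + right
    guide = GuideRNA(proto, pam, 85, "+", name="gC")
    return AmpliconDesign(amp, [guide], name="single")


@pytest.fixture(scope="session")
def dual_guide_design(single_guide_design) -> AmpliconDesign:
    """The same amplicon with a second, − strand guide at position 150."""
    amp = single_guide_design.reference
    g1 = single_guide_design.guides[0]
    g2 = GuideRNA(
        revcomp(amp[150:170]), revcomp(amp[147:150]), 150, "-", name="gRev"
    )
    return AmpliconDesign(amp, [g1, g2], name="dual")
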