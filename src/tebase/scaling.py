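"""Scaling per-site editing frequencies to genome-wide edited-loci counts.

For a guide whose target occurs ``copies`` times per haploid genome, a
measured target-nucleotide conversion frequency f corresponds to an
expected ``f × copies`` edited loci per haploid genome. Published counts
round this product for readability, so the rounding convention is an
explicit, recorded argument rather than a silent default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

ROUNDING_MODES = ("none", "nearest_10", "nearest_100", "sig3")


def _round_half_up(x: float) -> float:
    return math.floor(x + 0.5)


def round_to(value: float, mode: str) -> float:
    """Apply a named rounding convention (half rounds up)."""
    if mode == "none":
        return value
    if mode == "nearest_10":
        return _round_half_up(value / 10.0) * 10.0
    if mode == "nearest_100":
        return _round_half_up(value / 100.0) * 100.0
    if mode == "sig3":
        if value == 0:
            return 0.0
        digits = 2 - math.floor(math.log10(abs(value)))
        return _round_half_up(value * 10**digits) / 10**digits
    raise ValueError(f"unknown rounding mode {mode!r}; use {ROUNDING_MODES}")


@dataclass
class EditScale:
    frequency: float
    copies: float
    estimated_loci: float
    rounding: str
    reported_loci: float


def estimate_edited_loci(
    frequency: float, copies: float, rounding: str = "none"
) -> EditScale:
    """Expected edited loci = conversion frequency × target copy number."""
    if not 0.0 <= frequency <= 1.0:
        raise ValueError("frequency must be in [0, 1]")
    if copies <= 0:
        raise ValueError("copies must be positive")
    loci = frequency * copies
    return EditScale(
        frequency=frequency,
        copies=copies,
        estimated_loci=loci,
        rounding=rounding,
        reported_loci=round_to(loci, rounding),
    )


def fold_change(a: float, b: float) -> float:
    """Ratio a/b reported to two decimals (e.g. an nBE/dBE efficiency drop)."""
    if b <= 0 or a <= 0:
        raise ValueError("fold change requires positive inputs")
    return round(a / b, 2)


def edited_fraction(edited_loci: float, total_copies: float) -> float:
    """Percentage of target copies edited, to three significant figures."""
    if total_copies <= 0:
        raise ValueError("total_copies must be positive")
    if not 0 <= edited_loci <= total_copies:
        raise ValueError("edited_loci must lie in [0, total_copies]")
    return round_to(100.0 * edited_loci / total_copies, "sig3")
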