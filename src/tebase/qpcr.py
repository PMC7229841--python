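"""qPCR relative copy-number estimation for repetitive targets.

A repetitive element amplified with consensus primers reaches threshold
earlier than a single-copy control locus; under the efficiency-corrected
ΔCt model the abundance ratio is ``E ** (Ct_reference − Ct_target)``
with E the per-cycle amplification factor (2.0 at 100% efficiency).
Replicates are averaged on the Ct (log) scale, the convention for ΔCt
analysis. Copies are reported per haploid genome; multiplying by ploidy
gives the per-cell count, kept as metadata for cells such as the largely
triploid HEK 293T line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass
class CopyNumberEstimate:
    element: str
    copies_per_haploid: float
    copies_per_cell: float
    ploidy: float
    efficiency: float
    ct_target_mean: float = float("nan")
    ct_target_sd: float = float("nan")
    ct_reference_mean: float = float("nan")


def estimate_copy_number(
    ct_target: float,
    ct_reference: float,
    efficiency: float = 2.0,
    reference_copies: float = 1.0,
) -> float:
    """Copies per haploid genome from mean Ct values.

    ``reference_copies`` rescales when the control locus is not single
    copy. Raises on non-finite Cts or efficiency outside (1, 2].
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_reference)):
        raise ValueError("Ct values must be finite")
    if not 1.0 < efficiency <= 2.0:
        raise ValueError("efficiency must be in (1, 2]")
    return reference_copies * efficiency ** (ct_reference - ct_target)


def per_cell_copies(copies_per_haploid: float, ploidy: float) -> float:
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    return copies_per_haploid * ploidy


def aggregate_replicates(measurements: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of Ct per (sample, primer_pair), on the Ct scale.

    Expects columns ``sample``, ``primer_pair``, ``ct`` (and optionally
    ``replicate``); SD is the population-style pandas default (ddof=1),
    reported as 0 for a single replicate.
    """
    if (measurements["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    g = measurements.groupby(["sample", "primer_pair"], sort=True)["ct"]
    out = g.agg(ct_mean="mean", ct_sd="std", n_replicates="count")
    out["ct_sd"] = out["ct_sd"].fillna(0.0)
    return out.reset_index()


def estimate_from_table(
    measurements: pd.DataFrame,
    reference_primer: str,
    efficiency: float = 2.0,
    ploidy: float = 1.0,
    reference_copies: float = 1.0,
) -> pd.DataFrame:
    """Copy-number estimates for every non-reference primer pair.

    One estimate per (sample, primer_pair), each sample normalised to its
    own reference-primer mean Ct.
    """
    agg = aggregate_replicates(measurements)
    ref = agg[agg["primer_pair"] == reference_primer].set_index("sample")
    if ref.empty:
        raise ValueError(
            f"reference primer {reference_primer!r} not found in table"
        )
    rows = []
    for _, row in agg[agg["primer_pair"] != reference_primer].iterrows():
        sample = row["sample"]
        if sample not in ref.index:
            continue
        ct_ref = float(ref.loc[sample, "ct_mean"])
        cph = estimate_copy_number(
            row["ct_mean"], ct_ref, efficiency, reference_copies
        )
        rows.append(
            {
                "sample": sample,
                "element": row["primer_pair"],
                "copies_per_haploid": cph,
                "copies_per_cell": per_cell_copies(cph, ploidy),
                "ploidy": ploidy,
                "efficiency": efficiency,
                "ct_target_mean": row["ct_mean"],
                "ct_target_sd": row["ct_sd"],
                "ct_reference_mean": ct_ref,
            }
        )
    return pd.DataFrame(rows)
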