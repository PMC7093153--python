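"""Steady-state {1H}-15N heteronuclear NOE and backbone-flexibility summaries.

The heteronuclear NOE of a backbone amide is the intensity ratio
``I_sat / I_ref`` between spectra acquired with and without proton
presaturation.  Values near the rigid-limit (~0.8 at high field) indicate
restricted ps-ns motion; values well below ~0.4-0.5 indicate the fast
backbone dynamics typical of disordered chains, and negative values
indicate extreme flexibility.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .shift_io import IntensityTable

__all__ = ["NoeRecord", "FlexibilitySummary", "compute_noe", "summarize_flexibility"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NoeRecord:
    residue_index: int
    i_sat: float
    i_ref: float
    noe: float
    valid: bool = True


@dataclass
class FlexibilitySummary:
    mean_noe: float
    region_means: list[tuple[int, int, float]]
    n_below_threshold: int
    threshold: float
    n_residues: int


def _single_condition(table: IntensityTable, name: str) -> dict[int, float]:
    if len(table.condition_labels) != 1:
        raise ValueError(f"{name} table must hold exactly one condition")
    return {idx: vals[0] for idx, vals in table.values.items()}


def compute_noe(sat: IntensityTable, ref: IntensityTable) -> list[NoeRecord]:
    """Per-residue NOE = I_sat / I_ref over residues present in both tables.

    Residues missing from either table are omitted (logged); residues with
    a non-positive reference intensity are returned flagged invalid and are
    excluded from summaries.
    """
    i_sat = _single_condition(sat, "saturated")
    i_ref = _single_condition(ref, "reference")
    common = sorted(set(i_sat) & set(i_ref))
    skipped = sorted(set(i_sat) ^ set(i_ref))
    if skipped:
        logger.info("NOE: %d residues present in only one table, omitted", len(skipped))
    records: list[NoeRecord] = []
    for idx in common:
        s, r = i_sat[idx], i_ref[idx]
        if math.isnan(s) or math.isnan(r):
            continue
        if r <= 0:
            records.append(NoeRecord(idx, s, r, math.nan, valid=False))
            continue
        records.append(NoeRecord(idx, s, r, s / r))
    return records


def summarize_flexibility(
    records: Sequence[NoeRecord],
    regions: Iterable[tuple[int, int]] = (),
    threshold: float = 0.44,
) -> FlexibilitySummary:
    """Protein-wide and per-region mean NOE plus a sub-threshold count.

    ``threshold`` is a reporting threshold for flagging flexible residues,
    not a classifier. Regions with no evaluable residue get a NaN mean.
    """
    valid = [r for r in records if r.valid]
    if not valid:
        raise ValueError("no evaluable NOE records")
    values = {r.residue_index: r.noe for r in valid}
    mean = sum(values.values()) / len(values)
    region_means: list[tuple[int, int, float]] = []
    for start, end in regions:
        inside = [v for i, v in values.items() if start <= i <= end]
        region_means.append(
            (start, end, sum(inside) / len(inside) if inside else math.nan)
        )
    return FlexibilitySummary(
        mean_noe=mean,
        region_means=region_means,
        n_below_threshold=sum(1 for v in values.values() if v < threshold),
        threshold=threshold,
        n_residues=len(values),
    )
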