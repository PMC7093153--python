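"""Titration-series attenuation binning and interaction-site delineation.

When a small disordered protein binds a large, multimeric partner in fast
exchange, the residues at the interface lose HSQC peak intensity rather
than shifting: the bound state is broadened beyond detection.  Mapping the
per-residue intensity ratio (with ligand vs. without) along the sequence
therefore paints the binding footprint.  Residues are binned by their
signal reduction at a fixed reference titration point (default the first
substoichiometric point, ligand ratio 1:0.25):

* ``red``     reduction > 80 %
* ``yellow``  60 % < reduction <= 80 %
* ``green``   40 % <= reduction <= 60 %
* ``minimal`` reduction < 40 %

An interaction site is a contiguous run of attenuated residues (any of
green/yellow/red) containing at least one red residue; short stretches of
non-evaluable or minimal residues (prolines, unassigned, overlapped peaks)
may be bridged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .shift_io import IntensityTable, ShiftTable

__all__ = [
    "AttenuationProfile",
    "InteractionSite",
    "CspProfile",
    "intensity_ratios",
    "delineate_sites",
    "csp",
]

logger = logging.getLogger(__name__)

ATTENUATED_BINS = frozenset({"green", "yellow", "red"})


def bin_for_reduction(reduction_pct: float) -> str:
    """Map a percent signal reduction to its attenuation bin."""
    if reduction_pct > 80:
        return "red"
    if reduction_pct > 60:
        return "yellow"
    if reduction_pct >= 40:
        return "green"
    return "minimal"


@dataclass
class AttenuationProfile:
    """Per-residue titration ratios and attenuation bins.

    ``ratios[i]`` holds I(i, c)/I(i, zero) for every condition; ``bins`` are
    assigned from the reduction at ``reference_label`` only, clipped to
    [0, 100] %.
    """

    condition_labels: list[str]
    reference_label: str
    ratios: dict[int, list[float]]
    reduction_pct: dict[int, float]
    bins: dict[int, str]

    def residue_indices(self) -> list[int]:
        return sorted(self.bins)


@dataclass(frozen=True)
class InteractionSite:
    start: int
    end: int
    n_red: int
    n_yellow: int
    n_green: int
    label: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CspProfile:
    """Combined 1H/15N chemical-shift perturbations per residue and point."""

    condition_labels: list[str]
    d_h: dict[int, list[float]]
    d_n: dict[int, list[float]]
    csp: dict[int, list[float]]
    w_n: float


def intensity_ratios(
    series: IntensityTable,
    zero_label: str | None = None,
    reference_label: str | None = None,
) -> AttenuationProfile:
    """Compute intensity ratios against the zero-ligand condition and bin them.

    ``zero_label`` defaults to the first condition; ``reference_label`` (the
    point at which bins are assigned) defaults to the first non-zero point.
    Residues whose status is not ``assigned``, or whose zero-ligand
    intensity is non-positive, are ``not_evaluable``.
    """
    labels = series.condition_labels
    if zero_label is None:
        zero_label = labels[0]
    if zero_label not in labels:
        raise ValueError(f"zero-ligand condition {zero_label!r} not in series")
    if reference_label is None:
        non_zero = [c for c in labels if c != zero_label]
        if not non_zero:
            raise ValueError("series has no non-zero titration point")
        reference_label = non_zero[0]
    if reference_label not in labels:
        raise ValueError(f"reference condition {reference_label!r} not in series")
    i_zero = labels.index(zero_label)
    i_ref = labels.index(reference_label)

    ratios: dict[int, list[float]] = {}
    reduction: dict[int, float] = {}
    bins: dict[int, str] = {}
    for idx, vals in series.values.items():
        status = series.status.get(idx, "assigned")
        v0 = vals[i_zero]
        if status != "assigned" or math.isnan(v0) or v0 <= 0:
            if status == "assigned" and not math.isnan(v0) and v0 <= 0:
                logger.warning("residue %d: non-positive zero-ligand intensity", idx)
            ratios[idx] = [math.nan] * len(labels)
            reduction[idx] = math.nan
            bins[idx] = "not_evaluable"
            continue
        r = [v / v0 if not math.isnan(v) else math.nan for v in vals]
        ratios[idx] = r
        red = (1.0 - r[i_ref]) * 100.0 if not math.isnan(r[i_ref]) else math.nan
        if math.isnan(red):
            reduction[idx] = math.nan
            bins[idx] = "not_evaluable"
            continue
        red = min(max(red, 0.0), 100.0)
        reduction[idx] = red
        bins[idx] = bin_for_reduction(red)
    return AttenuationProfile(
        condition_labels=list(labels),
        reference_label=reference_label,
        ratios=ratios,
        reduction_pct=reduction,
        bins=bins,
    )


def delineate_sites(profile: AttenuationProfile, max_gap: int = 3) -> list[InteractionSite]:
    """Delineate contiguous interaction sites from an attenuation profile.

    A site is a maximal run of attenuated residues (bins green/yellow/red)
    in which up to ``max_gap`` consecutive minimal or not-evaluable residues
    are bridged when attenuated residues resume after them. Runs without a
    red residue are discarded; boundaries are trimmed to the outermost
    attenuated residues.
    """
    indices = profile.residue_indices()
    if indices and indices != list(range(indices[0], indices[-1] + 1)):
        raise ValueError("profile must cover a contiguous residue range")
    attenuated = [i for i in indices if profile.bins[i] in ATTENUATED_BINS]
    sites: list[InteractionSite] = []
    group: list[int] = []

    def flush(group: list[int]) -> None:
        if not group:
            return
        members = [i for i in range(group[0], group[-1] + 1)]
        counts = {"red": 0, "yellow": 0, "green": 0}
        for i in members:
            b = profile.bins[i]
            if b in counts:
                counts[b] += 1
        if counts["red"] >= 1:
            sites.append(
                InteractionSite(
                    start=group[0],
                    end=group[-1],
                    n_red=counts["red"],
                    n_yellow=counts["yellow"],
                    n_green=counts["green"],
                )
            )

    for i in attenuated:
        if group and i - group[-1] - 1 > max_gap:
            flush(group)
            group = []
        group.append(i)
    flush(group)
    for k, site in enumerate(sites):
        sites[k] = InteractionSite(
            site.start, site.end, site.n_red, site.n_yellow, site.n_green,
            label=f"Site {k + 1}",
        )
    return sites


def csp(
    shift_tables: Sequence[ShiftTable],
    condition_labels: Sequence[str] | None = None,
    w_n: float = 0.14,
) -> CspProfile:
    """Combined 1H/15N chemical-shift perturbation per residue per point.

    The first table is the zero-ligand reference. For each later point,
    ``csp = sqrt(dd_H**2 + (w_n * dd_N)**2)`` with dd relative to the
    reference; 15N shifts are down-weighted by ``w_n`` (default 0.14, a
    common convention reflecting the relative shift dispersion of the two
    nuclei). Residues missing at a point get NaN there.
    """
    if len(shift_tables) < 2:
        raise ValueError("need the zero-ligand table plus at least one titration point")
    if condition_labels is None:
        condition_labels = [f"point{i}" for i in range(len(shift_tables))]
    if len(condition_labels) != len(shift_tables):
        raise ValueError("one condition label per shift table required")
    ref = shift_tables[0]
    ref_h = {r.residue_index: r.shift for r in ref.records if r.atom == "H"}
    ref_n = {r.residue_index: r.shift for r in ref.records if r.atom == "N"}
    residues = sorted(set(ref_h) & set(ref_n))
    n_points = len(shift_tables) - 1
    d_h = {i: [math.nan] * n_points for i in residues}
    d_n = {i: [math.nan] * n_points for i in residues}
    combined = {i: [math.nan] * n_points for i in residues}
    for p, table in enumerate(shift_tables[1:]):
        cur_h = {r.residue_index: r.shift for r in table.records if r.atom == "H"}
        cur_n = {r.residue_index: r.shift for r in table.records if r.atom == "N"}
        for i in residues:
            if i in cur_h and i in cur_n:
                dh = cur_h[i] - ref_h[i]
                dn = cur_n[i] - ref_n[i]
                d_h[i][p] = dh
                d_n[i][p] = dn
                combined[i][p] = math.sqrt(dh * dh + (w_n * dn) ** 2)
    return CspProfile(
        condition_labels=list(condition_labels[1:]),
        d_h=d_h,
        d_n=d_n,
        csp=combined,
        w_n=w_n,
    )
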