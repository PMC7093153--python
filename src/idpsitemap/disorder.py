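"""Secondary-chemical-shift disorder analysis and a CD disorder heuristic.

The secondary chemical shift of a residue is the deviation of its observed
13C shift from the random-coil value for that residue type,
``dd_X(i) = d_obs(i, X) - rc(type(i), X)`` for X in {CA, CB, CO}.  In a
fully disordered chain these deviations scatter around zero; systematic
positive dd_CA/dd_CO with negative dd_CB indicates transient helix, the
opposite signs indicate transient strand.  A residue is called coil when
every available deviation lies within a residue-class-dependent window
(|dd| <= 0.7 ppm for CA/CB and <= 0.5 ppm for CO of non-proline residues;
|dd| <= 4 ppm for all three carbons of prolines, whose shifts are strongly
perturbed by cis/trans isomerism).  Candidate structured elements are
maximal runs of at least ``min_run`` consecutive residues sharing the same
out-of-window sign pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .shift_io import AA1, ShiftTable

__all__ = [
    "RandomCoilTable",
    "ClassificationRanges",
    "SecondaryShiftProfile",
    "ResidueCall",
    "StructuredRun",
    "CdSpectrum",
    "secondary_shifts",
    "classify_residues",
    "detect_structured_runs",
    "cd_disorder_heuristic",
]

C_ATOMS = ("CA", "CB", "CO")


@dataclass(frozen=True)
class RandomCoilTable:
    """Random-coil 13C reference shifts, complete for all 20 residue types.

    Glycine has no CB; its entry is ``None`` (marked not-applicable).
    """

    values: Mapping[tuple[str, str], float | None]

    def __post_init__(self) -> None:
        for aa in AA1:
            for atom in C_ATOMS:
                if (aa, atom) not in self.values:
                    raise ValueError(f"random-coil table incomplete: missing ({aa}, {atom})")

    def get(self, residue_type: str, atom: str) -> float | None:
        try:
            return self.values[(residue_type, atom)]
        except KeyError:
            raise ValueError(
                f"residue type {residue_type!r} / atom {atom!r} absent from random-coil table"
            ) from None

    @classmethod
    def bundled(cls) -> "RandomCoilTable":
        """Load the packaged Wishart-style reference table."""
        text = (
            resources.files("idpsitemap")
            .joinpath("data/random_coil_wishart.tsv")
            .read_text()
        )
        values: dict[tuple[str, str], float | None] = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].rstrip()
            if not line or line.startswith("residue"):
                continue
            fields = line.split("\t")
            aa = fields[0]
            for atom, raw in zip(C_ATOMS, fields[1:4]):
                values[(aa, atom)] = float(raw) if raw.strip() else None
        return cls(values=values)

    @classmethod
    def from_tsv(cls, text: str) -> "RandomCoilTable":
        values: dict[tuple[str, str], float | None] = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].rstrip()
            if not line or line.startswith("residue"):
                continue
            fields = line.split("\t")
            for atom, raw in zip(C_ATOMS, fields[1:4]):
                values[(fields[0], atom)] = float(raw) if raw.strip() else None
        return cls(values=values)


@dataclass(frozen=True)
class ClassificationRanges:
    """Half-widths of the coil windows, in ppm."""

    ca: float = 0.7
    cb: float = 0.7
    co: float = 0.5
    proline: float = 4.0

    def for_residue(self, is_proline: bool) -> dict[str, float]:
        if is_proline:
            return {"CA": self.proline, "CB": self.proline, "CO": self.proline}
        return {"CA": self.ca, "CB": self.cb, "CO": self.co}


@dataclass
class SecondaryShiftProfile:
    """Per-residue secondary chemical shifts (NaN where unobserved)."""

    residue_indices: list[int]
    dca: dict[int, float]
    dcb: dict[int, float]
    dco: dict[int, float]
    is_proline: dict[int, bool]

    def deltas(self, idx: int) -> dict[str, float]:
        return {"CA": self.dca[idx], "CB": self.dcb[idx], "CO": self.dco[idx]}


@dataclass(frozen=True)
class ResidueCall:
    residue_index: int
    call: str  # coil | helix_indicating | strand_indicating | insufficient_data
    conflict: bool = False


@dataclass(frozen=True)
class StructuredRun:
    start: int
    end: int
    kind: str  # helix_like | strand_like

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CdSpectrum:
    """Far-UV CD spectrum: strictly increasing wavelengths (nm) and signal."""

    wavelength: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.wavelength.ndim != 1 or self.wavelength.shape != self.signal.shape:
            raise ValueError("wavelength and signal must be matching 1-D arrays")
        if not np.all(np.diff(self.wavelength) > 0):
            raise ValueError("wavelengths must be strictly increasing")


def secondary_shifts(table: ShiftTable, rc: RandomCoilTable) -> SecondaryShiftProfile:
    """Compute dd = observed - random-coil for CA, CB and CO of every residue.

    Requires a sequence-bound table. Residues with no observed shift for an
    atom get NaN; glycine CB is not applicable and is NaN by construction.
    """
    if table.sequence is None:
        raise ValueError("shift table must have an attached sequence")
    seq = table.sequence
    obs: dict[tuple[int, str], float] = {
        (r.residue_index, r.atom): r.shift for r in table.records
    }
    indices = list(range(seq.first_index, seq.last_index + 1))
    out = {atom: {} for atom in C_ATOMS}
    is_pro: dict[int, bool] = {}
    for i in indices:
        aa = seq.residue_type(i)
        is_pro[i] = aa == "P"
        for atom in C_ATOMS:
            ref = rc.get(aa, atom)
            val = obs.get((i, atom))
            if ref is None or val is None:
                out[atom][i] = math.nan
            else:
                out[atom][i] = val - ref
    return SecondaryShiftProfile(
        residue_indices=indices,
        dca=out["CA"],
        dcb=out["CB"],
        dco=out["CO"],
        is_proline=is_pro,
    )


def _indications(deltas: Mapping[str, float], ranges: Mapping[str, float]) -> tuple[bool, bool]:
    """Return (helix evidence, strand evidence) from available deviations."""
    helix = strand = False
    dca, dcb, dco = deltas["CA"], deltas["CB"], deltas["CO"]
    if not math.isnan(dca):
        helix |= dca > ranges["CA"]
        strand |= dca < -ranges["CA"]
    if not math.isnan(dco):
        helix |= dco > ranges["CO"]
        strand |= dco < -ranges["CO"]
    if not math.isnan(dcb):
        helix |= dcb < -ranges["CB"]
        strand |= dcb > ranges["CB"]
    return helix, strand


def classify_residues(
    profile: SecondaryShiftProfile,
    ranges: ClassificationRanges | None = None,
) -> list[ResidueCall]:
    """Classify each residue as coil, helix- or strand-indicating.

    A residue with no observed 13C shift at all is ``insufficient_data``;
    conflicting helix and strand evidence within one residue is resolved
    conservatively to coil with ``conflict=True``.
    """
    ranges = ranges or ClassificationRanges()
    calls: list[ResidueCall] = []
    for i in profile.residue_indices:
        deltas = profile.deltas(i)
        if all(math.isnan(v) for v in deltas.values()):
            calls.append(ResidueCall(i, "insufficient_data"))
            continue
        r = ranges.for_residue(profile.is_proline[i])
        helix, strand = _indications(deltas, r)
        if helix and strand:
            calls.append(ResidueCall(i, "coil", conflict=True))
        elif helix:
            calls.append(ResidueCall(i, "helix_indicating"))
        elif strand:
            calls.append(ResidueCall(i, "strand_indicating"))
        else:
            calls.append(ResidueCall(i, "coil"))
    return calls


def detect_structured_runs(
    calls: Sequence[ResidueCall], min_run: int = 3
) -> list[StructuredRun]:
    """Find maximal runs of >= ``min_run`` consecutive same-kind residues.

    Residues with insufficient data (or any other call) break runs; calls
    must be ordered by residue index and contiguous.
    """
    kind_of = {"helix_indicating": "helix_like", "strand_indicating": "strand_like"}
    runs: list[StructuredRun] = []
    cur_kind: str | None = None
    cur_start = cur_end = 0
    def flush() -> None:
        if cur_kind is not None and cur_end - cur_start + 1 >= min_run:
            runs.append(StructuredRun(cur_start, cur_end, cur_kind))
    prev_idx: int | None = None
    for call in calls:
        contiguous = prev_idx is None or call.residue_index == prev_idx + 1
        kind = kind_of.get(call.call)
        if kind is not None and kind == cur_kind and contiguous:
            cur_end = call.residue_index
        else:
            flush()
            cur_kind = kind
            cur_start = cur_end = call.residue_index
        prev_idx = call.residue_index
    flush()
    return runs


def cd_disorder_heuristic(
    spectrum: CdSpectrum,
) -> tuple[bool, dict]:
    """Flag a far-UV CD spectrum as disorder-like.

    A disordered chain shows a single negative trough near 200 nm and no
    negative local minima above 210 nm (where helix/strand bands appear).
    The spectrum is smoothed with a 3-point moving average before minima
    are located; local minima are interior points lower than both
    neighbors. Returns ``(flag, features)`` where features carry the
    global-minimum wavelength and the negative local minima above 210 nm.
    """
    wl, sig = spectrum.wavelength, spectrum.signal
    if len(wl) < 20 or wl[0] > 195 or wl[-1] < 250:
        raise ValueError("spectrum must have >= 20 points spanning at least 195-250 nm")
    smooth = sig.copy()
    smooth[1:-1] = (sig[:-2] + sig[1:-1] + sig[2:]) / 3.0
    gmin = int(np.argmin(smooth))
    gmin_wl = float(wl[gmin])
    gmin_val = float(smooth[gmin])
    interior = np.arange(1, len(wl) - 1)
    is_min = (smooth[interior] < smooth[interior - 1]) & (smooth[interior] < smooth[interior + 1])
    local_minima = [
        (float(wl[i]), float(smooth[i]))
        for i in interior[is_min]
        if wl[i] > 210 and smooth[i] < 0
    ]
    flag = (195.0 <= gmin_wl <= 205.0) and gmin_val < 0 and not local_minima
    features = {
        "global_min_wavelength": gmin_wl,
        "global_min_signal": gmin_val,
        "local_minima_above_210": local_minima,
    }
    return flag, features
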