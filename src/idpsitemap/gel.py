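"""Gel densitometry quantification for strand-exchange and EMSA assays.

Three-strand exchange reactions are resolved on agarose gels into the
linear double-stranded substrate (lds), three-stranded joint-molecule
intermediates (JM) and nicked-circular products (NC).  Per-lane band
signals are background-subtracted; the JM signal is divided by 1.5 to
compensate for the extra staining of a three-stranded molecule; the
corrected lds + JM + NC signals are normalized to 100 %, and the total
yield is %JM + %NC.  The circular single-stranded substrate (css) does not
enter the normalization.

EMSA lanes are quantified as the band signal minus a blank-lane
background, normalized by the total lane signal, and expressed relative to
the no-protein control lane (set to 100 % unbound DNA).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

__all__ = ["LaneQuantification", "strand_exchange_yields", "emsa_unbound"]

BANDS = ("lds", "jm", "nc")


@dataclass
class LaneQuantification:
    raw: dict[str, float]
    background: dict[str, float]
    corrected: dict[str, float]
    jm_divisor: float
    pct_lds: float
    pct_jm: float
    pct_nc: float

    @property
    def total_yield(self) -> float:
        return self.pct_jm + self.pct_nc


def _norm_band(name: str) -> str:
    key = name.strip().lower()
    if key not in BANDS:
        raise ValueError(f"unknown band {name!r}; expected one of {BANDS}")
    return key


def strand_exchange_yields(
    raw: Mapping[str, float],
    background: Mapping[str, float] | None = None,
    jm_divisor: float = 1.5,
) -> LaneQuantification:
    """Convert raw lds/JM/NC band signals into percentage yields.

    ``corrected(band) = max(raw - background, 0)``; the JM value is divided
    by ``jm_divisor`` and the three corrected signals are normalized to sum
    to 100 %. A lane whose corrected signals all vanish is an error.
    """
    raw_n = {_norm_band(k): float(v) for k, v in raw.items()}
    bg_n = {_norm_band(k): float(v) for k, v in (background or {}).items()}
    for band in BANDS:
        raw_n.setdefault(band, 0.0)
        bg_n.setdefault(band, 0.0)
        if raw_n[band] < 0 or bg_n[band] < 0:
            raise ValueError(f"negative signal for band {band!r}")
    corrected: dict[str, float] = {}
    for band in BANDS:
        value = raw_n[band] - bg_n[band]
        if value < 0:
            warnings.warn(
                f"background exceeds raw signal for band {band!r}; clipping to 0"
            )
            value = 0.0
        corrected[band] = value
    corrected["jm"] /= jm_divisor
    total = sum(corrected.values())
    if total <= 0:
        raise ValueError("empty lane: corrected signals sum to zero")
    pct = {band: 100.0 * corrected[band] / total for band in BANDS}
    return LaneQuantification(
        raw=raw_n,
        background=bg_n,
        corrected=corrected,
        jm_divisor=jm_divisor,
        pct_lds=pct["lds"],
        pct_jm=pct["jm"],
        pct_nc=pct["nc"],
    )


def emsa_unbound(
    band_signal: float,
    blank_background: float,
    total_lane_signal: float,
    control_band_signal: float,
    control_blank_background: float,
    control_total_lane_signal: float,
) -> float:
    """Unbound-DNA percentage relative to the no-protein control lane.

    Both lanes are quantified identically: (band - blank background) /
    total lane signal; the sample value is expressed relative to the
    control value, which defines 100 % unbound DNA.
    """
    if total_lane_signal <= 0 or control_total_lane_signal <= 0:
        raise ValueError("total lane signal must be positive")
    lane_frac = (band_signal - blank_background) / total_lane_signal
    ctrl_frac = (control_band_signal - control_blank_background) / control_total_lane_signal
    if ctrl_frac <= 0:
        raise ValueError("control lane has non-positive normalized signal")
    return 100.0 * lane_frac / ctrl_frac
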