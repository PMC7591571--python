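"""Per-plate normalization (InH %) and plate quality control (Z' factor).

The inhibition rate normalizes a well's luminescence between the two
control populations of its own plate:

    InH (%) = 100 * (1 - (sample - mean_p) / (mean_n - mean_p))

where mean_p is the mean of the positive controls (DMSO only, no JH ->
baseline signal) and mean_n the mean of the negative controls (1 nM JH I ->
full signal). InH is 0 at the negative-control mean, 100 at the
positive-control mean, may exceed 100 (super-maximal inhibition) and is
negative for activation. Plate quality is summarized by the Z' factor

    Z' = 1 - (3*SD_p + 3*SD_n) / |mean_n - mean_p|

which is 1 for noiseless, well-separated controls and degrades as control
variability eats into the separation band.

Normalization is strictly per plate and per channel: every compound well is
scored against the control summary of the plate it sits on; replicate wells
are normalized first and averaged afterwards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .plate_io import (
    ROLE_COMPOUND,
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
    Plate,
    PlateLayout,
)

__all__ = [
    "ControlSummary",
    "InhibitionResult",
    "PlateQC",
    "ReplicateSummary",
    "InsufficientControlsError",
    "DegenerateSeparationError",
    "summarize_controls",
    "inhibition_rate",
    "viability_inhibition",
    "z_prime",
    "plate_qc",
    "plate_inhibition",
    "plate_viability_inhibition",
    "aggregate_replicates",
]

CHANNELS = ("fluc", "rluc")


class InsufficientControlsError(ValueError):
    """Fewer than the required valid control wells on a plate."""


class DegenerateSeparationError(ValueError):
    """Control means coincide; normalization is undefined."""


@dataclass(frozen=True)
class ControlSummary:
    """Per-plate, per-channel control statistics (sample SD, n-1)."""

    channel: str
    mean_p: float
    mean_n: float
    sd_p: float
    sd_n: float
    n_p: int
    n_n: int


@dataclass
class InhibitionResult:
    """InH values for one compound at one concentration on one channel."""

    compound_id: str
    conc: float
    channel: str
    values: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> Optional[float]:
        if len(self.values) < 2:
            return None
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class PlateQC:
    plate_id: str
    channel: str
    summary: ControlSummary
    z_prime: float
    pass_flag: bool


@dataclass(frozen=True)
class ReplicateSummary:
    mean: float
    sd: Optional[float]
    n: int
    shortfall: bool


def _channel_value(well, channel: str) -> float:
    if channel not in CHANNELS:
        raise ValueError(f"unknown channel {channel!r}")
    return well.fluc if channel == "fluc" else well.rluc


def summarize_controls(plate: Plate, layout: PlateLayout, channel: str) -> ControlSummary:
    """Mean and sample SD of both control populations for one channel."""
    pos = [_channel_value(w, channel) for w in plate.wells_by_role(ROLE_POSITIVE)]
    neg = [_channel_value(w, channel) for w in plate.wells_by_role(ROLE_NEGATIVE)]
    if len(pos) < 2 or len(neg) < 2:
        raise InsufficientControlsError(
            f"plate {plate.plate_id}: need >=2 wells per control role, "
            f"got {len(pos)} positive / {len(neg)} negative"
        )
    return ControlSummary(
        channel=channel,
        mean_p=float(np.mean(pos)),
        mean_n=float(np.mean(neg)),
        sd_p=float(np.std(pos, ddof=1)),
        sd_n=float(np.std(neg, ddof=1)),
        n_p=len(pos),
        n_n=len(neg),
    )


def inhibition_rate(sample: float, summary: ControlSummary) -> float:
    """InH (%) of one luminescence reading against a control summary.

    Unbounded: 0 at mean_n, 100 at mean_p, negative for activation.
    """
    sep = summary.mean_n - summary.mean_p
    if sep == 0:
        raise DegenerateSeparationError("control means coincide (mean_n == mean_p)")
    return 100.0 * (1.0 - (sample - summary.mean_p) / sep)


def viability_inhibition(sample: float, control_mean: float) -> float:
    """Percent loss of a viability-reporter signal relative to controls.

    Used for the Rluc counterscreen, where both control populations are
    compound-free and therefore share the same expected Rluc level: 100%
    means complete signal loss, 0% means control-level viability.
    """
    if control_mean <= 0:
        raise DegenerateSeparationError("non-positive control Rluc mean")
    return 100.0 * (1.0 - sample / control_mean)


def z_prime(summary: ControlSummary) -> float:
    """Z' = 1 - (3*SD_p + 3*SD_n)/|mean_n - mean_p|; always <= 1."""
    sep = summary.mean_n - summary.mean_p
    if sep == 0:
        raise DegenerateSeparationError("control means coincide (mean_n == mean_p)")
    if sep < 0:
        warnings.warn(
            "mean_n < mean_p: controls are inverted relative to the expected "
            "JH-induced signal; using |mean_n - mean_p|",
            stacklevel=2,
        )
    return 1.0 - 3.0 * (summary.sd_p + summary.sd_n) / abs(sep)


def plate_qc(
    plate: Plate, layout: PlateLayout, channel: str = "fluc", z_min: float = 0.5
) -> PlateQC:
    summary = summarize_controls(plate, layout, channel)
    z = z_prime(summary)
    return PlateQC(
        plate_id=plate.plate_id,
        channel=channel,
        summary=summary,
        z_prime=z,
        pass_flag=z >= z_min,
    )


def plate_inhibition(
    plate: Plate, layout: PlateLayout, channel: str = "fluc"
) -> list[InhibitionResult]:
    """InH for every compound well, normalized to this plate's controls.

    Wells sharing (compound_id, conc) on the plate are collected as
    replicates of one result.
    """
    summary = summarize_controls(plate, layout, channel)
    grouped: dict[tuple[str, float], list[float]] = {}
    for w in plate.wells_by_role(ROLE_COMPOUND):
        if w.compound_id is None:
            continue
        key = (w.compound_id, w.conc)
        grouped.setdefault(key, []).append(
            inhibition_rate(_channel_value(w, channel), summary)
        )
    return [
        InhibitionResult(compound_id=cid, conc=conc, channel=channel, values=tuple(vals))
        for (cid, conc), vals in grouped.items()
    ]


def plate_viability_inhibition(plate: Plate, layout: PlateLayout) -> list[InhibitionResult]:
    """Rluc percent-loss for every compound well, against the pooled mean of
    all control wells (both roles are compound-free on the Rluc channel)."""
    controls = [
        w.rluc
        for w in plate.wells
        if w.role in (ROLE_POSITIVE, ROLE_NEGATIVE)
    ]
    if len(controls) < 2:
        raise InsufficientControlsError(
            f"plate {plate.plate_id}: need >=2 control wells for the Rluc reference"
        )
    ref = float(np.mean(controls))
    grouped: dict[tuple[str, float], list[float]] = {}
    for w in plate.wells_by_role(ROLE_COMPOUND):
        if w.compound_id is None:
            continue
        grouped.setdefault((w.compound_id, w.conc), []).append(
            viability_inhibition(w.rluc, ref)
        )
    return [
        InhibitionResult(compound_id=cid, conc=conc, channel="rluc", values=tuple(vals))
        for (cid, conc), vals in grouped.items()
    ]


def aggregate_replicates(values: Sequence[float], n_expected: int) -> ReplicateSummary:
    """Mean and sample SD of replicate InH values, flagging shortfalls."""
    values = list(values)
    if not values:
        raise ValueError("no replicate values to aggregate")
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else None
    return ReplicateSummary(
        mean=float(np.mean(values)),
        sd=sd,
        n=len(values),
        shortfall=len(values) < n_expected,
    )
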