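"""Relative gene expression by the 2^-ddCt method and dose-curve assembly.

The JH-inducible target gene (BmKr-h1) is quantified against a constitutive
reference (BmRp49) and a calibrator condition (JH alone, no inhibitor):

    relative expression = 2^-[(Ct_target - Ct_ref)_sample
                              - (Ct_target - Ct_ref)_calibrator]

PCR efficiency is fixed at 2 per cycle (no efficiency correction).
Replicates are averaged on the Ct scale before the ddCt by default; a
per-replicate mode (geometric-mean equivalent) is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dose_response import DoseResponseCurve

__all__ = [
    "QpcrMeasurement",
    "delta_delta_ct",
    "expression_dose_curve",
]


@dataclass(frozen=True)
class QpcrMeasurement:
    """One qPCR well pair: target and reference Ct under one condition."""

    sample_id: str
    ct_target: float
    ct_reference: float
    jh_conc: Optional[float] = None
    inhibitor_conc: Optional[float] = None
    replicate: int = 0

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if ct is None or not np.isfinite(ct) or ct <= 0:
                raise ValueError(f"{self.sample_id}: {name} must be positive and finite")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


def delta_delta_ct(sample: QpcrMeasurement, calibrator: QpcrMeasurement) -> float:
    """Relative expression of ``sample`` versus ``calibrator``: 2^-ddCt."""
    return float(2.0 ** -(sample.delta_ct - calibrator.delta_ct))


def expression_dose_curve(
    measurements: pd.DataFrame,
    calibrator_conc: float = 0.0,
    method: str = "ct_mean",
) -> DoseResponseCurve:
    """Relative-expression dose-response across inhibitor concentrations.

    ``measurements`` needs columns inhibitor_conc, replicate, ct_target,
    ct_reference (as written by the qPCR simulator). The calibrator is the
    ``calibrator_conc`` condition (JH alone by default). With
    ``method="ct_mean"`` replicate Cts are averaged per dose before the
    ddCt (one point per dose; per-replicate spread is reported as the SD);
    ``method="per_replicate"`` computes a ddCt per replicate and returns
    all points.
    """
    required = {"inhibitor_conc", "replicate", "ct_target", "ct_reference"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"missing qPCR column(s): {sorted(missing)}")
    cal = measurements[measurements["inhibitor_conc"] == calibrator_conc]
    if cal.empty:
        raise ValueError(
            f"calibrator condition (inhibitor_conc == {calibrator_conc:g}) absent"
        )
    cal_dct = float((cal["ct_target"] - cal["ct_reference"]).mean())

    doses, resp, sds, ns = [], [], [], []
    for conc, grp in measurements.groupby("inhibitor_conc", sort=True):
        dct = grp["ct_target"] - grp["ct_reference"]
        per_rep = 2.0 ** -(dct - cal_dct)
        n = len(grp)
        if n < 2:
            warnings.warn(
                f"single replicate at inhibitor_conc {conc:g}; SD unavailable",
                stacklevel=2,
            )
        if method == "ct_mean":
            doses.append(float(conc))
            resp.append(float(2.0 ** -(dct.mean() - cal_dct)))
            sds.append(float(per_rep.std(ddof=1)) if n >= 2 else np.nan)
            ns.append(n)
        elif method == "per_replicate":
            doses.extend([float(conc)] * n)
            resp.extend(per_rep.tolist())
            sds.extend([np.nan] * n)
            ns.extend([1] * n)
        else:
            raise ValueError(f"unknown method {method!r}")
    return DoseResponseCurve(
        concs=np.array(doses),
        responses=np.array(resp),
        response_kind="relative_expression",
        sd=np.array(sds),
        n=np.array(ns),
    )
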