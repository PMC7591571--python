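"""Competitive vs noncompetitive antagonist classification.

An inhibitor is profiled by measuring the JH I dose-response with and
without the compound. A noncompetitive antagonist depresses the maximal
response: the call is made by an equal-variance two-sided Student's t-test
comparing replicate responses at the top agonist dose (1e-6 M JH I) alone
versus with 0.5 uM inhibitor, significant at p < 0.001 with a reduced mean.
A competitive (surmountable) antagonist instead shifts the curve rightward
in parallel; that pattern is operationalized as a fitted EC50 dose ratio
(Gaddum shift, DR = 1 + [I]/Ki) of at least ``min_dose_ratio`` at the top
inhibitor concentration with a non-significant maximal-effect test.
Anything else is called indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .dose_response import (
    DoseResponseCurve,
    FitConvergenceError,
    FlatCurveError,
    FourPLFit,
    fit_4pl,
)

__all__ = [
    "AntagonistAssayData",
    "AntagonistCall",
    "EmaxTestResult",
    "emax_reduction_test",
    "dose_ratio",
    "classify_antagonist",
]

CALL_NONCOMPETITIVE = "noncompetitive"
CALL_COMPETITIVE = "competitive_like"
CALL_INDETERMINATE = "indeterminate"


@dataclass
class AntagonistAssayData:
    """Replicate responses over an agonist x inhibitor concentration grid.

    ``responses`` maps (agonist_conc, inhibitor_conc) to replicate arrays.
    Must include the inhibitor-free reference series and the maximal
    agonist dose in every series.
    """

    agonist_concs: tuple[float, ...]
    inhibitor_concs: tuple[float, ...]
    responses: dict[tuple[float, float], np.ndarray]
    compound_id: Optional[str] = None

    def __post_init__(self) -> None:
        if 0.0 not in self.inhibitor_concs:
            raise ValueError("assay must include the inhibitor-free reference series")
        top = max(self.agonist_concs)
        for inh in self.inhibitor_concs:
            if (top, inh) not in self.responses:
                raise ValueError(
                    f"missing maximal agonist dose for inhibitor conc {inh:g}"
                )
        self.responses = {
            k: np.asarray(v, dtype=float) for k, v in self.responses.items()
        }

    def series(self, inhibitor_conc: float) -> DoseResponseCurve:
        """Agonist dose-response (replicates flattened) at one inhibitor conc."""
        concs, resp = [], []
        for ag in self.agonist_concs:
            vals = self.responses.get((ag, inhibitor_conc))
            if vals is None:
                continue
            concs.extend([ag] * len(vals))
            resp.extend(vals.tolist())
        return DoseResponseCurve(
            concs=np.array(concs),
            responses=np.array(resp),
            response_kind="reporter_activity",
            compound_id=self.compound_id,
        )


@dataclass(frozen=True)
class EmaxTestResult:
    t_statistic: float
    p_value: float
    significant: bool
    mean_alone: float
    mean_with: float


@dataclass
class AntagonistCall:
    compound_id: Optional[str]
    call: str
    p_value: float
    dose_ratios: dict[float, float] = field(default_factory=dict)
    fits: dict[float, FourPLFit] = field(default_factory=dict)


def emax_reduction_test(
    resp_max_alone: Sequence[float],
    resp_max_with: Sequence[float],
    alpha: float = 0.001,
) -> EmaxTestResult:
    """Student's t-test (equal variances, two-sided) for a reduced maximal
    effect; significant only when p < alpha AND the treated mean is lower."""
    a = np.asarray(resp_max_alone, dtype=float)
    b = np.asarray(resp_max_with, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 replicates per group for the t-test")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):  # zero pooled variance
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:  # deterministic separation
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = 0.0
    significant = bool(p < alpha and b.mean() < a.mean())
    return EmaxTestResult(
        t_statistic=float(t),
        p_value=float(p),
        significant=significant,
        mean_alone=float(a.mean()),
        mean_with=float(b.mean()),
    )


def dose_ratio(fit_alone: FourPLFit, fit_with: FourPLFit) -> float:
    """EC50 fold-shift produced by the inhibitor (Gaddum: 1 + [I]/Ki for a
    purely competitive antagonist)."""
    for f in (fit_alone, fit_with):
        if not f.converged:
            raise FitConvergenceError("dose_ratio requires converged fits")
    return fit_with.ec50 / fit_alone.ec50


def classify_antagonist(
    data: AntagonistAssayData,
    alpha: float = 0.001,
    min_dose_ratio: float = 2.0,
) -> AntagonistCall:
    """Classify an inhibitor from the with/without-inhibitor JH curves.

    The maximal-effect test pairs the top agonist dose alone against the
    lowest nonzero inhibitor concentration (0.5 uM by default); dose ratios
    are estimated against the inhibitor-free fit for every nonzero
    inhibitor concentration, and the highest one drives the
    competitive_like call.
    """
    top_ag = max(data.agonist_concs)
    nonzero = sorted(c for c in data.inhibitor_concs if c > 0)
    if not nonzero:
        raise ValueError("no nonzero inhibitor concentrations in assay")
    test = emax_reduction_test(
        data.responses[(top_ag, 0.0)],
        data.responses[(top_ag, nonzero[0])],
        alpha=alpha,
    )

    fits: dict[float, FourPLFit] = {}
    ratios: dict[float, float] = {}
    try:
        fit0 = fit_4pl(data.series(0.0))
        fits[0.0] = fit0
    except (FlatCurveError, FitConvergenceError, ValueError):
        fit0 = None
    if fit0 is not None:
        for inh in nonzero:
            try:
                f = fit_4pl(data.series(inh))
            except (FlatCurveError, FitConvergenceError, ValueError):
                continue
            fits[inh] = f
            ratios[inh] = dose_ratio(fit0, f)

    if test.significant:
        call = CALL_NONCOMPETITIVE
    elif ratios and ratios[max(ratios)] >= min_dose_ratio:
        call = CALL_COMPETITIVE
    else:
        call = CALL_INDETERMINATE
    return AntagonistCall(
        compound_id=data.compound_id,
        call=call,
        p_value=test.p_value,
        dose_ratios=ratios,
        fits=fits,
    )
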