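"""Four-parameter logistic (4PL) dose-response fitting and EC50 extraction.

The model is the standard Hill/logistic curve

    R(c) = bottom + (top - bottom) / (1 + (ec50 / c)^hill)

fitted by nonlinear least squares with ec50 and hill optimized on the log10
scale (removes positivity constraints and makes the loss landscape well
behaved across decades of concentration). Luminescence-derived responses
carry multiplicative (constant-CV) measurement noise, so the default loss
weights residuals by the inverse model value (with a small floor to keep
near-zero asymptotes from dominating); ``weighting="absolute"`` gives the
plain unweighted fit. The response at c = ec50 is
exactly (bottom + top)/2, so the fitted ec50 parameter IS the half-maximal
concentration. Descending curves (e.g. relative expression falling with
inhibitor dose) are fitted in the same parameterization with the low- and
high-dose asymptotes swapping roles; the returned fit is canonicalized to
bottom <= top with a direction label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseCurve",
    "FourPLFit",
    "FlatCurveError",
    "FitConvergenceError",
    "four_pl",
    "fit_4pl",
    "estimate_ec50",
    "inhibition_ec50",
]

HILL_BOUNDS = (0.2, 5.0)
EC50_RANGE_DECADES = 2.0  # ec50 bounded within tested range * 10^+-2


class FlatCurveError(ValueError):
    """Responses carry no dose-dependent signal; a 4PL is unidentifiable."""


class FitConvergenceError(RuntimeError):
    """The optimizer did not converge; carries the best point found."""

    def __init__(self, message: str, best_fit: Optional["FourPLFit"] = None):
        super().__init__(message)
        self.best_fit = best_fit


@dataclass
class DoseResponseCurve:
    """Concentration/response pairs (replicates as repeated concentrations).

    ``concs`` are molar; a zero-dose point is allowed (it anchors the
    baseline initialization but is excluded from the log-concentration fit).
    ``sd``/``n`` optionally carry per-point summary info for display.
    """

    concs: np.ndarray
    responses: np.ndarray
    response_kind: str = "response"
    compound_id: Optional[str] = None
    sd: Optional[np.ndarray] = None
    n: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.concs = np.asarray(self.concs, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.concs.shape != self.responses.shape or self.concs.ndim != 1:
            raise ValueError("concs and responses must be 1-D and the same length")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")
        if np.any(self.concs < 0):
            raise ValueError("concentrations must be >= 0")

    @property
    def positive(self) -> tuple[np.ndarray, np.ndarray]:
        m = self.concs > 0
        return self.concs[m], self.responses[m]

    def dose_means(self) -> tuple[np.ndarray, np.ndarray]:
        c, y = self.positive
        doses = np.unique(c)
        means = np.array([y[c == d].mean() for d in doses])
        return doses, means


def four_pl(c, bottom: float, top: float, ec50: float, hill: float):
    """Evaluate the 4PL model (vectorized over c; c > 0)."""
    c = np.asarray(c, dtype=float)
    return bottom + (top - bottom) / (1.0 + (ec50 / c) ** hill)


@dataclass
class FourPLFit:
    """Canonicalized 4PL parameters: bottom <= top, hill > 0."""

    bottom: float
    top: float
    ec50: float
    hill: float
    rss: float
    converged: bool
    direction: str = "increasing"  # response rises or falls with dose
    n_points: int = 0
    se: Optional[dict] = None

    def predict(self, c):
        if self.direction == "increasing":
            return four_pl(c, self.bottom, self.top, self.ec50, self.hill)
        return four_pl(c, self.top, self.bottom, self.ec50, self.hill)


def _flat_check(curve: DoseResponseCurve) -> None:
    c, y = curve.positive
    if np.ptp(y) == 0:
        raise FlatCurveError("all responses are identical")
    doses, means = curve.dose_means()
    # with replicates, require the dose-mean span to rise above within-dose noise
    within = []
    for d in doses:
        vals = y[c == d]
        if len(vals) >= 2:
            within.append(np.var(vals, ddof=1))
    if within:
        pooled_sd = float(np.sqrt(np.mean(within)))
        if pooled_sd > 0 and np.ptp(means) < 3.0 * pooled_sd:
            raise FlatCurveError(
                "dose-mean span is indistinguishable from replicate noise"
            )


def fit_4pl(
    curve: DoseResponseCurve,
    weighting: str = "relative",
    max_nfev: int = 10000,
) -> FourPLFit:
    """Least-squares 4PL fit in (bottom, top, log10 ec50, log10 hill).

    Initialization: asymptotes from the lowest/highest dose means (a
    zero-dose mean, if present, overrides the baseline anchor); ec50 from
    the dose whose mean response is nearest midrange; hill = 1. Bounds:
    ec50 within the tested range +-2 decades, hill in [0.2, 5].
    ``weighting="relative"`` (default) divides residuals by
    |model| + 0.05 * mean|y|, matching constant-CV noise;
    ``"absolute"`` is the unweighted fit. The reported ``rss`` is always
    the unweighted residual sum of squares at the solution.
    """
    if weighting not in ("relative", "absolute"):
        raise ValueError(f"unknown weighting {weighting!r}")
    c, y = curve.positive
    if len(np.unique(c)) < 4:
        raise ValueError("need >=4 distinct positive concentrations for a 4PL fit")
    _flat_check(curve)
    doses, means = curve.dose_means()
    logc = np.log10(c)

    baseline = means[0]
    zero_mask = curve.concs == 0
    if np.any(zero_mask):
        baseline = float(curve.responses[zero_mask].mean())
    b0, t0 = baseline, means[-1]
    mid = 0.5 * (means.min() + means.max())
    ec50_0 = doses[int(np.argmin(np.abs(means - mid)))]

    lo = np.array([-np.inf, -np.inf, np.log10(c.min()) - EC50_RANGE_DECADES,
                   np.log10(HILL_BOUNDS[0])])
    hi = np.array([np.inf, np.inf, np.log10(c.max()) + EC50_RANGE_DECADES,
                   np.log10(HILL_BOUNDS[1])])
    x0 = np.array([b0, t0, np.clip(np.log10(ec50_0), lo[2], hi[2]), 0.0])

    floor = 0.05 * float(np.mean(np.abs(y))) if weighting == "relative" else 0.0

    def model(x):
        b, t, lec50, lhill = x
        h = 10.0 ** lhill
        return b + (t - b) / (1.0 + 10.0 ** ((lec50 - logc) * h))

    def resid(x):
        m = model(x)
        if weighting == "relative":
            return (m - y) / (np.abs(m) + floor)
        return m - y

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = least_squares(
            resid, x0, bounds=(lo, hi), method="trf",
            xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=max_nfev,
        )
    b, t, lec50, lhill = res.x
    rss = float(np.sum((model(res.x) - y) ** 2))

    se = None
    n = len(y)
    wrss = float(np.sum(res.fun ** 2))
    if res.success and n > 4 and wrss > 0:
        try:
            jtj = res.jac.T @ res.jac
            cov = np.linalg.inv(jtj) * wrss / (n - 4)
            se = dict(zip(("bottom", "top", "log10_ec50", "log10_hill"),
                          np.sqrt(np.diag(cov))))
        except np.linalg.LinAlgError:
            se = None

    direction = "increasing"
    bottom, top = float(b), float(t)
    if bottom > top:
        bottom, top = top, bottom
        direction = "decreasing"
    fit = FourPLFit(
        bottom=bottom,
        top=top,
        ec50=float(10.0 ** lec50),
        hill=float(10.0 ** lhill),
        rss=rss,
        converged=bool(res.success),
        direction=direction,
        n_points=n,
        se=se,
    )
    if not res.success:
        raise FitConvergenceError(
            f"4PL fit did not converge ({res.message})", best_fit=fit
        )
    return fit


def estimate_ec50(fit: FourPLFit) -> float:
    """Half-maximal concentration of a converged fit (molar)."""
    if not fit.converged:
        raise FitConvergenceError("cannot extract EC50 from a non-converged fit")
    return fit.ec50


def inhibition_ec50(curve: DoseResponseCurve) -> float:
    """Half-maximal inhibitor concentration from an InH-vs-dose (or relative
    expression-vs-dose) curve measured at fixed agonist concentration."""
    return estimate_ec50(fit_4pl(curve))
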