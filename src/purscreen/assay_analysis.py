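"""Reduction of pharmacological assay readouts.

Two computations: three-parameter logistic fits of concentration–response
curves (free bottom, top and log IC50; unit Hill slope), and percentage
inhibition/activation of fluorescence readouts with autofluorescence
correction.

The logistic model, with x = log10(concentration in molar), is

    response(x) = bottom + (top − bottom) / (1 + 10**(x − log_ic50))

which is the inhibition orientation: response falls from ``top`` toward
``bottom`` as the concentration sweeps past the IC50.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit


@dataclass
class DoseResponse:
    """A concentration–response curve; concentrations in molar.

    Concentration/response pairs are sorted by ascending concentration on
    construction.  ``replicate_sem`` optionally carries per-point SEMs from
    replicate wells (not used as fit weights by default).
    """

    concentrations: np.ndarray
    responses: np.ndarray
    replicate_sem: np.ndarray | None = None

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        resp = np.asarray(self.responses, dtype=float)
        if conc.shape != resp.shape:
            raise ValueError("concentrations and responses must have equal length")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive (molar)")
        order = np.argsort(conc)
        self.concentrations = conc[order]
        self.responses = resp[order]
        if self.replicate_sem is not None:
            self.replicate_sem = np.asarray(self.replicate_sem, dtype=float)[order]


@dataclass(frozen=True)
class LogisticFit:
    bottom: float
    top: float
    log_ic50: float  # log10 molar
    converged: bool

    @property
    def ic50(self) -> float:
        return 10.0 ** self.log_ic50

    def predict(self, concentrations) -> np.ndarray:
        x = np.log10(np.asarray(concentrations, dtype=float))
        return _logistic3(x, self.bottom, self.top, self.log_ic50)


class FitError(RuntimeError):
    """The curve cannot be fitted (too few points)."""


def _logistic3(x, bottom, top, log_ic50):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (x - log_ic50))


def fit_three_param_logistic(
    curve: DoseResponse, weighting: str = "none"
) -> LogisticFit:
    """Least-squares three-parameter logistic fit of a dose–response curve.

    Initialization takes bottom/top from the response extrema and log IC50
    from the concentration whose response is nearest the midpoint — a robust
    default for monotone sigmoidal data.  ``weighting="relative"`` weights
    residuals by 1/response² (σᵢ ∝ |yᵢ|), the appropriate scheme when the
    measurement error is a constant percentage of the signal, as is typical
    of fluorescence intensities; the default is ordinary unweighted least
    squares.  ``converged`` is False when the optimizer fails, the fitted
    curve is essentially flat, or the IC50 falls more than 10× outside the
    tested concentration range (the midpoint is then not determined by the
    data).
    """
    if weighting not in ("none", "relative"):
        raise ValueError(f"unknown weighting {weighting!r}")
    x = np.log10(curve.concentrations)
    yv = np.asarray(curve.responses, dtype=float)
    if len(np.unique(x)) < 4:
        raise FitError("at least 4 distinct concentrations are required")

    y_span = float(yv.max() - yv.min())
    mid = (yv.max() + yv.min()) / 2.0
    x0 = float(x[np.argmin(np.abs(yv - mid))])
    # orientation guess: falling curve ⇒ top is the low-concentration end
    falling = yv[0] >= yv[-1]
    p0 = (yv.min(), yv.max(), x0) if falling else (yv.max(), yv.min(), x0)

    sigma = None
    if weighting == "relative":
        # floor the weights so near-zero responses cannot dominate the fit
        sigma = np.maximum(np.abs(yv), 0.01 * max(np.abs(yv).max(), 1e-12))

    try:
        with warnings.catch_warnings():
            # degenerate (flat) data makes the covariance inestimable; that
            # case is detected below and reported via converged=False
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(_logistic3, x, yv, p0=p0, sigma=sigma, maxfev=20000)
    except (RuntimeError, ValueError):
        return LogisticFit(float(yv.min()), float(yv.max()), float(x0), converged=False)

    bottom, top, log_ic50 = (float(v) for v in popt)
    if top < bottom:  # canonical ordering; the model is symmetric under swap
        bottom, top = top, bottom

    flat = (top - bottom) < max(1e-9, 0.05 * max(abs(yv).max(), 1.0)) or y_span == 0.0
    out_of_range = not (x.min() - 1.0 <= log_ic50 <= x.max() + 1.0)
    converged = not (flat or out_of_range or not math.isfinite(log_ic50))
    return LogisticFit(bottom, top, log_ic50, converged)


def percent_inhibition(
    mfi_sample: float, mfi_control: float, autofluorescence: float
) -> float:
    """Percent inhibition of a fluorescence signal, autofluorescence-corrected.

    Both sample and control mean fluorescence intensities are corrected by
    subtracting the cells' autofluorescence before forming the ratio:
    100 × (1 − (sample − auto) / (control − auto)).  Values below 0
    (enhancement) and above 100 are possible and preserved.
    """
    if mfi_control <= autofluorescence:
        raise ValueError(
            "control MFI must exceed autofluorescence for a defined % inhibition"
        )
    return 100.0 * (1.0 - (mfi_sample - autofluorescence) / (mfi_control - autofluorescence))


def percent_activation(
    response: float, full_agonist_response: float, baseline: float
) -> float:
    """Percent activation relative to a full agonist (full agonist = 100%)."""
    if full_agonist_response <= baseline:
        raise ValueError(
            "full-agonist response must exceed baseline for a defined % activation"
        )
    return 100.0 * (response - baseline) / (full_agonist_response - baseline)
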