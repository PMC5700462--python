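"""Two-state melting-curve analysis: Tm extraction and unfolded fraction.

A normalized A260-vs-temperature melting curve is modelled as a two-state
sigmoid

    f(T) = lo + (hi - lo) / (1 + exp((t_m - T) / slope))

where ``t_m`` is the melting temperature (the midpoint, deg C), ``slope`` the
transition width (deg C), and ``lo``/``hi`` the folded/unfolded baselines.
Raw curves are normalized by the fitted baselines (monotone rescale), which
is robust to noise at the temperature extremes.  The baseline-free sigmoid
value at a temperature is the unfolded (unwound) fraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from lmfit import Model

from .models import MeltingCurve, ParameterError


class MeltingFitError(ValueError):
    """Raised when no sigmoid signal can be fitted."""


@dataclass
class MeltingFit:
    """Fitted two-state melting model."""

    t_m: float
    slope: float
    lower: float
    upper: float
    residual_norm: float
    reoriented: bool = False

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise MeltingFitError("fitted slope must be positive")
        if self.lower >= self.upper:
            raise MeltingFitError("lower baseline must sit below the upper baseline")


def _sigmoid(T, t_m, slope, lo, hi):
    return lo + (hi - lo) / (1.0 + np.exp((t_m - T) / slope))


def fit_melting_curve(curve: MeltingCurve) -> MeltingFit:
    """Nonlinear least-squares fit of the two-state sigmoid.

    Curves recorded with decreasing orientation (absorbance falling with
    temperature) are re-oriented automatically and the flip is flagged in the
    result.  A warning is emitted if the fitted midpoint falls outside the
    measured temperature span.
    """
    T = curve.temperatures
    A = curve.absorbance
    if T.size < 6:
        raise ParameterError("need at least 6 points spanning the transition")
    reoriented = False
    if np.corrcoef(T, A)[0, 1] < 0:
        A = A.max() + A.min() - A
        reoriented = True

    span = T.max() - T.min()
    model = Model(_sigmoid)
    params = model.make_params(
        t_m=dict(value=float(T[np.argmin(np.abs(A - (A.min() + A.max()) / 2))])),
        slope=dict(value=span / 15.0, min=1e-3),
        lo=dict(value=float(A.min())),
        hi=dict(value=float(A.max())),
    )
    result = model.fit(A, params, T=T)
    lo, hi = result.params["lo"].value, result.params["hi"].value
    t_m = result.params["t_m"].value
    resid = float(np.linalg.norm(result.residual))
    # no sigmoid signal: transition amplitude indistinguishable from noise
    if hi - lo < 3.0 * resid / max(np.sqrt(T.size), 1.0) and hi - lo < 0.1:
        raise MeltingFitError(
            f"no sigmoid signal (amplitude {hi - lo:.3g}, residual norm {resid:.3g})"
        )
    if not (T.min() <= t_m <= T.max()):
        warnings.warn(
            f"fitted t_m = {t_m:.1f} C lies outside the measured span "
            f"[{T.min():.1f}, {T.max():.1f}] C",
            stacklevel=2,
        )
    return MeltingFit(
        t_m=float(t_m),
        slope=float(result.params["slope"].value),
        lower=float(lo),
        upper=float(hi),
        residual_norm=resid,
        reoriented=reoriented,
    )


def normalize(curve: MeltingCurve, fit: MeltingFit) -> MeltingCurve:
    """Rescale a raw curve to [0, 1] using the fitted baselines."""
    A = curve.absorbance
    if fit.reoriented:
        A = A.max() + A.min() - A
    return MeltingCurve(
        temperatures=curve.temperatures,
        absorbance=(A - fit.lower) / (fit.upper - fit.lower),
    )


def unfolded_fraction(fit: MeltingFit, temperature: float) -> float:
    """Baseline-free unfolded fraction at a temperature: 1/(1+exp((t_m-T)/slope))."""
    return float(1.0 / (1.0 + np.exp((fit.t_m - temperature) / fit.slope)))
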