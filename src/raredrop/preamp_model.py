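"""Threshold-gated exponential preamplification model.

The detectable output of the preamplification reaction is modelled as

    n = f(k) · k · A,    f(k) = 0 for k < h, 1 for k ≥ h,

where ``k`` is the template copy number at the start of the reaction, ``n``
the resulting number of positive droplets, ``A = exp(tv)`` the amplification
factor (reaction rate and time enter only through their product, so only A
is identifiable), and ``h`` a detection threshold below which the reaction
yields nothing detectable.  Observed counts far below the model prediction
are artifacts (probe degradation or non-specific binding) and are censored
to zero.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InvalidParameterError, UnfittableModelError

__all__ = [
    "PreampModel",
    "fit_amp_factor",
    "predict_output",
    "censor_artifacts",
    "fit_cycle_trend",
]


@dataclass(frozen=True)
class PreampModel:
    """Amplification factor A = exp(tv), detection threshold h, and the R²
    of the trend fit that produced A (None when A came from a single
    observation or was supplied directly)."""

    amp_factor: float
    threshold_h: float = 0.0
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.amp_factor < 1:
            raise InvalidParameterError("amp_factor must be >= 1")
        if self.threshold_h < 0:
            raise InvalidParameterError("threshold_h must be >= 0")
        if self.r2 is not None and not 0.0 <= self.r2 <= 1.0:
            raise InvalidParameterError("r2 must be in [0, 1]")


def fit_amp_factor(observations: Sequence[tuple[float, float]]) -> float:
    """Least-squares-through-origin fit of A in n = A·k.

    Observations with ``n == 0`` are treated as sub-threshold (the gate
    fired) and excluded; a single usable observation reduces to the ratio
    n/k.  The model has no intercept by construction.
    """
    usable = [(k, n) for k, n in observations if n > 0]
    if not usable:
        raise UnfittableModelError("all observations sub-threshold; cannot fit A")
    for k, n in usable:
        if k < 1:
            raise InvalidParameterError(f"k must be >= 1, got {k}")
    k_arr = np.array([k for k, _ in usable], dtype=float)
    n_arr = np.array([n for _, n in usable], dtype=float)
    return float(np.dot(k_arr, n_arr) / np.dot(k_arr, k_arr))


def predict_output(model: PreampModel, k: float) -> int:
    """Expected positive-droplet count at k input copies: round(A·k) above
    the threshold gate, 0 below it."""
    if k < 0:
        raise InvalidParameterError("k must be >= 0")
    if k < model.threshold_h:
        return 0
    return int(math.floor(model.amp_factor * k + 0.5))


def censor_artifacts(
    observed_n: int,
    model: PreampModel,
    k: float,
    artifact_fraction: float = 0.01,
) -> int:
    """Replace artifactual counts with zero.

    A count far below the model's prediction (ratio under
    ``artifact_fraction``) cannot be genuine amplification product — solitary
    droplets at high predicted yield come from probe degradation — and is
    censored, as is any count where the gate predicts nothing.
    """
    if observed_n < 0:
        raise InvalidParameterError("observed_n must be >= 0")
    if not 0 < artifact_fraction < 1:
        raise InvalidParameterError("artifact_fraction must be in (0, 1)")
    predicted = predict_output(model, k)
    if predicted == 0:
        return 0
    if observed_n / predicted < artifact_fraction:
        return 0
    return observed_n


def fit_cycle_trend(points: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Fit an exponential trend output = c·g^cycles and return (g, R²).

    Linear regression of log(output) on cycle number; non-positive outputs
    are excluded with a warning (log undefined).  A zero-variance response
    is an exact flat trend: growth 1.0, R² 1.0.
    """
    usable = [(c, y) for c, y in points if y > 0]
    dropped = len(points) - len(usable)
    if dropped:
        warnings.warn(
            f"excluded {dropped} non-positive output(s) from trend fit", stacklevel=2
        )
    if len(usable) < 3:
        raise UnfittableModelError(
            f"need >= 3 usable points to fit a cycle trend, have {len(usable)}"
        )
    cycles = np.array([c for c, _ in usable], dtype=float)
    logy = np.log([y for _, y in usable])
    if np.ptp(cycles) == 0:
        raise UnfittableModelError("all points at the same cycle number")
    if np.allclose(np.ptp(logy), 0.0):
        return 1.0, 1.0
    res = stats.linregress(cycles, logy)
    return float(np.exp(res.slope)), float(res.rvalue**2)
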