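"""Bland–Altman agreement between two dPCR platforms on log10 concentrations.

Paired concentration measurements (copies/µl) are compared on the log10
scale: the bias is the mean of the per-pair differences, the limits of
agreement are bias ± 1.96·SD (sample SD, n−1), and pairs whose difference
falls outside the limits are outliers.  Unpaired measurements and zero
concentrations (log undefined) are excluded before analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidParameterError, ValidationError

__all__ = [
    "AgreementResult",
    "PairingResult",
    "pair_measurements",
    "bland_altman",
    "limits_of_agreement",
    "plot_bland_altman",
]


@dataclass(frozen=True)
class PairingResult:
    """Retained pairs plus an account of exclusions."""

    keys: tuple
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    n_raw: int
    excluded_unpaired: tuple
    excluded_zero: tuple

    @property
    def pairs(self) -> list[tuple[float, float]]:
        return list(zip(self.values_a, self.values_b))


@dataclass(frozen=True)
class AgreementResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n_pairs: int
    n_outliers: int
    outlier_ids: tuple


def _as_keyed(measurements) -> dict:
    if isinstance(measurements, Mapping):
        return dict(measurements)
    items = list(measurements)
    keys = [k for k, _ in items]
    if len(keys) != len(set(keys)):
        dupes = sorted({k for k in keys if keys.count(k) > 1}, key=str)
        raise ValidationError(f"duplicate measurement keys: {dupes}")
    return dict(items)


def pair_measurements(platform_a, platform_b) -> PairingResult:
    """Pair measurements by key, excluding unpaired keys and zero values.

    Keys are whatever identifies a measurement (sample/target/condition);
    inputs are mappings or iterables of ``(key, value)``.  Repeated keys in
    an iterable input are rejected.
    """
    platform_a = _as_keyed(platform_a)
    platform_b = _as_keyed(platform_b)
    all_keys = sorted(set(platform_a) | set(platform_b), key=str)
    shared = [k for k in all_keys if k in platform_a and k in platform_b]
    unpaired = tuple(k for k in all_keys if k not in shared)
    kept, zeros = [], []
    for k in shared:
        a, b = float(platform_a[k]), float(platform_b[k])
        if a < 0 or b < 0:
            raise ValidationError(f"negative concentration for key {k!r}")
        if a == 0 or b == 0:
            zeros.append(k)
        else:
            kept.append((k, a, b))
    return PairingResult(
        keys=tuple(k for k, _, _ in kept),
        values_a=tuple(a for _, a, _ in kept),
        values_b=tuple(b for _, _, b in kept),
        n_raw=len(all_keys),
        excluded_unpaired=unpaired,
        excluded_zero=tuple(zeros),
    )


def limits_of_agreement(bias: float, sd: float) -> tuple[float, float]:
    """(bias − 1.96·sd, bias + 1.96·sd)."""
    if sd < 0:
        raise InvalidParameterError("sd must be >= 0")
    return bias - 1.96 * sd, bias + 1.96 * sd


def bland_altman(
    pairs: Sequence[tuple[float, float]],
    ids: Sequence | None = None,
    orientation: str = "b_minus_a",
) -> AgreementResult:
    """Bland–Altman statistics on log10-transformed pairs.

    ``orientation`` fixes the sign of the differences; the default
    ``"b_minus_a"`` reports platform-B-minus-platform-A (with B the newer
    platform, positive bias means B reads higher).
    """
    if len(pairs) < 2:
        raise InvalidParameterError("need >= 2 pairs for Bland-Altman analysis")
    if orientation not in ("b_minus_a", "a_minus_b"):
        raise InvalidParameterError(f"unknown orientation {orientation!r}")
    a = np.array([p[0] for p in pairs], dtype=float)
    b = np.array([p[1] for p in pairs], dtype=float)
    if np.any(a <= 0) or np.any(b <= 0):
        raise InvalidParameterError(
            "non-positive concentration in pairs; exclude zeros upstream"
        )
    diffs = np.log10(b) - np.log10(a)
    if orientation == "a_minus_b":
        diffs = -diffs
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    lo, hi = limits_of_agreement(bias, sd)
    outside = np.abs(diffs - bias) > 1.96 * sd
    if ids is None:
        ids = list(range(len(pairs)))
    if len(ids) != len(pairs):
        raise InvalidParameterError("ids must match pairs one-to-one")
    outlier_ids = tuple(i for i, o in zip(ids, outside) if o)
    return AgreementResult(
        bias=bias,
        sd=sd,
        loa_low=lo,
        loa_high=hi,
        n_pairs=len(pairs),
        n_outliers=int(outside.sum()),
        outlier_ids=outlier_ids,
    )


def plot_bland_altman(
    pairs: Sequence[tuple[float, float]],
    result: AgreementResult,
    path: str,
    orientation: str = "b_minus_a",
) -> None:
    """Mean-vs-difference plot with bias and limit-of-agreement lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = np.log10([p[0] for p in pairs])
    b = np.log10([p[1] for p in pairs])
    diffs = b - a if orientation == "b_minus_a" else a - b
    means = (a + b) / 2
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=18, color="black", zorder=3)
    ax.axhline(result.bias, color="tab:blue", linestyle="--", label=f"bias = {result.bias:.2f}")
    for y, lbl in ((result.loa_low, "LoA low"), (result.loa_high, "LoA high")):
        ax.axhline(y, color="tab:red", linestyle="--", label=f"{lbl} = {y:.2f}")
    ax.set_xlabel("mean log10 concentration (copies/µl)")
    ax.set_ylabel("difference (log10 copies/µl)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
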