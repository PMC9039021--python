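"""Poisson-based target quantification from partition counts.

Digital PCR quantifies without standards: with ``p = n_pos / n_total``
positive partitions, the mean occupancy per partition is ``λ = −ln(1 − p)``
and the reaction concentration is ``λ / partition volume`` (times the
platform's volume precision factor).  Confidence intervals come from an
exact Clopper–Pearson interval on ``p`` pushed through the same transform,
which is monotone, so coverage is preserved.

Back-calculation to the starting sample divides out the post-preamplification
dilution and the preamplification factor, and rescales by the
reaction-to-template volume ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .droplet_io import PlatformProfile
from .errors import (
    InvalidParameterError,
    SaturatedWellError,
    UndefinedVafError,
)
from .calling import WellClassification

__all__ = [
    "LambdaEstimate",
    "ConcentrationEstimate",
    "estimate_lambda",
    "lambda_to_concentration",
    "back_calculate",
    "vaf",
    "merge_replicates",
    "quantify_channel",
]


@dataclass(frozen=True)
class LambdaEstimate:
    """Mean copies per partition with a 95% (by default) interval."""

    lam: float
    lam_low: float
    lam_high: float
    n_pos: int
    n_total: int


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Concentration at reaction scale and back-calculated sample scale.

    ``ci_low``/``ci_high`` bracket ``conc_reaction`` (copies/µl in the dPCR
    reaction); ``conc_sample`` is copies/µl in the starting sample after
    dividing out dilution and preamplification.
    """

    lam: float
    conc_reaction: float
    conc_sample: float
    ci_low: float
    ci_high: float
    channel: str


def estimate_lambda(n_pos: int, n_total: int, alpha: float = 0.05) -> LambdaEstimate:
    """Estimate mean copies/partition from positive-partition counts.

    Raises :class:`SaturatedWellError` when every partition is positive
    (the Poisson estimate diverges; the well is unquantifiable, not
    infinite).
    """
    if n_total < 1:
        raise InvalidParameterError("n_total must be >= 1")
    if not 0 <= n_pos <= n_total:
        raise InvalidParameterError("n_pos must satisfy 0 <= n_pos <= n_total")
    if n_pos == n_total:
        raise SaturatedWellError(
            f"all {n_total} partitions positive: concentration not quantifiable"
        )
    p = n_pos / n_total
    lam = -np.log1p(-p)
    # Clopper-Pearson bounds on p, mapped through the monotone -ln(1-p)
    if n_pos == 0:
        p_low = 0.0
    else:
        p_low = stats.beta.ppf(alpha / 2, n_pos, n_total - n_pos + 1)
    p_high = stats.beta.ppf(1 - alpha / 2, n_pos + 1, n_total - n_pos)
    lam_high = float(-np.log1p(-p_high)) if p_high < 1 else float("inf")
    return LambdaEstimate(
        lam=float(lam),
        lam_low=float(-np.log1p(-p_low)),
        lam_high=lam_high,
        n_pos=n_pos,
        n_total=n_total,
    )


def lambda_to_concentration(lam: float, profile: PlatformProfile) -> float:
    """Copies/µl in the reaction from mean copies per partition."""
    if lam < 0:
        raise InvalidParameterError("lam must be >= 0")
    volume_ul = profile.partition_volume_nl * 1e-3
    if volume_ul <= 0:
        raise InvalidParameterError("partition volume must be > 0")
    return lam / volume_ul * profile.vpf


def back_calculate(
    conc_reaction: float,
    dilution_factor: float = 1.0,
    preamp_factor: float = 1.0,
    volume_ratio: float = 1.0,
) -> float:
    """Concentration in the starting sample from the reaction concentration.

    ``dilution_factor`` is the post-preamplification dilution (2 for the
    protocol's 1:1 TE dilution), ``preamp_factor`` the per-molecule
    amplification factor A = exp(tv), and ``volume_ratio`` the reaction
    volume over the template volume drawn from the sample (1 when reporting
    per-reaction-equivalent units).
    """
    if conc_reaction < 0:
        raise InvalidParameterError("conc_reaction must be >= 0")
    if dilution_factor < 1:
        raise InvalidParameterError("dilution_factor must be >= 1")
    if preamp_factor < 1:
        raise InvalidParameterError("preamp_factor must be >= 1")
    if volume_ratio <= 0:
        raise InvalidParameterError("volume_ratio must be > 0")
    return conc_reaction * dilution_factor / preamp_factor * volume_ratio


def vaf(conc_mut: float, conc_wt: float) -> float:
    """Variant allele frequency in percent: 100·mut/(mut+wt)."""
    if conc_mut < 0 or conc_wt < 0:
        raise InvalidParameterError("concentrations must be >= 0")
    total = conc_mut + conc_wt
    if total == 0:
        raise UndefinedVafError("VAF undefined: both concentrations are zero")
    return 100.0 * conc_mut / total


def merge_replicates(
    classifications: Sequence[WellClassification],
    profiles: Sequence[PlatformProfile] | None = None,
) -> WellClassification:
    """Pool replicate wells by summing counts (before λ estimation).

    Summing first is the statistically correct pooling: the pooled counts
    remain binomial, whereas averaging per-well λ estimates does not shrink
    the interval correctly.  Mixing wells measured under different platform
    profiles is rejected.
    """
    if not classifications:
        raise InvalidParameterError("need at least one well to merge")
    if profiles is not None:
        if len(profiles) != len(classifications):
            raise InvalidParameterError("profiles must match classifications one-to-one")
        if len({(p.name, p.partition_volume_nl, p.vpf) for p in profiles}) > 1:
            raise InvalidParameterError("cannot pool wells from different platform profiles")
    return WellClassification(
        n_total=sum(w.n_total for w in classifications),
        n_fam_pos=sum(w.n_fam_pos for w in classifications),
        n_hex_pos=sum(w.n_hex_pos for w in classifications),
        n_double_pos=sum(w.n_double_pos for w in classifications),
        n_double_neg=sum(w.n_double_neg for w in classifications),
    )


def quantify_channel(
    n_pos: int,
    n_total: int,
    profile: PlatformProfile,
    channel: str,
    dilution_factor: float = 1.0,
    preamp_factor: float = 1.0,
    volume_ratio: float = 1.0,
    alpha: float = 0.05,
) -> ConcentrationEstimate:
    """End-to-end estimate for one channel: λ → reaction conc → sample conc."""
    est = estimate_lambda(n_pos, n_total, alpha=alpha)
    conc = lambda_to_concentration(est.lam, profile)
    ci_low = lambda_to_concentration(est.lam_low, profile)
    ci_high = (
        lambda_to_concentration(est.lam_high, profile)
        if np.isfinite(est.lam_high)
        else float("inf")
    )
    conc_sample = back_calculate(conc, dilution_factor, preamp_factor, volume_ratio)
    return ConcentrationEstimate(
        lam=est.lam,
        conc_reaction=conc,
        conc_sample=conc_sample,
        ci_low=ci_low,
        ci_high=ci_high,
        channel=channel,
    )
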