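"""Low-copy template sampling: probability of capturing mutant alleles.

Pipetting ``k_total`` template molecules from a cfDNA extract captures a
Binomial(k_total, f) number of mutant alleles, f being the variant allele
fraction.  At high copy number (k ≥ 100) the binomial is well approximated
by a Gaussian (de Moivre–Laplace); the exact tail is always available and
is the library default.

Composed with the preamplification model this yields the distribution of
FAM-positive droplet counts — and hence the probability that a sample will
meet the ≥50-droplet positivity rule — as a function of input copies and
VAF.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidParameterError, UnreachableTargetError
from .preamp_model import PreampModel, predict_output

__all__ = [
    "SamplingScenario",
    "PostPreampSummary",
    "capture_probability",
    "min_input_for_detection",
    "expected_positive_droplets_after_preamp",
]

NORMAL_APPROX_MIN_K = 100


@dataclass(frozen=True)
class SamplingScenario:
    """Template copies entering the reaction and the mutant allele fraction."""

    k_total: int
    vaf_f: float

    def __post_init__(self) -> None:
        if self.k_total < 0 or int(self.k_total) != self.k_total:
            raise InvalidParameterError("k_total must be a non-negative integer")
        if not 0.0 <= self.vaf_f <= 1.0:
            raise InvalidParameterError("vaf_f must be in [0, 1]")


@dataclass(frozen=True)
class PostPreampSummary:
    """Distribution summary of predicted FAM-positive droplet counts."""

    mean: float
    p_positive_call: float
    min_count: int


def _exact_tail(k: int, f: float, min_mutant: int) -> float:
    # P(X >= min_mutant), X ~ Binomial(k, f)
    if min_mutant <= 0:
        return 1.0
    return float(stats.binom.sf(min_mutant - 1, k, f))


def _normal_tail(k: int, f: float, min_mutant: int) -> float:
    # de Moivre-Laplace with continuity correction
    if min_mutant <= 0:
        return 1.0
    var = k * f * (1.0 - f)
    if var == 0:
        return _exact_tail(k, f, min_mutant)
    z = (min_mutant - 0.5 - k * f) / np.sqrt(var)
    return float(stats.norm.sf(z))


def capture_probability(
    scenario: SamplingScenario,
    min_mutant: int = 1,
    method: str = "exact",
) -> float:
    """P(at least ``min_mutant`` mutant copies land in the reaction).

    ``method="exact"`` (default) always uses the binomial tail;
    ``"normal"`` forces the Gaussian approximation;
    ``"auto"`` switches to the approximation at k_total ≥ 100.
    """
    if min_mutant < 0:
        raise InvalidParameterError("min_mutant must be >= 0")
    if method not in ("exact", "normal", "auto"):
        raise InvalidParameterError(f"unknown method {method!r}")
    k, f = scenario.k_total, scenario.vaf_f
    if method == "auto":
        method = "normal" if k >= NORMAL_APPROX_MIN_K else "exact"
    if method == "normal":
        return min(1.0, max(0.0, _normal_tail(k, f, min_mutant)))
    return _exact_tail(k, f, min_mutant)


def min_input_for_detection(
    vaf_f: float,
    target_prob: float,
    min_mutant: int = 1,
    max_k: int = 10_000_000,
) -> int:
    """Smallest template copy number whose capture probability reaches
    ``target_prob``, found by upward scan (the probability is monotone
    non-decreasing in k)."""
    if not 0 < vaf_f <= 1:
        if vaf_f == 0:
            raise UnreachableTargetError("vaf_f = 0: no input reaches the target")
        raise InvalidParameterError("vaf_f must be in (0, 1]")
    if not 0 < target_prob < 1:
        raise InvalidParameterError("target_prob must be in (0, 1)")
    k = min_mutant
    while k <= max_k:
        if capture_probability(SamplingScenario(k, vaf_f), min_mutant) >= target_prob:
            return k
        k += 1
    raise UnreachableTargetError(
        f"target probability {target_prob} not reached by k = {max_k}"
    )


def expected_positive_droplets_after_preamp(
    scenario: SamplingScenario,
    model: PreampModel,
    min_count: int = 50,
) -> PostPreampSummary:
    """Propagate mutant-copy sampling through the preamplification model.

    Enumerates the Binomial(k_total, f) mutant copy number exactly, maps
    each value through the threshold-gated prediction, and reports the mean
    predicted FAM-positive count and the probability of meeting the
    ``min_count`` positivity rule.
    """
    k, f = scenario.k_total, scenario.vaf_f
    m = np.arange(k + 1)
    pmf = stats.binom.pmf(m, k, f) if k > 0 else np.array([1.0])
    counts = np.array([predict_output(model, int(mi)) for mi in m], dtype=float)
    mean = float(np.dot(pmf, counts))
    p_call = float(pmf[counts >= min_count].sum())
    return PostPreampSummary(mean=mean, p_positive_call=p_call, min_count=min_count)
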