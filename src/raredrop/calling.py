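"""Partition classification and sample-level verdict rules.

A partition is positive in a channel when its amplitude is at or above the
platform threshold (boundary inclusive).  Sample verdicts follow the
protocol's count rules over two technical replicates:

* **positive** — ≥ ``min_count`` (default 50) FAM-positive partitions summed
  over the duplicates, reproducible (each replicate contributes ≥ 1);
* **negative** — > ``min_count`` HEX-positive and < ``min_count``
  FAM-positive partitions in the duplicate total;
* **ambiguous** — FAM signal present but below the positive rule, with
  insufficient HEX evidence, or FAM positivity confined to one replicate;
* **non_informative** — no FAM signal and ≤ ``min_count`` HEX positives
  (too little amplifiable template to call anything).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .droplet_io import CohortRecord, DropletRecord, PlatformProfile
from .errors import EmptyWellError, InvalidParameterError, MissingDataError

__all__ = ["Verdict", "WellClassification", "SampleCall", "classify_droplets",
           "call_sample", "informativeness_filter"]


class Verdict(str, enum.Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    AMBIGUOUS = "ambiguous"
    NON_INFORMATIVE = "non_informative"


@dataclass(frozen=True)
class WellClassification:
    """Per-well counts of the four threshold classes.

    Channel-positive counts include double positives, so
    ``n_fam_pos + n_hex_pos − n_double_pos + n_double_neg == n_total``.
    """

    n_total: int
    n_fam_pos: int
    n_hex_pos: int
    n_double_pos: int
    n_double_neg: int

    def __post_init__(self) -> None:
        counts = (self.n_total, self.n_fam_pos, self.n_hex_pos,
                  self.n_double_pos, self.n_double_neg)
        if any(c < 0 for c in counts):
            raise InvalidParameterError("partition counts must be >= 0")
        if any(c > self.n_total for c in counts[1:]):
            raise InvalidParameterError("no class count may exceed n_total")
        if self.n_fam_pos + self.n_hex_pos - self.n_double_pos + self.n_double_neg != self.n_total:
            raise InvalidParameterError(
                "counts violate the partition identity "
                "n_fam_pos + n_hex_pos - n_double_pos + n_double_neg = n_total"
            )


@dataclass(frozen=True)
class SampleCall:
    verdict: Verdict
    fam_pos_total: int
    hex_pos_total: int
    replicate_fam_counts: tuple[int, ...]


def classify_droplets(
    records: Sequence[DropletRecord], profile: PlatformProfile
) -> WellClassification:
    """Count threshold classes in one well (threshold comparison is ``>=``)."""
    if not records:
        raise EmptyWellError("cannot classify an empty well")
    fam = np.fromiter((r.fam_rfu for r in records), dtype=float, count=len(records))
    hexv = np.fromiter((r.hex_rfu for r in records), dtype=float, count=len(records))
    fam_pos = fam >= profile.fam_threshold_rfu
    hex_pos = hexv >= profile.hex_threshold_rfu
    return WellClassification(
        n_total=len(records),
        n_fam_pos=int(fam_pos.sum()),
        n_hex_pos=int(hex_pos.sum()),
        n_double_pos=int((fam_pos & hex_pos).sum()),
        n_double_neg=int((~fam_pos & ~hex_pos).sum()),
    )


def call_sample(
    duplicates: Sequence[WellClassification],
    min_count: int = 50,
    positive_rule: str = "total",
) -> SampleCall:
    """Apply the duplicate-level verdict rules.

    ``positive_rule`` selects how the ``min_count`` criterion is read:
    ``"total"`` (default) requires the duplicate-summed FAM count to reach
    ``min_count`` with every replicate contributing at least one positive;
    ``"per_replicate"`` requires every replicate to reach ``min_count`` on
    its own.
    """
    if len(duplicates) != 2:
        raise InvalidParameterError(
            f"call_sample expects exactly 2 technical replicates, got {len(duplicates)}"
        )
    if min_count < 1:
        raise InvalidParameterError("min_count must be >= 1")
    if positive_rule not in ("total", "per_replicate"):
        raise InvalidParameterError(f"unknown positive_rule {positive_rule!r}")

    fam_counts = tuple(w.n_fam_pos for w in duplicates)
    fam_total = sum(fam_counts)
    hex_total = sum(w.n_hex_pos for w in duplicates)

    if positive_rule == "total":
        meets_positive = fam_total >= min_count
    else:
        meets_positive = all(c >= min_count for c in fam_counts)
    reproducible = all(c >= 1 for c in fam_counts)

    if meets_positive and reproducible:
        verdict = Verdict.POSITIVE
    elif meets_positive:
        verdict = Verdict.AMBIGUOUS  # enough droplets but confined to one replicate
    elif hex_total > min_count and fam_total < min_count:
        verdict = Verdict.NEGATIVE
    elif fam_total >= 1:
        verdict = Verdict.AMBIGUOUS  # sub-rule FAM signal without HEX backing
    else:
        verdict = Verdict.NON_INFORMATIVE

    return SampleCall(
        verdict=verdict,
        fam_pos_total=fam_total,
        hex_pos_total=hex_total,
        replicate_fam_counts=fam_counts,
    )


def informativeness_filter(record: CohortRecord) -> bool:
    """Whether an isolate is analytically informative.

    An isolate with no amplifiable ≥150 bp fragments (measured concentration
    exactly zero) cannot carry the assay and is excluded as non-informative.
    A missing 150 bp measurement is an error, not a zero.
    """
    if record.conc_150 is None:
        raise MissingDataError(
            f"patient {record.patient_id}: 150 bp concentration missing; "
            "informativeness undefined"
        )
    return record.conc_150 > 0
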