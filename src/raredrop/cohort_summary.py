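"""Cohort-level cfDNA concentration summaries.

Summaries run on the 150 bp amplifiable-fragment concentration (the working
fragment length for the assay), overall and by CSF collection route, with
the option of restricting to analytically informative isolates (150 bp
concentration > 0).  Collection routes group into ventricular (ventricular
access device or intraoperative collection) versus lumbar puncture.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .calling import informativeness_filter
from .droplet_io import CohortRecord
from .errors import EmptyCohortError

__all__ = ["GroupSummary", "CohortSummary", "summarize", "route_comparison"]

VENTRICULAR_ROUTES = ("VAD", "IO")


@dataclass(frozen=True)
class GroupSummary:
    median: float
    range: tuple[float, float]
    n: int


@dataclass(frozen=True)
class CohortSummary:
    n_isolates: int
    n_informative: int
    median_150: float
    range_150: tuple[float, float]
    by_route: Mapping[str, GroupSummary]


def _group_summary(values: Sequence[float]) -> GroupSummary:
    arr = np.asarray(values, dtype=float)
    return GroupSummary(
        median=float(np.median(arr)),
        range=(float(arr.min()), float(arr.max())),
        n=len(arr),
    )


def _route_group(record: CohortRecord) -> str:
    return "ventricular" if record.collection_route in VENTRICULAR_ROUTES else "lumbar"


def summarize(records: Sequence[CohortRecord], informative_only: bool = False) -> CohortSummary:
    """Median and range of 150 bp concentrations, overall and by route group.

    With ``informative_only`` the zero-concentration isolates are dropped
    first (they cannot carry the assay); each isolate counts as one
    observation even when a patient contributed several.  Even-sized groups
    take the midpoint of the central pair as the median.
    """
    if not records:
        raise EmptyCohortError("no cohort records")
    usable = [r for r in records if r.conc_150 is not None]
    informative = [r for r in usable if informativeness_filter(r)]
    retained = informative if informative_only else usable
    if not retained:
        raise EmptyCohortError("no isolates retained after filtering")
    values = [r.conc_150 for r in retained]
    by_route = {}
    for group in ("ventricular", "lumbar"):
        vals = [r.conc_150 for r in retained if _route_group(r) == group]
        if vals:
            by_route[group] = _group_summary(vals)
    overall = _group_summary(values)
    return CohortSummary(
        n_isolates=len(usable),
        n_informative=len(informative),
        median_150=overall.median,
        range_150=overall.range,
        by_route=by_route,
    )


def route_comparison(records: Sequence[CohortRecord]) -> dict[str, GroupSummary]:
    """Ventricular vs lumbar concentration summaries over all isolates
    (zeros and repeat isolates included)."""
    if not records:
        raise EmptyCohortError("no cohort records")
    out: dict[str, GroupSummary] = {}
    for group in ("ventricular", "lumbar"):
        vals = [r.conc_150 for r in records
                if r.conc_150 is not None and _route_group(r) == group]
        if vals:
            out[group] = _group_summary(vals)
    return out
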