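"""Dilution-series design and limit-of-detection calling.

The analytical sensitivity of the assay is characterised on a geometric
dilution series of template mass (default ten two-fold dilutions descending
from 600 pg).  The LoD is the smallest input mass whose duplicate-summed
positive-partition count reaches the detection rule (≥ 50 droplets above
threshold in at least one channel, totalled over the two replicates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .calling import WellClassification
from .errors import InvalidParameterError, ValidationError

__all__ = [
    "DilutionPoint",
    "make_dilution_series",
    "call_lod",
    "mass_to_genome_equivalents",
    "PG_PER_HAPLOID_GENOME",
]

PG_PER_HAPLOID_GENOME = 3.3


@dataclass(frozen=True)
class DilutionPoint:
    """One dilution level: input mass and its two replicate wells."""

    input_mass_pg: float
    duplicate_classifications: tuple[WellClassification, WellClassification]

    def __post_init__(self) -> None:
        if self.input_mass_pg <= 0:
            raise ValidationError("input_mass_pg must be > 0")
        if len(self.duplicate_classifications) != 2:
            raise ValidationError("a dilution point carries exactly two replicate wells")


def make_dilution_series(
    start_mass_pg: float = 600.0, n_dilutions: int = 10, factor: float = 2.0
) -> list[float]:
    """Geometric series of input masses: start, start/factor, ..."""
    if start_mass_pg <= 0:
        raise InvalidParameterError("start_mass_pg must be > 0")
    if n_dilutions < 1:
        raise InvalidParameterError("n_dilutions must be >= 1")
    if factor <= 1:
        raise InvalidParameterError("dilution factor must be > 1")
    return [start_mass_pg / factor**i for i in range(n_dilutions)]


def _detected(point: DilutionPoint, min_count: int) -> bool:
    fam = sum(w.n_fam_pos for w in point.duplicate_classifications)
    hexv = sum(w.n_hex_pos for w in point.duplicate_classifications)
    return fam >= min_count or hexv >= min_count


def call_lod(series: Sequence[DilutionPoint], min_count: int = 50) -> float | None:
    """Smallest input mass meeting the detection rule, or None if no point
    does.  The rule: duplicate-summed FAM or HEX positives ≥ ``min_count``
    ("at least 50 droplets ... in at least one of the channels in total
    counts for the duplicates")."""
    if not series:
        raise ValidationError("dilution series is empty")
    if min_count < 1:
        raise InvalidParameterError("min_count must be >= 1")
    detected = [p.input_mass_pg for p in series if _detected(p, min_count)]
    return min(detected) if detected else None


def mass_to_genome_equivalents(
    mass_pg: float, pg_per_haploid_genome: float = PG_PER_HAPLOID_GENOME
) -> int:
    """Nearest whole number of haploid genome equivalents in a DNA mass."""
    if mass_pg < 0:
        raise InvalidParameterError("mass_pg must be >= 0")
    if pg_per_haploid_genome <= 0:
        raise InvalidParameterError("pg_per_haploid_genome must be > 0")
    return int(round(mass_pg / pg_per_haploid_genome))
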