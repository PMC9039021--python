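"""Read/write partition amplitude tables, cohort metadata and platform profiles.

Two CSV dialects are defined by this package.  They approximate the flat
exports of the droplet (QX200-style) and nanoplate (QIAcuity-style) platforms
without binding to any vendor format version:

``droplet`` dialect columns
    ``well``, ``sample``, ``ch1_amplitude`` (FAM), ``ch2_amplitude`` (HEX)

``nanoplate`` dialect columns
    ``well_name``, ``replicate_id``, ``fam_rfu``, ``hex_rfu``

The FAM channel carries the mutant-allele signal (H3F3A K27M), HEX the wild
type.  A ``column_map`` argument lets callers rename columns when an export
deviates from the documented lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import InvalidParameterError, SchemaError, ValidationError

__all__ = [
    "DropletRecord",
    "PlatformProfile",
    "CohortRecord",
    "DIALECT_COLUMNS",
    "BUILTIN_PROFILES",
    "read_amplitude_csv",
    "write_amplitude_csv",
    "read_cohort_table",
    "load_platform_profile",
    "write_truth_sidecar",
    "packaged_cohort_path",
]

ROUTES = ("VAD", "IO", "LP")
H3_STATUSES = ("positive", "negative", "unavailable")


@dataclass(frozen=True)
class DropletRecord:
    """One partition's two-channel fluorescence readout."""

    well_id: str
    replicate_id: str
    fam_rfu: float
    hex_rfu: float

    def __post_init__(self) -> None:
        for name in ("fam_rfu", "hex_rfu"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class PlatformProfile:
    """Thresholds and partition geometry of a dPCR platform.

    ``vpf`` is the Volume Precision Factor, a multiplicative correction for
    partition-volume variation on nanoplate platforms (1.0 = no correction).
    """

    name: str
    fam_threshold_rfu: float
    hex_threshold_rfu: float
    partition_volume_nl: float
    vpf: float = 1.0

    def __post_init__(self) -> None:
        if self.fam_threshold_rfu <= 0 or self.hex_threshold_rfu <= 0:
            raise InvalidParameterError("fluorescence thresholds must be > 0")
        if self.partition_volume_nl <= 0:
            raise InvalidParameterError("partition_volume_nl must be > 0")
        if self.vpf <= 0:
            raise InvalidParameterError("vpf must be > 0")


@dataclass(frozen=True)
class CohortRecord:
    """One cfDNA isolate from one CSF collection.

    Concentrations are per amplifiable fragment length (37/150/300 bp) in
    copies/µl; ``None`` encodes a missing measurement, 0.0 a measured zero.
    The distinction matters: the informativeness filter excludes measured
    zeros at 150 bp, not missing values.
    """

    patient_id: str
    collection_route: str
    csf_volume_ml: float | None
    conc_37: float | None
    conc_150: float | None
    conc_300: float | None
    tissue_h3_status: str = "unavailable"
    isolate_id: str = "1"

    def __post_init__(self) -> None:
        if self.collection_route not in ROUTES:
            raise ValidationError(
                f"unknown collection route {self.collection_route!r}; expected one of {ROUTES}"
            )
        if self.tissue_h3_status not in H3_STATUSES:
            raise ValidationError(
                f"unknown tissue H3 status {self.tissue_h3_status!r}; expected one of {H3_STATUSES}"
            )
        for name in ("conc_37", "conc_150", "conc_300"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValidationError(f"{name} must be >= 0 or null, got {v!r}")


DIALECT_COLUMNS: dict[str, dict[str, str]] = {
    # field name -> column name in the dialect
    "droplet": {
        "well_id": "well",
        "replicate_id": "sample",
        "fam_rfu": "ch1_amplitude",
        "hex_rfu": "ch2_amplitude",
    },
    "nanoplate": {
        "well_id": "well_name",
        "replicate_id": "replicate_id",
        "fam_rfu": "fam_rfu",
        "hex_rfu": "hex_rfu",
    },
}

BUILTIN_PROFILES: dict[str, PlatformProfile] = {
    # Droplet platform: manually set thresholds of 2000/1500 RFU (FAM/HEX).
    "qx200": PlatformProfile("qx200", 2000.0, 1500.0, 0.85, 1.0),
    # Nanoplate platform: thresholds 40/20 RFU; VPF defaults to no correction
    # and is overridden per instrument from config.
    "qiacuity": PlatformProfile("qiacuity", 40.0, 20.0, 1.34, 1.0),
}


def _dialect_map(dialect: str, column_map: Mapping[str, str] | None) -> dict[str, str]:
    try:
        cols = dict(DIALECT_COLUMNS[dialect])
    except KeyError:
        raise InvalidParameterError(
            f"unknown dialect {dialect!r}; expected one of {sorted(DIALECT_COLUMNS)}"
        ) from None
    if column_map:
        cols.update(column_map)
    return cols


def read_amplitude_csv(
    path: str | Path,
    dialect: str = "droplet",
    column_map: Mapping[str, str] | None = None,
) -> list[DropletRecord]:
    """Read a partition amplitude table into :class:`DropletRecord` objects.

    Raises :class:`SchemaError` naming every missing mandatory column, and
    :class:`ValidationError` with the (0-based) data row index for negative
    or non-finite amplitudes.  Parsing is total: any bad row aborts the read.
    """
    cols = _dialect_map(dialect, column_map)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s) {missing} for dialect {dialect!r}"
        )
    records: list[DropletRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        vals = {f: getattr(row, c) for f, c in cols.items()}
        try:
            records.append(
                DropletRecord(
                    well_id=str(vals["well_id"]),
                    replicate_id=str(vals["replicate_id"]),
                    fam_rfu=float(vals["fam_rfu"]),
                    hex_rfu=float(vals["hex_rfu"]),
                )
            )
        except (ValidationError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: bad amplitude in data row {i}: {exc}") from exc
    return records


def write_amplitude_csv(
    records: Iterable[DropletRecord],
    path: str | Path,
    dialect: str = "droplet",
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write records as CSV in the given dialect (inverse of the reader)."""
    cols = _dialect_map(dialect, column_map)
    recs = list(records)
    df = pd.DataFrame(
        {
            cols["well_id"]: [r.well_id for r in recs],
            cols["replicate_id"]: [r.replicate_id for r in recs],
            cols["fam_rfu"]: [r.fam_rfu for r in recs],
            cols["hex_rfu"]: [r.hex_rfu for r in recs],
        }
    )
    # %.17g guarantees float round-trip through the text format
    df.to_csv(path, index=False, float_format="%.17g")


_COHORT_COLUMNS = [
    "patient_id",
    "isolate_id",
    "collection_route",
    "csf_volume_ml",
    "conc_37",
    "conc_150",
    "conc_300",
    "tissue_h3_status",
]


def read_cohort_table(path: str | Path) -> list[CohortRecord]:
    """Read a cohort metadata TSV (one row per cfDNA isolate).

    Patients contributing several isolates appear on several rows.  Empty
    cells in concentration columns become ``None``; literal zeros stay 0.0.
    """
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "isolate_id": str})
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory column(s) {missing}")
    records = []
    for i, row in df.iterrows():
        def _num(v):
            return None if pd.isna(v) else float(v)

        try:
            records.append(
                CohortRecord(
                    patient_id=str(row["patient_id"]),
                    isolate_id=str(row["isolate_id"]),
                    collection_route=str(row["collection_route"]),
                    csf_volume_ml=_num(row["csf_volume_ml"]),
                    conc_37=_num(row["conc_37"]),
                    conc_150=_num(row["conc_150"]),
                    conc_300=_num(row["conc_300"]),
                    tissue_h3_status=str(row["tissue_h3_status"]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: data row {i}: {exc}") from exc
    return records


def packaged_cohort_path() -> Path:
    """Path to the packaged cohort fixture (21 CSF cfDNA isolates)."""
    return Path(resources.files("raredrop").joinpath("data/cohort_csf_isolates.tsv"))


def load_platform_profile(
    name: str, config: Mapping[str, Mapping[str, float]] | None = None
) -> PlatformProfile:
    """Return a platform profile by name.

    ``config`` may define new profiles or override builtin fields, e.g.::

        {"qiacuity": {"vpf": 1.05}}

    Omitted fields fall back to the builtin (or ``vpf=1.0`` for new names).
    """
    base = BUILTIN_PROFILES.get(name)
    override = dict(config.get(name, {})) if config else {}
    if base is None and not override:
        raise InvalidParameterError(
            f"unknown platform profile {name!r}; known: {sorted(BUILTIN_PROFILES)}"
        )
    fields = {
        "name": name,
        "fam_threshold_rfu": base.fam_threshold_rfu if base else None,
        "hex_threshold_rfu": base.hex_threshold_rfu if base else None,
        "partition_volume_nl": base.partition_volume_nl if base else None,
        "vpf": base.vpf if base else 1.0,
    }
    fields.update(override)
    if any(v is None for v in fields.values()):
        missing = [k for k, v in fields.items() if v is None]
        raise InvalidParameterError(f"profile {name!r} incomplete: missing {missing}")
    return PlatformProfile(**fields)  # type: ignore[arg-type]


def write_truth_sidecar(truth, path: str | Path) -> None:
    """Write a simulation ground-truth sidecar as YAML."""
    from dataclasses import asdict

    with open(path, "w") as fh:
        yaml.safe_dump(asdict(truth), fh, sort_keys=False)
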