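"""Data model and I/O for allele-specific qPCR plates and validation tables.

The central objects are :class:`WellMeasurement` (one amplification reaction:
either the mutant-allele assay or the gene-reference assay for a sample) and
:class:`Plate` (an ordered collection of wells with the plate-level controls).
Replicate reference-standard runs and paired mutant-allele-fraction (MAF)
tables from orthogonal methods have their own containers.

Two representation rules hold everywhere:

* a cycle-threshold (Ct) value is either a finite positive float or *absent*
  (``None``) — "no signal" is never encoded as 0, NaN or a sentinel cycle;
* the stored dCt convention is ``Ct(mutant assay) - Ct(reference assay)``,
  so abundant mutant template gives a small dCt.  Instrument exports that
  print the negated difference are flipped on read via the dialect flag
  ``negated_delta_ct``.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .errors import FormatError, PairingError

__all__ = [
    "AssayRole",
    "WellKind",
    "Material",
    "Call",
    "WellMeasurement",
    "Plate",
    "ReferenceLevelRun",
    "MafRecord",
    "MafTable",
    "Dialect",
    "SDS_DIALECT",
    "read_plate",
    "write_plate",
    "read_reference_runs",
    "read_maf_table",
    "plate_to_json",
    "plate_from_json",
]

logger = logging.getLogger(__name__)

#: markers understood as "no Ct produced" in delimited inputs.  Table-style
#: exports mix ASCII hyphen-minus with typographic dashes; all are accepted.
ABSENT_MARKERS = ("", "-", "–", "—", "Undetermined", "undetermined", "NA", "N/A")

_DASHES = {"−": "-", "–": "-", "—": "-"}  # minus, en and em dash


class AssayRole(str, Enum):
    MUTANT = "mutant"
    REFERENCE = "reference"


class WellKind(str, Enum):
    SAMPLE = "sample"
    NTC = "ntc"
    POSITIVE_CONTROL = "positive_control"
    REFERENCE_STANDARD = "reference_standard"


class Material(str, Enum):
    HIGH_QUALITY = "high_quality"
    FFPE = "ffpe"
    CTDNA = "ctdna"


class Call(str, Enum):
    DETECTED = "detected"
    NOT_DETECTED = "not_detected"


def _parse_cell(raw: str, *, absent_markers: Sequence[str], where: str) -> float | None:
    """Parse one numeric cell; absent markers map to None, anything else must
    be a plain decimal number (optionally signed with -, minus or en-dash)."""
    text = raw.strip()
    if text in absent_markers:
        return None
    for dash, repl in _DASHES.items():
        text = text.replace(dash, repl)
    try:
        value = float(text)
    except ValueError:
        raise FormatError(f"non-numeric cell {raw!r} at {where}") from None
    if not math.isfinite(value):
        raise FormatError(f"non-finite cell {raw!r} at {where}")
    return value


@dataclass(frozen=True)
class WellMeasurement:
    """One amplification reaction.

    ``ct`` and ``ipc_ct`` are cycle numbers; ``None`` means the reaction never
    crossed the detection threshold within the run.
    """

    sample_id: str
    assay_role: AssayRole
    ct: float | None
    ipc_ct: float | None = None
    well_kind: WellKind = WellKind.SAMPLE
    replicate_index: int = 1
    operator_id: str | None = None
    run_id: str = ""

    def __post_init__(self) -> None:
        for name in ("ct", "ipc_ct"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v <= 0):
                raise ValueError(f"{name} must be finite and > 0 when present, got {v!r}")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")


@dataclass
class Plate:
    """An ordered set of wells from one assay run.

    Invariants (checked by :meth:`validate`, which the readers call): at least
    two no-template-control wells, and every sample measured by the mutant
    assay is also measured by the reference assay.
    """

    plate_id: str
    wells: list[WellMeasurement] = field(default_factory=list)
    run_date: _dt.date | None = None

    def validate(self) -> "Plate":
        ntc = [w for w in self.wells if w.well_kind is WellKind.NTC]
        if len(ntc) < 2:
            raise FormatError(
                f"plate {self.plate_id!r} has {len(ntc)} NTC wells; the design requires >= 2"
            )
        roles: dict[tuple[str, int], set[AssayRole]] = {}
        for w in self.wells:
            if w.well_kind is WellKind.SAMPLE:
                roles.setdefault((w.sample_id, w.replicate_index), set()).add(w.assay_role)
        for (sid, rep), seen in sorted(roles.items()):
            if seen != {AssayRole.MUTANT, AssayRole.REFERENCE}:
                missing = ({AssayRole.MUTANT, AssayRole.REFERENCE} - seen).pop()
                raise PairingError(
                    f"sample {sid!r} (replicate {rep}) lacks a {missing.value}-assay well"
                )
        return self

    def sample_ids(self) -> list[str]:
        return sorted({w.sample_id for w in self.wells if w.well_kind is WellKind.SAMPLE})

    def wells_for(self, sample_id: str, role: AssayRole) -> list[WellMeasurement]:
        out = [
            w
            for w in self.wells
            if w.sample_id == sample_id and w.assay_role is role and w.well_kind is WellKind.SAMPLE
        ]
        return sorted(out, key=lambda w: w.replicate_index)


@dataclass
class ReferenceLevelRun:
    """Replicate dCt results for one level of a DNA reference standard."""

    level_maf: float
    input_copies_per_ml: float
    delta_ct_values: list[float | None]
    material: Material

    def __post_init__(self) -> None:
        if not 0.0 <= self.level_maf <= 1.0:
            raise ValueError(f"level_maf must lie in [0, 1], got {self.level_maf}")

    @property
    def present_values(self) -> list[float]:
        return [v for v in self.delta_ct_values if v is not None]

    @property
    def n_absent(self) -> int:
        return sum(v is None for v in self.delta_ct_values)


@dataclass(frozen=True)
class MafRecord:
    """One replicate measurement paired across two quantitative methods."""

    level_expected_maf: float
    method_a_maf: float
    method_b_maf: float
    replicate_index: int
    call: Call

    def __post_init__(self) -> None:
        for name in ("level_expected_maf", "method_a_maf", "method_b_maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.replicate_index < 1:
            raise ValueError("replicate_index must be >= 1")


@dataclass
class MafTable:
    """Replicated MAF measurements across expected levels and two methods.

    ``method_a`` is the comparator method (one value per level is fine: it is
    simply repeated across that level's replicates); ``method_b`` carries the
    per-replicate values of the method under evaluation.
    """

    records: list[MafRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    def levels(self) -> list[float]:
        return sorted({r.level_expected_maf for r in self.records})


# ---------------------------------------------------------------------------
# Dialects and delimited I/O
# ---------------------------------------------------------------------------


@dataclass
class Dialect:
    """Column mapping and conventions of one delimited export layout.

    Rather than sniffing instrument exports, the layout is declared: which
    column holds what, which strings mean "no signal", and whether dCt
    columns in replicate-run tables are printed with the opposite sign of the
    stored mutant-minus-reference convention (``negated_delta_ct``).
    """

    columns: dict[str, str] = field(
        default_factory=lambda: {
            "sample_id": "sample_id",
            "assay_role": "assay_role",
            "ct": "ct",
            "ipc_ct": "ipc_ct",
            "well_kind": "well_kind",
            "replicate_index": "replicate_index",
            "operator_id": "operator_id",
            "run_id": "run_id",
        }
    )
    delimiter: str = ","
    absent_markers: tuple[str, ...] = ABSENT_MARKERS
    absent_out: str = "-"
    negated_delta_ct: bool = False

    #: columns that may be missing from a file without error
    OPTIONAL = ("replicate_index", "operator_id", "run_id", "ipc_ct")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "Dialect":
        kwargs = dict(data)
        if "absent_markers" in kwargs:
            kwargs["absent_markers"] = tuple(kwargs["absent_markers"])
        if "columns" in kwargs:
            base = cls().columns
            base.update(kwargs["columns"])
            kwargs["columns"] = base
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Dialect":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})

    @classmethod
    def from_json(cls, path: str | Path) -> "Dialect":
        with open(path) as fh:
            return cls.from_mapping(json.load(fh))


#: Layout mimicking a Sequence-Detection-System style export (one row per
#: well, "Undetermined" for censored reactions).
SDS_DIALECT = Dialect()


def _read_table(path: str | Path, delimiter: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, encoding="utf-8")


def read_plate(path: str | Path, dialect: Dialect = SDS_DIALECT) -> Plate:
    """Read a plate export into a validated :class:`Plate`.

    Raises :class:`FormatError` for missing required columns or unparsable
    cells, :class:`PairingError` when a sample's mutant-assay well has no
    reference-assay partner.
    """
    df = _read_table(path, dialect.delimiter)
    cols = dialect.columns
    required = ("sample_id", "assay_role", "ct", "well_kind")
    for key in required:
        if cols[key] not in df.columns:
            raise FormatError(f"required column {cols[key]!r} (for {key}) missing from {path}")

    wells: list[WellMeasurement] = []
    n_absent = 0
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}"  # 1-based with header
        ct = _parse_cell(row[cols["ct"]], absent_markers=dialect.absent_markers, where=f"{where} col {cols['ct']}")
        if ct is None:
            n_absent += 1
        ipc = None
        if cols["ipc_ct"] in df.columns:
            ipc = _parse_cell(
                row[cols["ipc_ct"]], absent_markers=dialect.absent_markers, where=f"{where} col {cols['ipc_ct']}"
            )
        rep = 1
        if cols["replicate_index"] in df.columns and row[cols["replicate_index"]].strip():
            rep = int(row[cols["replicate_index"]])
        wells.append(
            WellMeasurement(
                sample_id=row[cols["sample_id"]].strip(),
                assay_role=AssayRole(row[cols["assay_role"]].strip().lower()),
                ct=ct,
                ipc_ct=ipc,
                well_kind=WellKind(row[cols["well_kind"]].strip().lower()),
                replicate_index=rep,
                operator_id=(row[cols["operator_id"]].strip() or None)
                if cols["operator_id"] in df.columns
                else None,
                run_id=row[cols["run_id"]].strip() if cols["run_id"] in df.columns else "",
            )
        )
    if n_absent:
        logger.info("read_plate(%s): %d wells with no Ct signal", path, n_absent)
    return Plate(plate_id=str(Path(path).stem), wells=wells).validate()


def write_plate(plate: Plate, path: str | Path, dialect: Dialect = SDS_DIALECT) -> None:
    """Write a plate back to the delimited layout described by *dialect*.

    Absent Ct values are written as ``dialect.absent_out`` so a read/write
    round trip preserves the absent state exactly.
    """
    cols = dialect.columns
    rows = []
    for w in plate.wells:
        rows.append(
            {
                cols["sample_id"]: w.sample_id,
                cols["assay_role"]: w.assay_role.value,
                cols["ct"]: dialect.absent_out if w.ct is None else repr(w.ct),
                cols["ipc_ct"]: dialect.absent_out if w.ipc_ct is None else repr(w.ipc_ct),
                cols["well_kind"]: w.well_kind.value,
                cols["replicate_index"]: w.replicate_index,
                cols["operator_id"]: w.operator_id or "",
                cols["run_id"]: w.run_id,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=dialect.delimiter, index=False, encoding="utf-8")


def read_reference_runs(
    path: str | Path, dialect: Dialect = SDS_DIALECT
) -> list[ReferenceLevelRun]:
    """Read a replicate reference-standard run table.

    Expected columns: ``material``, ``maf_percent``, ``copies_per_ml`` and one
    ``run_<k>`` column per attempted run.  Absent cells (no mutant-assay Ct,
    so no dCt) are preserved as ``None``.  Levels are returned ordered by MAF
    descending within material.  If ``dialect.negated_delta_ct`` is set the
    sign of every dCt is flipped on read to restore the stored
    mutant-minus-reference convention.
    """
    df = _read_table(path, dialect.delimiter)
    for col in ("material", "maf_percent", "copies_per_ml"):
        if col not in df.columns:
            raise FormatError(f"required column {col!r} missing from {path}")
    run_cols = [c for c in df.columns if c.startswith("run_")]
    if not run_cols:
        raise FormatError(f"no run_<k> columns found in {path}")
    run_cols.sort(key=lambda c: int(c.split("_", 1)[1]))

    sign = -1.0 if dialect.negated_delta_ct else 1.0
    runs: list[ReferenceLevelRun] = []
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}"
        values: list[float | None] = []
        for c in run_cols:
            v = _parse_cell(row[c], absent_markers=dialect.absent_markers, where=f"{where} col {c}")
            values.append(None if v is None else sign * v)
        maf = _parse_cell(row["maf_percent"], absent_markers=("",), where=f"{where} col maf_percent")
        copies = _parse_cell(row["copies_per_ml"], absent_markers=("",), where=f"{where} col copies_per_ml")
        if maf is None or copies is None:
            raise FormatError(f"maf_percent/copies_per_ml empty at {where}")
        runs.append(
            ReferenceLevelRun(
                level_maf=maf / 100.0,
                input_copies_per_ml=copies,
                delta_ct_values=values,
                material=Material(row["material"].strip().lower()),
            )
        )
    runs.sort(key=lambda r: (r.material.value, -r.level_maf, r.input_copies_per_ml))
    return runs


def read_maf_table(path: str | Path, dialect: Dialect = SDS_DIALECT) -> MafTable:
    """Read a cross-method MAF table (percent columns on disk, fractions in
    memory).  Expected columns: ``level_expected_maf_pct``, ``method_a_maf_pct``,
    ``method_b_maf_pct``, ``replicate_index``, ``call``."""
    df = _read_table(path, dialect.delimiter)
    required = (
        "level_expected_maf_pct",
        "method_a_maf_pct",
        "method_b_maf_pct",
        "replicate_index",
        "call",
    )
    for col in required:
        if col not in df.columns:
            raise FormatError(f"required column {col!r} missing from {path}")
    records = []
    for i, row in df.iterrows():
        where = f"{path} row {i + 2}"
        vals = {}
        for col in required[:3]:
            v = _parse_cell(row[col], absent_markers=("",), where=f"{where} col {col}")
            if v is None:
                raise FormatError(f"empty MAF cell at {where} col {col}")
            vals[col] = v / 100.0
        records.append(
            MafRecord(
                level_expected_maf=vals["level_expected_maf_pct"],
                method_a_maf=vals["method_a_maf_pct"],
                method_b_maf=vals["method_b_maf_pct"],
                replicate_index=int(row["replicate_index"]),
                call=Call(row["call"].strip().lower()),
            )
        )
    return MafTable(records=records)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------


def plate_to_json(plate: Plate) -> str:
    payload = {
        "plate_id": plate.plate_id,
        "run_date": plate.run_date.isoformat() if plate.run_date else None,
        "wells": [
            {
                "sample_id": w.sample_id,
                "assay_role": w.assay_role.value,
                "ct": w.ct,
                "ipc_ct": w.ipc_ct,
                "well_kind": w.well_kind.value,
                "replicate_index": w.replicate_index,
                "operator_id": w.operator_id,
                "run_id": w.run_id,
            }
            for w in plate.wells
        ],
    }
    return json.dumps(payload, indent=2)


def plate_from_json(text: str) -> Plate:
    payload = json.loads(text)
    wells = [
        WellMeasurement(
            sample_id=w["sample_id"],
            assay_role=AssayRole(w["assay_role"]),
            ct=w["ct"],
            ipc_ct=w["ipc_ct"],
            well_kind=WellKind(w["well_kind"]),
            replicate_index=w["replicate_index"],
            operator_id=w.get("operator_id"),
            run_id=w.get("run_id", ""),
        )
        for w in payload["wells"]
    ]
    run_date = _dt.date.fromisoformat(payload["run_date"]) if payload.get("run_date") else None
    return Plate(plate_id=payload["plate_id"], wells=wells, run_date=run_date)
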