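"""Readers and writers for the delimited tables the pipeline consumes.

Two table families are supported:

* **Viability tables** — one row per well of a CellTiter-Glo style plate
  readout, annotated with cell line, primary (pretreatment) drug and dose,
  secondary drug dose, schedule and replicate.
* **Differential-expression tables** — one row per gene with control/treated
  FPKM, log2 fold change, p-value and FDR, either in a simple ``generic``
  dialect or in the Cuffdiff ``gene_exp.diff`` dialect.

Parsing is bit-faithful plumbing: no science happens here.  Infinite fold
changes (a gene going from 0 FPKM to a positive FPKM, or vice versa) are
round-tripped as the literal strings ``inf`` / ``-inf``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PlateRecord",
    "DERecord",
    "TableFormatError",
    "TableValidationError",
    "read_viability_table",
    "write_viability_table",
    "read_de_table",
    "write_de_table",
]


class TableFormatError(ValueError):
    """A table is structurally malformed (missing column, bad cell)."""


class TableValidationError(ValueError):
    """A table parsed but violates a domain invariant (negative dose...)."""


VIABILITY_COLUMNS = [
    "cell_line",
    "primary_drug",
    "primary_dose_uM",
    "secondary_drug",
    "secondary_dose_nM",
    "schedule",
    "replicate",
    "signal",
]

DE_COLUMNS = ["gene_id", "fpkm_control", "fpkm_treated", "log2_fc", "p_value", "fdr"]

# column mapping for Cuffdiff gene_exp.diff output
_CUFFDIFF_MAP = {
    "gene_id": "gene_id",
    "value_1": "fpkm_control",
    "value_2": "fpkm_treated",
    "log2(fold_change)": "log2_fc",
    "p_value": "p_value",
    "q_value": "fdr",
}


@dataclass(frozen=True)
class PlateRecord:
    """A single well measurement.

    ``primary`` refers to the pretreatment drug (EZH2 inhibitor), dosed in
    µM; ``secondary`` to the drug whose dose–response is being traced
    (panobinostat), dosed in nM.  ``signal`` is raw luminescence unless
    ``is_normalized`` is set, in which case it is already a viability
    fraction.
    """

    cell_line: str
    primary_drug: str | None
    primary_dose: float  # µM
    secondary_drug: str | None
    secondary_dose: float  # nM
    schedule: str
    replicate: int
    signal: float
    is_normalized: bool = False

    def __post_init__(self) -> None:
        if self.primary_dose < 0 or self.secondary_dose < 0:
            raise TableValidationError(
                f"negative dose in record for {self.cell_line!r}"
            )
        if self.signal < 0:
            raise TableValidationError(
                f"negative signal in record for {self.cell_line!r}"
            )
        if self.replicate < 1:
            raise TableValidationError("replicate index must be >= 1")


@dataclass(frozen=True)
class DERecord:
    """One gene's differential-expression measurement for one condition.

    ``log2_fc`` may be ``±inf`` when one FPKM value is exactly zero.  The
    ``p_value`` and ``fdr`` columns are carried independently, exactly as
    emitted by upstream tools (no ``fdr >= p_value`` check is imposed).
    """

    gene_id: str
    fpkm_control: float
    fpkm_treated: float
    log2_fc: float
    p_value: float
    fdr: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.fpkm_control < 0 or self.fpkm_treated < 0:
            raise TableValidationError(f"negative FPKM for gene {self.gene_id!r}")
        for name, v in (("p_value", self.p_value), ("fdr", self.fdr)):
            if not (0.0 <= v <= 1.0):
                raise TableValidationError(
                    f"{name}={v} outside [0,1] for gene {self.gene_id!r}"
                )
        if self.fpkm_control > 0 and self.fpkm_treated > 0 and math.isfinite(self.log2_fc):
            expected = math.log2(self.fpkm_treated / self.fpkm_control)
            if abs(expected - self.log2_fc) > 1e-6:
                raise TableValidationError(
                    f"log2_fc={self.log2_fc} inconsistent with FPKM ratio "
                    f"({expected:.8f}) for gene {self.gene_id!r}"
                )


def _sniff_delimiter(path: Path, override: str | None) -> str:
    if override is not None:
        return override
    with open(path, "r", encoding="utf-8") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") and "\t" in head else ","


def _parse_float(cell: str, *, row: int, column: str) -> float:
    """Parse a numeric cell, accepting 'inf'/'-inf' spellings."""
    text = cell.strip()
    try:
        return float(text)  # float() accepts 'inf', '-inf', 'nan'
    except ValueError:
        raise TableFormatError(
            f"unparseable numeric value {cell!r} at row {row}, column {column!r}"
        ) from None


def read_viability_table(
    path: str | Path,
    *,
    delimiter: str | None = None,
    normalized: bool | None = None,
) -> list[PlateRecord]:
    """Read a viability plate table into :class:`PlateRecord` rows.

    Column order/naming follows the viability dialect: ``cell_line,
    primary_drug, primary_dose_uM, secondary_drug, secondary_dose_nM,
    schedule, replicate, signal``.  An optional ``is_normalized`` column (or
    a ``viability`` column in place of ``signal``) marks pre-normalized
    fractions; ``normalized`` overrides per-file detection.
    """
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        fields = reader.fieldnames or []
        signal_col = "signal" if "signal" in fields else (
            "viability" if "viability" in fields else None
        )
        required = [c for c in VIABILITY_COLUMNS if c != "signal"]
        for col in required:
            if col not in fields:
                raise TableFormatError(f"missing mandatory column {col!r} in {path}")
        if signal_col is None:
            raise TableFormatError(f"missing mandatory column 'signal' in {path}")
        file_normalized = signal_col == "viability"
        records: list[PlateRecord] = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            primary = row["primary_drug"].strip() or None
            secondary = row["secondary_drug"].strip() or None
            if primary in ("", "none", "NA"):
                primary = None
            if secondary in ("", "none", "NA"):
                secondary = None
            p_dose = _parse_float(row["primary_dose_uM"], row=i, column="primary_dose_uM")
            s_dose = _parse_float(row["secondary_dose_nM"], row=i, column="secondary_dose_nM")
            if p_dose < 0 or s_dose < 0:
                raise TableValidationError(f"negative dose at row {i} of {path}")
            sig = _parse_float(row[signal_col], row=i, column=signal_col)
            if sig < 0:
                raise TableValidationError(f"negative signal at row {i} of {path}")
            is_norm = file_normalized
            if "is_normalized" in row and row["is_normalized"].strip() != "":
                is_norm = row["is_normalized"].strip().lower() in ("1", "true", "yes")
            if normalized is not None:
                is_norm = normalized
            records.append(
                PlateRecord(
                    cell_line=row["cell_line"].strip(),
                    primary_drug=primary,
                    primary_dose=p_dose,
                    secondary_drug=secondary,
                    secondary_dose=s_dose,
                    schedule=row["schedule"].strip(),
                    replicate=int(row["replicate"]),
                    signal=sig,
                    is_normalized=is_norm,
                )
            )
    return records


def write_viability_table(
    records: Iterable[PlateRecord], path: str | Path, *, delimiter: str = ","
) -> None:
    rows = [
        {
            "cell_line": r.cell_line,
            "primary_drug": r.primary_drug or "",
            "primary_dose_uM": repr(r.primary_dose),
            "secondary_drug": r.secondary_drug or "",
            "secondary_dose_nM": repr(r.secondary_dose),
            "schedule": r.schedule,
            "replicate": r.replicate,
            "signal": repr(r.signal),
            "is_normalized": str(r.is_normalized).lower(),
        }
        for r in records
    ]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=VIABILITY_COLUMNS + ["is_normalized"], delimiter=delimiter
        )
        writer.writeheader()
        writer.writerows(rows)


def _fmt_log2fc(v: float) -> str:
    if math.isinf(v):
        return "inf" if v > 0 else "-inf"
    return repr(v)


def read_de_table(
    path: str | Path,
    dialect: str = "generic",
    *,
    delimiter: str | None = None,
    condition: str = "",
) -> list[DERecord]:
    """Read a differential-expression table.

    ``dialect`` is ``"generic"`` (columns ``gene_id, fpkm_control,
    fpkm_treated, log2_fc, p_value, fdr``) or ``"cuffdiff"`` (a
    ``gene_exp.diff`` file; ``value_1``/``value_2`` are taken as
    control/treated FPKM and ``q_value`` as the FDR).  Duplicate gene ids
    keep the first occurrence and log a warning.
    """
    if dialect not in ("generic", "cuffdiff"):
        raise ValueError(f"unknown DE table dialect {dialect!r}")
    path = Path(path)
    delim = _sniff_delimiter(path, delimiter)
    colmap = _CUFFDIFF_MAP if dialect == "cuffdiff" else {c: c for c in DE_COLUMNS}
    records: list[DERecord] = []
    seen: set[str] = set()
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        fields = reader.fieldnames or []
        for src in colmap:
            if src not in fields:
                raise TableFormatError(f"missing mandatory column {src!r} in {path}")
        for i, row in enumerate(reader, start=2):
            vals = {dst: row[src] for src, dst in colmap.items()}
            gene = vals["gene_id"].strip()
            if gene in seen:
                logger.warning("duplicate gene_id %r at row %d of %s; keeping first", gene, i, path)
                continue
            seen.add(gene)
            records.append(
                DERecord(
                    gene_id=gene,
                    fpkm_control=_parse_float(vals["fpkm_control"], row=i, column="fpkm_control"),
                    fpkm_treated=_parse_float(vals["fpkm_treated"], row=i, column="fpkm_treated"),
                    log2_fc=_parse_float(vals["log2_fc"], row=i, column="log2_fc"),
                    p_value=_parse_float(vals["p_value"], row=i, column="p_value"),
                    fdr=_parse_float(vals["fdr"], row=i, column="fdr"),
                    condition=condition,
                )
            )
    return records


def write_de_table(
    records: Iterable[DERecord], path: str | Path, *, delimiter: str = "\t"
) -> None:
    """Write records in the generic dialect; round-trips :func:`read_de_table`."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(DE_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.gene_id,
                    repr(r.fpkm_control),
                    repr(r.fpkm_treated),
                    _fmt_log2fc(r.log2_fc),
                    repr(r.p_value),
                    repr(r.fdr),
                ]
            )


def de_records_to_frame(records: Sequence[DERecord]) -> pd.DataFrame:
    """Convenience view of DE records as a pandas DataFrame."""
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "fpkm_control": [r.fpkm_control for r in records],
            "fpkm_treated": [r.fpkm_treated for r in records],
            "log2_fc": [r.log2_fc for r in records],
            "p_value": [r.p_value for r in records],
            "fdr": [r.fdr for r in records],
            "condition": [r.condition for r in records],
        }
    )
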