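"""Per-complex energy-component tables: loading, validation, subsetting.

A *dataset* is an ordered collection of PDZ:peptide complex records.  Each
record carries the relative (reference-subtracted) energy components produced
by continuum-electrostatics post-processing of an MD trajectory of the bound
complex -- the PB electrostatic binding term, the protein-peptide van der
Waals interaction energy, the change in molecular surface upon binding -- plus
the mean restraint energy of the simulation, the experimental relative binding
free energy (when measured), and the reference complex the record is scored
against.  Two reference complexes exist in the packaged data: the wildtype
Tiam1 PDZ bound to the Syndecan-1 peptide (group ``sdc1``) and the
quadruple-mutant PDZ bound to Caspr4 (group ``caspr4``).

The packaged fixtures are verbatim transcriptions of the published component
tables: ``table1.csv`` (37 complexes, 35 of them in the fitting set),
``table2.csv`` (14 held-out or prediction-only complexes) and ``table5.csv``
(folded fractions of unbound peptides from duplicate MD runs).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "ComplexRecord",
    "Dataset",
    "SchemaError",
    "ValidationError",
    "load_dataset",
    "write_dataset",
    "load_table1",
    "load_table2",
    "load_table5",
    "fitting_subset",
    "reference_records",
    "REQUIRED_COLUMNS",
]

REQUIRED_COLUMNS = (
    "complex_id",
    "reference_group",
    "in_fit",
    "exp_ddg",
    "exp_is_lower_bound",
    "pb",
    "vdw",
    "sa",
    "restraint",
)

OPTIONAL_COLUMNS = (
    "printed_comp_ddg",
    "printed_uncertainty",
    "printed_correction",
)

KNOWN_GROUPS = ("sdc1", "caspr4")


class SchemaError(ValueError):
    """Header of a component table does not match the expected schema."""


class ValidationError(ValueError):
    """A row violates a dataset invariant; message carries the row number."""


@dataclass(frozen=True)
class ComplexRecord:
    """One PDZ:peptide complex and its energy components.

    Energies are in kcal/mol; the surface change ``sa`` is in Angstrom^2.
    ``exp_ddg`` is the experimental binding free energy relative to the
    group's reference complex, or ``None`` for prediction-only records.
    ``printed_*`` fields are the values printed in the source tables and are
    used only for regression checks, never inside any fit.
    """

    complex_id: str
    reference_group: str = "sdc1"
    in_fit: bool = False
    exp_ddg: float | None = None
    exp_is_lower_bound: bool = False
    pb: float = 0.0
    vdw: float = 0.0
    sa: float = 0.0
    restraint: float = 0.0
    printed_comp_ddg: float | None = None
    printed_uncertainty: float | None = None
    printed_correction: float | None = None


@dataclass
class Dataset:
    """Ordered, validated collection of :class:`ComplexRecord`."""

    records: tuple[ComplexRecord, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.records = tuple(self.records)
        _validate(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ComplexRecord]:
        return iter(self.records)

    def __getitem__(self, complex_id: str) -> ComplexRecord:
        for rec in self.records:
            if rec.complex_id == complex_id:
                return rec
        raise KeyError(complex_id)

    def to_frame(self) -> pd.DataFrame:
        """Records as a pandas DataFrame (one row per complex)."""
        cols = [f.name for f in fields(ComplexRecord)]
        return pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in self.records],
            columns=cols,
        )

    def subset(self, predicate) -> "Dataset":
        return Dataset(
            tuple(r for r in self.records if predicate(r)),
            provenance=self.provenance,
        )


def _parse_bool(text: str, row: int, column: str) -> bool:
    t = text.strip().lower()
    if t in {"true", "1", "yes"}:
        return True
    if t in {"false", "0", "no", ""}:
        return False
    raise ValidationError(f"row {row}: column {column!r}: not a boolean: {text!r}")


def _parse_float(text: str, row: int, column: str) -> float | None:
    t = text.strip().replace("−", "-")  # tolerate Unicode minus
    if t in {"", "NA", "na", "nan"}:
        return None
    try:
        return float(t)
    except ValueError as exc:
        raise ValidationError(
            f"row {row}: column {column!r}: not a number: {text!r}"
        ) from exc


def _validate(records: Iterable[ComplexRecord]) -> None:
    seen: set[str] = set()
    for i, rec in enumerate(records, start=1):
        if rec.complex_id in seen:
            raise ValidationError(f"row {i}: duplicate complex_id {rec.complex_id!r}")
        seen.add(rec.complex_id)
        if rec.exp_is_lower_bound and rec.exp_ddg is None:
            raise ValidationError(
                f"row {i} ({rec.complex_id}): lower-bound flag without exp_ddg"
            )
        if rec.in_fit and rec.exp_ddg is None:
            raise ValidationError(
                f"row {i} ({rec.complex_id}): in_fit record lacks exp_ddg"
            )
        if rec.restraint < 0:
            raise ValidationError(
                f"row {i} ({rec.complex_id}): negative restraint energy"
            )
        for col in ("pb", "vdw", "sa", "restraint"):
            v = getattr(rec, col)
            if v is None or not math.isfinite(v):
                raise ValidationError(
                    f"row {i} ({rec.complex_id}): non-finite {col!r}"
                )


def load_dataset(path: str | Path, provenance: str | None = None) -> Dataset:
    """Load and validate a component table in the packaged CSV schema.

    Raises :class:`SchemaError` when a required column is missing and
    :class:`ValidationError` (with the offending row number) when a row is
    malformed or an invariant is violated.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path.name}: missing column(s): {', '.join(missing)}")
        records = []
        for i, row in enumerate(reader, start=1):
            records.append(
                ComplexRecord(
                    complex_id=row["complex_id"].strip(),
                    reference_group=row["reference_group"].strip(),
                    in_fit=_parse_bool(row["in_fit"], i, "in_fit"),
                    exp_ddg=_parse_float(row["exp_ddg"], i, "exp_ddg"),
                    exp_is_lower_bound=_parse_bool(
                        row["exp_is_lower_bound"], i, "exp_is_lower_bound"
                    ),
                    pb=_parse_float(row["pb"], i, "pb"),
                    vdw=_parse_float(row["vdw"], i, "vdw"),
                    sa=_parse_float(row["sa"], i, "sa"),
                    restraint=_parse_float(row["restraint"], i, "restraint"),
                    printed_comp_ddg=_parse_float(
                        row.get("printed_comp_ddg", ""), i, "printed_comp_ddg"
                    ),
                    printed_uncertainty=_parse_float(
                        row.get("printed_uncertainty", ""), i, "printed_uncertainty"
                    ),
                    printed_correction=_parse_float(
                        row.get("printed_correction", ""), i, "printed_correction"
                    ),
                )
            )
    return Dataset(tuple(records), provenance=provenance or str(path))


_FLOAT2 = ("exp_ddg", "pb", "vdw", "sa", "restraint", "printed_comp_ddg",
           "printed_correction")


def _format_cell(rec: ComplexRecord, col: str) -> str:
    v = getattr(rec, col)
    if col in ("in_fit", "exp_is_lower_bound"):
        return "True" if v else "False"
    if v is None:
        return ""
    if col in _FLOAT2:
        return f"{v:.2f}"
    if col == "printed_uncertainty":
        return f"{v:.1f}"
    return str(v)


def write_dataset(ds: Dataset, path: str | Path) -> None:
    """Write a dataset back to CSV in the packaged-fixture format.

    ``write(load(x))`` is byte-identical for the packaged tables (two-decimal
    components, ASCII minus, minimal quoting).
    """
    cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(cols)
        for rec in ds.records:
            writer.writerow([_format_cell(rec, c) for c in cols])


def _packaged(name: str) -> Path:
    return Path(str(resources.files("pdzlie").joinpath("data", name)))


def load_table1() -> Dataset:
    """The 37-complex fitting table (35 in-fit records plus two references)."""
    return load_dataset(_packaged("table1.csv"), provenance="table1")


def load_table2() -> Dataset:
    """The 14 held-out / prediction-only complexes."""
    return load_dataset(_packaged("table2.csv"), provenance="table2")


def load_table5() -> pd.DataFrame:
    """Folded fractions of unbound peptides from duplicate MD runs.

    Columns: ``peptide_id``, ``folded_pct_run1``, ``folded_pct_run2`` (percent
    of frames in the extended, binding-competent conformation), the printed
    preorganization free energy and uncertainty (kcal/mol, regression use
    only), and the length of each run in ns.
    """
    return pd.read_csv(_packaged("table5.csv"))


def reference_records(ds: Dataset) -> dict[str, ComplexRecord]:
    """Identify the reference complex of each reference group.

    The reference is the unique record of its group that is outside the
    fitting set yet carries an experimental value (its residual is zero by
    construction, so it is not an independent observation).  Raises
    :class:`ValidationError` when a group's reference is absent or ambiguous.
    """
    out: dict[str, ComplexRecord] = {}
    for group in sorted({r.reference_group for r in ds.records}):
        candidates = [
            r
            for r in ds.records
            if r.reference_group == group and not r.in_fit and r.exp_ddg is not None
        ]
        if len(candidates) != 1:
            raise ValidationError(
                f"reference for group {group!r} is "
                f"{'absent' if not candidates else 'ambiguous'} "
                f"({len(candidates)} candidates)"
            )
        out[group] = candidates[0]
    return out


def fitting_subset(ds: Dataset) -> Dataset:
    """Records entering the least-squares fit.

    Keeps in-fit records only; reference complexes are excluded (they are
    flagged out of the fitting set in the packaged tables, and are dropped
    here even if a caller marks one in-fit by mistake).
    """
    try:
        refs = reference_records(ds)
        ref_ids = {r.complex_id for r in refs.values()}
    except ValidationError:
        ref_ids = set()
    return ds.subset(lambda r: r.in_fit and r.complex_id not in ref_ids)
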