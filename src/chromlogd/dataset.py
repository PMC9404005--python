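"""Compound tables: typed records, CSV/TSV round-trip, and the packaged reference set.

The central container is :class:`CompoundSet`, an ordered, id-indexed
collection of :class:`CompoundRecord`. The packaged reference table holds 73
solutes measured on a silica-based C18 column at mobile-phase pH 7.0: 26
neutral compounds (N1-N26), 33 carboxylic/phenolic acids (W1-W33) and 14
sulfonic acids (S1-S14), each with literature log P and pKa where available,
the apparent distribution coefficient log D at pH 7.0, extrapolated
100%-aqueous retention (log k_w) under ion-suppression (IS) and ion-pair (IP)
conditions, and the solute descriptors n_e (net static charge), A (H-bond
acidity) and B (H-bond basicity).

Missing values are explicit: the source table writes ``NA`` where no
literature value exists and ``/`` where a quantity was not measurable (e.g.
log k_w-IS for solutes unretained without ion-pair reagent). Both parse to
``None`` and the original token is kept as provenance.
"""

from __future__ import annotations

import csv
import importlib.resources
import math
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .errors import (
    DataQualityWarning,
    DuplicateIdError,
    TableParseError,
    UnknownIdError,
)

__all__ = [
    "CompoundClass",
    "CompoundRecord",
    "CompoundSet",
    "read_compound_table",
    "write_compound_table",
    "select_by_ids",
    "load_reference_table",
    "with_swapped_retention",
    "MISSING_TOKENS",
]

#: Tokens accepted as "missing" on read. The empty cell is what we emit on write.
MISSING_TOKENS = ("NA", "/", "")

_COLUMNS = (
    "id",
    "name",
    "class",
    "log_p",
    "pka",
    "log_d_ref",
    "log_kw_is",
    "log_kw_ip",
    "n_e",
    "a",
    "b",
)

_NUMERIC_FIELDS = (
    "log_p",
    "pka",
    "log_d_ref",
    "log_kw_is",
    "log_kw_ip",
    "n_e",
    "a",
    "b",
)


class CompoundClass(str, Enum):
    """Solute ionization class at the working pH."""

    NEUTRAL = "neutral"
    WEAK_ACID = "carboxylic_or_phenolic_acid"
    SULFONIC = "sulfonic_acid"


@dataclass(frozen=True)
class CompoundRecord:
    """One solute row: identity, ionization class, descriptors, reference values.

    ``missing_tokens`` maps a field name to the raw token ("NA" or "/") that
    produced its ``None``, preserving the distinction between *no literature
    value* and *not measurable*. ``notes`` carries free-text data-quality
    annotations (kept out of the numeric schema).
    """

    id: str
    name: str
    compound_class: CompoundClass
    log_p: float | None = None
    pka: float | None = None
    log_d_ref: float | None = None
    log_kw_is: float | None = None
    log_kw_ip: float | None = None
    n_e: float = 0.0
    a: float = 0.0
    b: float = 0.0
    missing_tokens: Mapping[str, str] = field(default_factory=dict, compare=False)
    notes: tuple[str, ...] = field(default=(), compare=False)

    def get(self, field_name: str) -> float | None:
        """Numeric field access by name (used to build regression designs)."""
        if field_name not in _NUMERIC_FIELDS:
            raise KeyError(f"{field_name!r} is not a numeric descriptor field")
        return getattr(self, field_name)


@dataclass(frozen=True)
class CompoundSet:
    """Ordered collection of compound records sharing one mobile-phase pH."""

    records: tuple[CompoundRecord, ...]
    ph: float = 7.0

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.id in seen:
                raise DuplicateIdError(f"duplicate compound id {rec.id!r}")
            seen.add(rec.id)
        for rec in self.records:
            if (
                rec.compound_class is CompoundClass.NEUTRAL
                and rec.log_kw_is is not None
                and rec.log_kw_ip is not None
                and not math.isclose(rec.log_kw_is, rec.log_kw_ip, abs_tol=1e-12)
            ):
                warnings.warn(
                    f"neutral compound {rec.id}: log_kw_is ({rec.log_kw_is}) != "
                    f"log_kw_ip ({rec.log_kw_ip}); ion-pair reagent should not "
                    "affect neutral retention",
                    DataQualityWarning,
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CompoundRecord]:
        return iter(self.records)

    def __contains__(self, compound_id: str) -> bool:
        return any(r.id == compound_id for r in self.records)

    def __getitem__(self, compound_id: str) -> CompoundRecord:
        for rec in self.records:
            if rec.id == compound_id:
                return rec
        raise UnknownIdError(f"unknown compound id {compound_id!r}")

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def by_class(self, compound_class: CompoundClass) -> "CompoundSet":
        return CompoundSet(
            tuple(r for r in self.records if r.compound_class is compound_class),
            ph=self.ph,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular view; missing values as NaN. Row order preserved."""
        rows = []
        for r in self.records:
            row = {"id": r.id, "name": r.name, "class": r.compound_class.value}
            for f in _NUMERIC_FIELDS:
                v = getattr(r, f)
                row[f] = float("nan") if v is None else v
            rows.append(row)
        return pd.DataFrame(rows, columns=list(_COLUMNS))


def _parse_cell(token: str, row_no: int, column: str) -> float | None:
    token = token.strip()
    if token in MISSING_TOKENS:
        return None
    try:
        return float(token)
    except ValueError:
        raise TableParseError(
            f"row {row_no}, column {column!r}: cannot parse {token!r} as a number"
        ) from None


def read_compound_table(path: str | Path, dialect: str = "csv") -> CompoundSet:
    """Read a compound table from CSV or TSV.

    Expects the documented header ``id,name,class,log_p,...,b``. ``NA``, ``/``
    and the empty cell all parse as missing, with the raw token recorded per
    field in ``missing_tokens``. Row order is preserved.
    """
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    sep = "," if dialect == "csv" else "\t"
    records: list[CompoundRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        if reader.fieldnames is None or tuple(reader.fieldnames) != _COLUMNS:
            raise TableParseError(
                f"{path}: header {reader.fieldnames} does not match the "
                f"expected schema {list(_COLUMNS)}"
            )
        for row_no, row in enumerate(reader, start=2):
            try:
                compound_class = CompoundClass(row["class"].strip())
            except ValueError:
                raise TableParseError(
                    f"row {row_no}, column 'class': unknown class {row['class']!r}"
                ) from None
            values: dict[str, float | None] = {}
            tokens: dict[str, str] = {}
            for f in _NUMERIC_FIELDS:
                raw = row[f]
                values[f] = _parse_cell(raw, row_no, f)
                if values[f] is None:
                    tokens[f] = raw.strip()
            records.append(
                CompoundRecord(
                    id=row["id"].strip(),
                    name=row["name"],
                    compound_class=compound_class,
                    missing_tokens=tokens,
                    **values,
                )
            )
    return CompoundSet(tuple(records))


def write_compound_table(
    cset: CompoundSet, path: str | Path, dialect: str = "csv"
) -> None:
    """Write a compound table; missing values become empty cells."""
    sep = "," if dialect == "csv" else "\t"
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(_COLUMNS)
        for r in cset.records:
            row: list[str] = [r.id, r.name, r.compound_class.value]
            for f in _NUMERIC_FIELDS:
                v = getattr(r, f)
                row.append("" if v is None else repr(v))
            writer.writerow(row)


def select_by_ids(cset: CompoundSet, ids: Sequence[str]) -> CompoundSet:
    """Subset in the requested order.

    Duplicate requests are rejected so that training-set sizes stay auditable;
    an unknown id raises naming the id.
    """
    seen: set[str] = set()
    for cid in ids:
        if cid in seen:
            raise DuplicateIdError(f"id {cid!r} requested more than once")
        seen.add(cid)
    return CompoundSet(tuple(cset[cid] for cid in ids), ph=cset.ph)


# Rows whose printed log k_w values are mutually inconsistent with their log P
# (anisole cannot out-retain pentabromotoluene on C18); see with_swapped_retention.
SUSPECT_TRANSPOSED_IDS = ("N5", "N6")


def with_swapped_retention(
    cset: CompoundSet, id_a: str = "N5", id_b: str = "N6"
) -> CompoundSet:
    """Return a copy with the log k_w values of two rows exchanged.

    The packaged reference table stores rows N5 (anisole) and N6 (benzyl
    chloride) exactly as published, but their log k_w entries are transposed:
    anisole (log P 2.11) is printed with log k_w 5.60 while the far more
    hydrophobic row carries 2.64, and only the exchanged pairing is consistent
    with the Collander-type log k_w ~ log P trend the rest of the table
    follows — and with the published regression models. This repair is applied
    by default in the cascade and can be switched off to fit the table
    exactly as printed.
    """
    rec_a, rec_b = cset[id_a], cset[id_b]
    note = f"log k_w values exchanged with {{}} (transposition repair)"
    new_a = replace(
        rec_a,
        log_kw_is=rec_b.log_kw_is,
        log_kw_ip=rec_b.log_kw_ip,
        notes=rec_a.notes + (note.format(id_b),),
    )
    new_b = replace(
        rec_b,
        log_kw_is=rec_a.log_kw_is,
        log_kw_ip=rec_a.log_kw_ip,
        notes=rec_b.notes + (note.format(id_a),),
    )
    swapped = {id_a: new_a, id_b: new_b}
    return CompoundSet(
        tuple(swapped.get(r.id, r) for r in cset.records), ph=cset.ph
    )


_DATA_QUALITY_NOTES: dict[str, str] = {
    "N5": "printed log k_w (5.60) inconsistent with log P 2.11; "
    "suspected transposition with N6",
    "N6": "printed log k_w (2.64) inconsistent with log P 5.50; "
    "suspected transposition with N5",
}


def load_reference_table() -> CompoundSet:
    """Load the packaged 73-compound reference table (values as published).

    Rows N5 and N6 carry data-quality notes flagging their suspected log k_w
    transposition; the values themselves are left exactly as printed. Use
    :func:`with_swapped_retention` (the cascade default) for the repaired set.
    """
    resource = importlib.resources.files("chromlogd.data").joinpath("table1.csv")
    with importlib.resources.as_file(resource) as path:
        cset = read_compound_table(path, dialect="csv")
    records = tuple(
        replace(r, notes=r.notes + (_DATA_QUALITY_NOTES[r.id],))
        if r.id in _DATA_QUALITY_NOTES
        else r
        for r in cset.records
    )
    return CompoundSet(records, ph=7.0)


def load_software_logd() -> dict[str, float]:
    """ACD/Labs-calculated log D_7.0 comparison values for the ionized solutes.

    These are never used in any fit; they populate the software-comparison
    column of prediction and validation reports.
    """
    resource = importlib.resources.files("chromlogd.data").joinpath("acd_logd.csv")
    with importlib.resources.as_file(resource) as path:
        df = pd.read_csv(path)
    return dict(zip(df["id"], df["acd_log_d"].astype(float)))
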