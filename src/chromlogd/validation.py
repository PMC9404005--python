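"""External validation of the IP-RPLC model and prediction-error summaries.

The stage-2 model is validated on held-out ionized solutes of different
types — a strongly hydrophobic phenol (pentachlorophenol, W20), a simple
carboxylic acid (benzoic acid, W1) and a sulfonic acid (S12) — none of which
may appear in the stage-2 training set. Reference values follow the
precedence: shake-flask/slow-stir literature value (via log P/pKa) first,
then the stage-1 IS-RPLC label, then a software-calculated value; each row
records which source supplied its reference.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import CompoundSet
from .errors import LeakageError, MissingValueError
from .qsrr import CascadeResult

__all__ = [
    "VALIDATION_IDS",
    "PredictionRow",
    "PredictionReport",
    "external_validation",
    "relative_error_summary",
]

#: Canonical external-validation solutes (held out of stage-2 training).
VALIDATION_IDS = ("W20", "W1", "S12")

REF_SOURCE_LITERATURE = "SFM/SSM"
REF_SOURCE_STAGE1 = "stage-1"
REF_SOURCE_SOFTWARE = "software-calculated"


@dataclass(frozen=True)
class PredictionRow:
    compound_id: str
    name: str
    reference: float
    reference_source: str
    predicted: float
    predicted_source: str
    software: float | None = None  # comparison column, never a fit input
    flag: str = ""

    @property
    def error(self) -> float:
        """Signed error, always recomputed from the stored pair."""
        return self.predicted - self.reference

    @property
    def relative_error(self) -> float | None:
        if self.reference == 0.0:
            return None
        return abs(self.error) / abs(self.reference)


@dataclass(frozen=True)
class PredictionReport:
    rows: tuple[PredictionRow, ...]
    relative_error_bound: float = 0.10

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.compound_id,
                    "name": r.name,
                    "reference_log_d": r.reference,
                    "reference_source": r.reference_source,
                    "predicted_log_d": r.predicted,
                    "predicted_source": r.predicted_source,
                    "software_log_d": np.nan if r.software is None else r.software,
                    "error": r.error,
                    "flag": r.flag,
                }
                for r in self.rows
            ]
        )


def external_validation(
    cascade: CascadeResult,
    data: CompoundSet,
    validation_ids: Sequence[str] = VALIDATION_IDS,
    software_values: Mapping[str, float] | None = None,
    relative_error_bound: float = 0.10,
) -> PredictionReport:
    """Predict each validation compound with the stage-2 model and compare.

    Raises :class:`LeakageError` if any validation id is in the stage-2
    training set. The reference is the compound's ``log_d_ref`` when present,
    else its stage-1 label (the IS-RPLC measured value); rows whose relative
    error exceeds ``relative_error_bound`` are flagged, never dropped.
    """
    training = set(cascade.stage2.spec.training_ids)
    for cid in validation_ids:
        if cid in training:
            raise LeakageError(
                f"validation compound {cid} is in the stage-2 training set; "
                "external validation requires held-out compounds"
            )
    software_values = software_values or {}
    rows = []
    for cid in validation_ids:
        rec = data[cid]
        if rec.log_d_ref is not None:
            reference, source = rec.log_d_ref, REF_SOURCE_LITERATURE
        elif cid in cascade.stage1_predictions:
            reference, source = cascade.stage1_predictions[cid], REF_SOURCE_STAGE1
        elif cid in software_values:
            reference, source = software_values[cid], REF_SOURCE_SOFTWARE
        else:
            raise MissingValueError(
                f"{cid}: no reference log D available from any source"
            )
        predicted = cascade.stage2.predict(rec)
        row = PredictionRow(
            compound_id=cid,
            name=rec.name,
            reference=reference,
            reference_source=source,
            predicted=predicted,
            predicted_source="stage-2",
            software=software_values.get(cid),
        )
        flag = ""
        rel = row.relative_error
        if rel is not None and rel > relative_error_bound:
            flag = (
                f"discrepancy: |error|/|reference| = {rel:.2f} exceeds "
                f"{relative_error_bound:.2f}"
            )
        rows.append(dataclasses.replace(row, flag=flag))
    return PredictionReport(tuple(rows), relative_error_bound=relative_error_bound)


@dataclass(frozen=True)
class ErrorSummary:
    n: int
    n_relative: int  # rows with nonzero reference, used for relative metrics
    max_abs_error: float
    mean_abs_error: float
    mean_signed_error: float
    max_relative_error: float | None
    mean_relative_error: float | None
    n_within_bound: int
    bound: float


def relative_error_summary(
    report: PredictionReport, bound: float | None = None
) -> ErrorSummary:
    """Absolute and relative error statistics over a prediction report.

    Zero-reference rows are excluded from relative metrics (they still count
    toward absolute ones); ``n_within_bound`` counts relative-metric rows
    meeting the bound (default: the report's own bound).
    """
    if not report.rows:
        raise ValueError("empty prediction report")
    if bound is None:
        bound = report.relative_error_bound
    errors = np.array([r.error for r in report.rows])
    rels = [r.relative_error for r in report.rows if r.relative_error is not None]
    return ErrorSummary(
        n=len(report.rows),
        n_relative=len(rels),
        max_abs_error=float(np.max(np.abs(errors))),
        mean_abs_error=float(np.mean(np.abs(errors))),
        mean_signed_error=float(np.mean(errors)),
        max_relative_error=float(np.max(rels)) if rels else None,
        mean_relative_error=float(np.mean(rels)) if rels else None,
        n_within_bound=sum(1 for r in rels if r <= bound),
        bound=bound,
    )
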