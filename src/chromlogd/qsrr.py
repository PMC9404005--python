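"""Linear QSRR models linking log k_w and solute descriptors to log D, and the
two-stage IS -> IP cascade for strongly ionized compounds.

The modeling problem: strongly ionized solutes (sulfonic acids, polycarboxylic
acids) have no reliable experimental log D and are unretained in plain
ion-suppression RPLC, so they cannot be calibrated directly against neutral
model compounds. The cascade bridges the gap with the solute descriptors
n_e (net static charge), A (H-bond acidity) and B (H-bond basicity):

stage 1 (IS-RPLC)  log D ~ log k_w-IS + n_e + A + B, trained on 26 neutral
                   solutes plus 20 weak acids whose log D at pH 7.0 follows
                   from literature log P/pKa. The fitted model labels the
                   ionized solutes that *are* retained without ion-pair
                   reagent (19 of them).
stage 2 (IP-RPLC)  log D ~ log k_w-IP + n_e + A + B, trained on the mixed
                   model group: the neutrals, the weak acids W2-W19, and 18
                   stage-1-labeled solutes (N = 62). It predicts the 8
                   strongly ionized solutes only retained with ion-pair
                   reagent, and is validated externally on held-out W20, W1
                   and S12.

All fits are plain ordinary least squares with intercept; coefficients are
reported with classical standard errors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .dataset import CompoundSet, CompoundRecord, select_by_ids, with_swapped_retention
from .errors import AssemblyError, MissingValueError, SingularDesignError

__all__ = [
    "PREDICTOR_FIELDS",
    "Coefficient",
    "ModelSpec",
    "QSRRModel",
    "CascadeConfig",
    "CascadeResult",
    "MODEL_SPECS",
    "REFERENCE_PVA_MODEL",
    "fit_ols",
    "fit_model",
    "run_cascade",
]

#: Descriptor fields allowed as predictors, in canonical order.
PREDICTOR_FIELDS = ("log_kw_is", "log_kw_ip", "n_e", "a", "b")

NEUTRAL_IDS = tuple(f"N{i}" for i in range(1, 27))
WEAK_ACID_MODEL_IDS = tuple(f"W{i}" for i in range(1, 21))

#: Ionized solutes retained in IS-RPLC, labeled by the stage-1 model.
STAGE1_PREDICTION_IDS = (
    tuple(f"W{i}" for i in (22, 23, 24, 25, 26, 28, 29, 30, 31, 32))
    + ("S1", "S3", "S4", "S5", "S7", "S8", "S9", "S11", "S12")
)

#: Stage-1-labeled solutes admitted to the stage-2 mixed model group.
#: S12 is reserved as an external-validation reference, never trained on.
STAGE2_EXTRA_TRAINING_IDS = tuple(i for i in STAGE1_PREDICTION_IDS if i != "S12")

#: Strongly ionized solutes, unretained without ion-pair reagent.
STAGE2_PREDICTION_IDS = ("W21", "W27", "W33", "S2", "S6", "S10", "S13", "S14")

STAGE1_TRAINING_IDS = NEUTRAL_IDS + WEAK_ACID_MODEL_IDS
STAGE2_TRAINING_IDS = (
    NEUTRAL_IDS + tuple(f"W{i}" for i in range(2, 20)) + STAGE2_EXTRA_TRAINING_IDS
)


@dataclass(frozen=True)
class Coefficient:
    """A fitted coefficient with its classical OLS standard error."""

    name: str
    value: float
    se: float


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model definition: response, predictors, training ids."""

    name: str
    response: str  # "log_d_ref" or "cascade" (reference value else stage-1 label)
    predictors: tuple[str, ...]
    training_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.predictors:
            raise ValueError(f"{self.name}: predictors must be non-empty")
        if len(set(self.predictors)) != len(self.predictors):
            raise ValueError(f"{self.name}: duplicate predictors {self.predictors}")


@dataclass(frozen=True)
class QSRRModel:
    """A fitted linear model with intercept."""

    spec: ModelSpec
    intercept: Coefficient
    coefficients: tuple[Coefficient, ...]
    r2: float
    n: int

    def predict(self, record: CompoundRecord) -> float:
        """Apply the model to one compound's descriptors."""
        value = self.intercept.value
        for coef in self.coefficients:
            x = record.get(coef.name)
            if x is None:
                raise MissingValueError(
                    f"{record.id}: predictor {coef.name!r} is missing "
                    f"(token {record.missing_tokens.get(coef.name, '')!r})"
                )
            value += coef.value * x
        return value

    def to_dict(self) -> dict:
        return {
            "name": self.spec.name,
            "predictors": list(self.spec.predictors),
            "intercept": {"value": self.intercept.value, "se": self.intercept.se},
            "coefficients": [
                {"name": c.name, "value": c.value, "se": c.se}
                for c in self.coefficients
            ],
            "r2": self.r2,
            "n": self.n,
            "training_ids": list(self.spec.training_ids),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def equation(self, response_label: str = "log D") -> str:
        """Human-readable equation string with +/- standard errors."""
        terms = [
            f"{c.value:+.3f}(±{c.se:.3f})·{c.name}" for c in self.coefficients
        ]
        terms.append(f"{self.intercept.value:+.3f}(±{self.intercept.se:.3f})")
        rhs = " ".join(terms)
        return f"{response_label} = {rhs}   (N={self.n}, R²={self.r2:.4f})"


#: The six canonical model definitions for this column system. Models 1-5 are
#: the IS-RPLC series on the 46 neutral + weak-acid model compounds; model 6
#: is the IP-RPLC mixed-model-group fit assembled by the cascade.
MODEL_SPECS: Mapping[str, ModelSpec] = {
    "model1": ModelSpec("model1", "log_d_ref", ("log_kw_is",), STAGE1_TRAINING_IDS),
    "model2": ModelSpec(
        "model2", "log_d_ref", ("log_kw_is", "a"), STAGE1_TRAINING_IDS
    ),
    "model3": ModelSpec(
        "model3", "log_d_ref", ("log_kw_is", "b"), STAGE1_TRAINING_IDS
    ),
    "model4": ModelSpec(
        "model4", "log_d_ref", ("log_kw_is", "n_e"), STAGE1_TRAINING_IDS
    ),
    "model5": ModelSpec(
        "model5", "log_d_ref", ("log_kw_is", "n_e", "a", "b"), STAGE1_TRAINING_IDS
    ),
    "model6": ModelSpec(
        "model6", "cascade", ("log_kw_ip", "n_e", "a", "b"), STAGE2_TRAINING_IDS
    ),
}

#: Published mixed-model-group fit on a polyvinyl-alcohol-matrix C18 column
#: (N=50, R^2=0.954), kept for cross-column comparison only — never refit here.
REFERENCE_PVA_MODEL: Mapping[str, float] = {
    "log_kw_ip": 1.18,
    "n_e": 1.55,
    "a": -0.09,
    "b": -0.44,
    "intercept": -0.82,
}


def fit_ols(
    y: Sequence[float],
    X: Sequence[Sequence[float]],
    predictor_names: Sequence[str],
    spec: ModelSpec | None = None,
) -> QSRRModel:
    """OLS with intercept; returns coefficients, classical SEs, R^2.

    ``X`` is the predictor matrix *without* the intercept column (one row per
    observation, columns ordered as ``predictor_names``).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError(f"design shape {X.shape} incompatible with n={y.shape[0]}")
    n, p = X.shape
    if len(predictor_names) != p:
        raise ValueError("predictor_names length does not match design columns")
    if n <= p + 1:
        raise SingularDesignError(
            f"need n > p+1 observations for classical errors (n={n}, p={p})"
        )
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < p + 1:
        raise SingularDesignError(
            f"design matrix is rank deficient (rank "
            f"{np.linalg.matrix_rank(design)} < {p + 1}); check for constant or "
            "collinear predictors"
        )
    res = sm.OLS(y, design).fit()
    params = np.asarray(res.params)
    bse = np.asarray(res.bse)
    if spec is None:
        spec = ModelSpec("adhoc", "y", tuple(predictor_names), ())
    return QSRRModel(
        spec=spec,
        intercept=Coefficient("intercept", float(params[0]), float(bse[0])),
        coefficients=tuple(
            Coefficient(name, float(v), float(se))
            for name, v, se in zip(predictor_names, params[1:], bse[1:])
        ),
        r2=float(res.rsquared),
        n=n,
    )


def _design_from_records(
    records: Sequence[CompoundRecord],
    predictors: Sequence[str],
    responses: Mapping[str, float],
) -> tuple[np.ndarray, np.ndarray]:
    rows, ys = [], []
    for rec in records:
        if rec.id not in responses or responses[rec.id] is None:
            raise MissingValueError(f"{rec.id}: no response value available")
        row = []
        for p in predictors:
            v = rec.get(p)
            if v is None:
                raise MissingValueError(
                    f"{rec.id}: predictor {p!r} is missing "
                    f"(token {rec.missing_tokens.get(p, '')!r})"
                )
            row.append(v)
        rows.append(row)
        ys.append(responses[rec.id])
    return np.asarray(ys, dtype=float), np.asarray(rows, dtype=float)


def fit_model(
    spec: ModelSpec,
    data: CompoundSet,
    responses: Mapping[str, float] | None = None,
) -> QSRRModel:
    """Fit a declared model on a compound set.

    The response defaults to each training compound's ``log_d_ref``;
    ``responses`` overrides per-id (the cascade uses this to splice stage-1
    labels into the stage-2 response).
    """
    unknown = [p for p in spec.predictors if p not in PREDICTOR_FIELDS]
    if unknown:
        raise ValueError(
            f"{spec.name}: unknown predictors {unknown}; choose from "
            f"{PREDICTOR_FIELDS}"
        )
    training = select_by_ids(data, spec.training_ids)
    if responses is None:
        responses = {
            r.id: r.log_d_ref for r in training if r.log_d_ref is not None
        }
    y, X = _design_from_records(training.records, spec.predictors, responses)
    return fit_ols(y, X, spec.predictors, spec=spec)


@dataclass(frozen=True)
class CascadeConfig:
    """Training/prediction id lists and data handling for the two-stage cascade.

    Defaults reproduce the canonical assembly on the packaged reference
    table: stage 1 N=46, stage 2 N=62. ``repair_transposed_retention``
    applies the documented N5/N6 log k_w swap before any fit (see
    :func:`chromlogd.dataset.with_swapped_retention`).
    """

    stage1_training_ids: tuple[str, ...] = STAGE1_TRAINING_IDS
    stage1_prediction_ids: tuple[str, ...] = STAGE1_PREDICTION_IDS
    stage2_training_ids: tuple[str, ...] = STAGE2_TRAINING_IDS
    stage2_prediction_ids: tuple[str, ...] = STAGE2_PREDICTION_IDS
    expected_stage1_n: int | None = 46
    expected_stage2_n: int | None = 62
    repair_transposed_retention: bool = True

    def with_available(self, data: CompoundSet) -> "CascadeConfig":
        """Drop prediction ids absent from ``data`` (training ids never shrink)."""
        from dataclasses import replace

        return replace(
            self,
            stage1_prediction_ids=tuple(
                i for i in self.stage1_prediction_ids if i in data
            ),
            stage2_prediction_ids=tuple(
                i for i in self.stage2_prediction_ids if i in data
            ),
        )


@dataclass(frozen=True)
class CascadeResult:
    """Both fitted models and their prediction maps."""

    stage1: QSRRModel
    stage1_predictions: Mapping[str, float]
    stage2: QSRRModel
    stage2_predictions: Mapping[str, float]
    data: CompoundSet = field(compare=False)

    @property
    def all_predictions(self) -> dict[str, float]:
        return {**dict(self.stage1_predictions), **dict(self.stage2_predictions)}


def run_cascade(data: CompoundSet, config: CascadeConfig | None = None) -> CascadeResult:
    """Run the full IS -> IP cascade on a compound set.

    Stage 1 fits the four-descriptor IS-RPLC model on compounds with
    reference log D and labels the IS-retained ionized compounds. Stage 2
    fits the IP-RPLC model on the mixed model group — reference log D where
    available, stage-1 labels otherwise — and predicts the strongly ionized
    compounds. Training-set sizes are checked against the expected N and the
    run fails loudly on any mismatch; prediction ids missing from ``data``
    are simply skipped (unknowns never affect training).
    """
    if config is None:
        config = CascadeConfig()
    if config.repair_transposed_retention and "N5" in data and "N6" in data:
        data = with_swapped_retention(data)
    config = config.with_available(data)

    spec1 = ModelSpec(
        "model5", "log_d_ref", ("log_kw_is", "n_e", "a", "b"),
        config.stage1_training_ids,
    )
    if (
        config.expected_stage1_n is not None
        and len(spec1.training_ids) != config.expected_stage1_n
    ):
        raise AssemblyError(
            f"stage-1 training set has {len(spec1.training_ids)} compounds, "
            f"expected {config.expected_stage1_n}"
        )
    stage1 = fit_model(spec1, data)
    stage1_predictions = {
        cid: stage1.predict(data[cid]) for cid in config.stage1_prediction_ids
    }

    spec2 = ModelSpec(
        "model6", "cascade", ("log_kw_ip", "n_e", "a", "b"),
        config.stage2_training_ids,
    )
    if (
        config.expected_stage2_n is not None
        and len(spec2.training_ids) != config.expected_stage2_n
    ):
        raise AssemblyError(
            f"stage-2 training set has {len(spec2.training_ids)} compounds, "
            f"expected {config.expected_stage2_n}"
        )
    responses: dict[str, float] = {}
    for cid in spec2.training_ids:
        rec = data[cid]
        if rec.log_d_ref is not None:
            responses[cid] = rec.log_d_ref
        elif cid in stage1_predictions:
            responses[cid] = stage1_predictions[cid]
        else:
            raise MissingValueError(
                f"{cid}: stage-2 training compound has neither a reference "
                "log D nor a stage-1 label"
            )
    stage2 = fit_model(spec2, data, responses=responses)
    stage2_predictions = {
        cid: stage2.predict(data[cid]) for cid in config.stage2_prediction_ids
    }
    return CascadeResult(
        stage1=stage1,
        stage1_predictions=stage1_predictions,
        stage2=stage2,
        stage2_predictions=stage2_predictions,
        data=data,
    )
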