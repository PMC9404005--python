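"""OLS engine, model definitions, and the two-stage IS->IP cascade."""

import numpy as np
import pytest

from chromlogd import dataset, qsrr
from chromlogd.errors import (
    AssemblyError,
    MissingValueError,
    SingularDesignError,
    UnknownIdError,
)
from chromlogd.qsrr import (
    CascadeConfig,
    MODEL_SPECS,
    ModelSpec,
    fit_model,
    fit_ols,
    run_cascade,
)


def _normal_equations(y, X):
    """Brute-force oracle: explicit normal equations + classical SEs."""
    y = np.asarray(y, float)
    A = np.column_stack([np.ones(len(y)), np.asarray(X, float)])
    xtx_inv = np.linalg.inv(A.T @ A)
    beta = xtx_inv @ A.T @ y
    resid = y - A @ beta
    n, p = A.shape
    s2 = resid @ resid / (n - p)
    se = np.sqrt(np.diag(s2 * xtx_inv))
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1 - resid @ resid / tss
    return beta, se, r2


def _random_instance(rng, n=None, p=None):
    n = n or int(rng.integers(6, 15))
    p = p or int(rng.integers(1, 4))
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p + 1)
    y = beta[0] + X @ beta[1:] + rng.normal(0, 0.5, size=n)
    return y, X


class TestFitOls:
    def test_matches_normal_equations_oracle_on_100_instances(self):
        rng = np.random.default_rng(12345)
        for _ in range(100):
            y, X = _random_instance(rng)
            names = [f"x{j}" for j in range(X.shape[1])]
            model = fit_ols(y, X, names)
            beta, se, r2 = _normal_equations(y, X)
            assert model.intercept.value == pytest.approx(beta[0], abs=1e-9)
            assert model.intercept.se == pytest.approx(se[0], abs=1e-9)
            for j, coef in enumerate(model.coefficients):
                assert coef.value == pytest.approx(beta[j + 1], abs=1e-9)
                assert coef.se == pytest.approx(se[j + 1], abs=1e-9)
            assert model.r2 == pytest.approx(r2, abs=1e-9)

    def test_exact_linear_response(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 2))
        y = 1.5 + 2.0 * X[:, 0] - 0.5 * X[:, 1]
        model = fit_ols(y, X, ["u", "v"])
        assert model.r2 == pytest.approx(1.0, abs=1e-12)
        assert model.intercept.value == pytest.approx(1.5, abs=1e-10)
        preds = model.intercept.value + X @ [c.value for c in model.coefficients]
        assert np.allclose(preds, y, atol=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(42)
        y, X = _random_instance(rng, n=30, p=3)
        model = fit_ols(y, X, ["a", "b", "c"])
        fitted = model.intercept.value + X @ [c.value for c in model.coefficients]
        resid = y - fitted
        assert abs(resid.sum()) < 1e-9
        for j in range(X.shape[1]):
            assert abs(resid @ X[:, j]) < 1e-9

    def test_r2_invariant_under_predictor_rescaling(self):
        rng = np.random.default_rng(99)
        y, X = _random_instance(rng, n=25, p=2)
        base = fit_ols(y, X, ["a", "b"])
        scale, shift = 3.7, -2.1
        X2 = X.copy()
        X2[:, 0] = scale * X[:, 0] + shift
        scaled = fit_ols(y, X2, ["a", "b"])
        assert scaled.r2 == pytest.approx(base.r2, abs=1e-10)
        assert scaled.coefficients[0].value == pytest.approx(
            base.coefficients[0].value / scale, abs=1e-10
        )

    def test_rank_deficient_design_rejected(self):
        X = np.ones((8, 2))
        X[:, 1] = 2 * X[:, 0]
        with pytest.raises(SingularDesignError):
            fit_ols(np.arange(8.0), X, ["a", "b"])

    def test_too_few_observations_rejected(self):
        # n must strictly exceed p+1 so residual variance has a df left
        with pytest.raises(SingularDesignError):
            fit_ols([1.0, 2.0], [[1.0], [2.0]], ["a"])


class TestModelSpecs:
    def test_spec_validation(self, table1):
        with pytest.raises(ValueError):
            ModelSpec("bad", "log_d_ref", (), ("N1",))
        with pytest.raises(ValueError):
            ModelSpec("bad", "log_d_ref", ("a", "a"), ("N1",))
        bogus = ModelSpec("bad", "log_d_ref", ("bogus",), tuple(f"N{i}" for i in range(1, 7)))
        with pytest.raises(ValueError, match="bogus"):
            fit_model(bogus, table1)

    def test_canonical_training_sizes(self):
        for name in ("model1", "model2", "model3", "model4", "model5"):
            assert len(MODEL_SPECS[name].training_ids) == 46
        assert len(MODEL_SPECS["model6"].training_ids) == 62

    def test_missing_predictor_named_in_error(self, table1):
        spec = ModelSpec(
            "m", "log_d_ref", ("log_kw_is",), ("N1", "N2", "N3", "W21", "N4", "N5")
        )
        with pytest.raises(MissingValueError, match="W21"):
            fit_model(spec, table1)

    def test_in_sample_prediction_equals_fitted_value(self, repaired):
        model = fit_model(MODEL_SPECS["model5"], repaired)
        rec = repaired["W7"]
        x = np.array([rec.log_kw_is, rec.n_e, rec.a, rec.b])
        manual = model.intercept.value + float(
            x @ np.array([c.value for c in model.coefficients])
        )
        assert model.predict(rec) == pytest.approx(manual, abs=1e-12)

    def test_nested_models_improve_on_reference_data(self, repaired):
        """Adding charge/H-bond descriptors can only help the IS-RPLC fit."""
        r2 = {
            name: fit_model(MODEL_SPECS[name], repaired).r2
            for name in ("model1", "model2", "model5")
        }
        assert r2["model5"] >= r2["model2"] >= r2["model1"]


class TestCascade:
    def test_training_sizes(self, cascade_result):
        assert cascade_result.stage1.n == 46
        assert cascade_result.stage2.n == 62

    def test_prediction_counts(self, cascade_result):
        assert len(cascade_result.stage1_predictions) == 19
        assert len(cascade_result.stage2_predictions) == 8

    def test_s12_held_out_of_stage2_training(self, cascade_result):
        assert "S12" not in cascade_result.stage2.spec.training_ids
        assert "S12" in cascade_result.stage1_predictions

    def test_stage2_response_mixes_reference_and_stage1_labels(self, cascade_result):
        ids = set(cascade_result.stage2.spec.training_ids)
        # neutrals and W2-W19 carry reference log D; the other 18 are labeled
        labeled = ids - {f"N{i}" for i in range(1, 27)} - {
            f"W{i}" for i in range(2, 20)
        }
        assert labeled == set(cascade_result.stage1_predictions) - {"S12"}

    def test_removing_an_unknown_leaves_models_unchanged(self, table1, cascade_result):
        without = dataset.CompoundSet(
            tuple(r for r in table1.records if r.id != "W21"), ph=table1.ph
        )
        res = run_cascade(without)
        assert len(res.stage2_predictions) == 7
        assert "W21" not in res.stage2_predictions
        assert res.stage2.r2 == pytest.approx(cascade_result.stage2.r2, abs=1e-12)
        for a, b in zip(
            res.stage2.coefficients, cascade_result.stage2.coefficients
        ):
            assert a.value == pytest.approx(b.value, abs=1e-12)

    def test_missing_training_compound_fails_loud(self, table1):
        without = dataset.CompoundSet(
            tuple(r for r in table1.records if r.id != "W5"), ph=table1.ph
        )
        with pytest.raises(UnknownIdError, match="W5"):
            run_cascade(without)

    def test_wrong_assembly_size_fails_loud(self, table1):
        config = CascadeConfig(
            stage1_training_ids=qsrr.STAGE1_TRAINING_IDS[:-1],  # 45, not 46
        )
        with pytest.raises(AssemblyError, match="45"):
            run_cascade(table1, config)

    def test_repair_switch_changes_stage1_fit(self, table1):
        repaired = run_cascade(table1)
        literal = run_cascade(
            table1, CascadeConfig(repair_transposed_retention=False)
        )
        # as-printed N5/N6 rows visibly degrade the IS-RPLC model
        assert literal.stage1.r2 < repaired.stage1.r2 - 0.05
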