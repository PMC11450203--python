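"""Dose-aware inhibition regressor with conformal confidence filtering.

A gradient-boosted tree ensemble (LightGBM) maps
``signature (+) fingerprint (+) log10 dose`` to percent inhibition.
Hyperparameters are chosen by randomized search scored by grouped
cross-validated RMSE; folds are grouped by (drug, cell line) pair so that no
pair contributes to both sides of a split.  Out-of-fold absolute residuals
from a repeated grouped CV form the split-conformal calibration set: the
90th residual quantile is the prediction-interval half-width, and the
confidence score is ``1 - halfwidth / 100``.  Predictions with confidence
below a threshold (default 0.8) are discarded, as are doses above a cap
(default 1 uM) when ranking from a predefined dose grid.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import lightgbm as lgb
import numpy as np
import pandas as pd

from .errors import InsufficientDataError, SchemaMismatchError
from .refdb import TrainingTable

__all__ = [
    "InhibitionModel",
    "PredictionRecord",
    "fit",
    "predict",
    "conformal_filter",
    "apply_dose_cap",
]

log = logging.getLogger(__name__)

#: randomized-search grid; kept deliberately small and documented here so a
#: fit is reproducible from the seed alone.
DEFAULT_PARAM_GRID: dict[str, list] = {
    "n_estimators": [100, 200],
    "num_leaves": [15, 31],
    "learning_rate": [0.05, 0.1],
    "min_child_samples": [5, 20],
    "colsample_bytree": [0.6, 1.0],
}

_BASE_PARAMS = dict(
    objective="regression",
    deterministic=True,
    force_row_wise=True,
    max_bin=63,
    n_jobs=1,
    verbosity=-1,
)


@dataclass
class PredictionRecord:
    """One (drug, dose) prediction with its conformal confidence."""

    drug_id: str
    dose_uM: float
    predicted_inhibition_pct: float
    halfwidth_pct: float
    confidence: float


@dataclass
class InhibitionModel:
    booster: lgb.Booster
    landmark_genes: list
    n_fp_bits: int
    residuals: np.ndarray  # held-out absolute errors, pooled over repeats
    params: dict
    cv_repeats: int
    cv_folds: int
    seed: int
    quantile: float = 0.90
    feature_names: list = field(default_factory=list)

    def halfwidth(self, quantile: float | None = None) -> float:
        """Conformal interval half-width (percent inhibition)."""
        q = self.quantile if quantile is None else quantile
        return float(np.quantile(self.residuals, q))

    def confidence(self) -> float:
        return 1.0 - self.halfwidth() / 100.0

    # -- persistence: versioned directory with model file + schema + residuals

    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        self.booster.save_model(os.path.join(out_dir, "model.txt"))
        schema = {
            "landmark_genes": self.landmark_genes,
            "n_fp_bits": self.n_fp_bits,
            "params": self.params,
            "cv_repeats": self.cv_repeats,
            "cv_folds": self.cv_folds,
            "seed": self.seed,
            "quantile": self.quantile,
            "feature_names": self.feature_names,
        }
        with open(os.path.join(out_dir, "schema.json"), "w") as fh:
            json.dump(schema, fh, indent=1)
        pd.Series(self.residuals, name="abs_residual").to_csv(
            os.path.join(out_dir, "residuals.csv"), index=False
        )

    @classmethod
    def load(cls, in_dir: str) -> "InhibitionModel":
        with open(os.path.join(in_dir, "schema.json")) as fh:
            schema = json.load(fh)
        booster = lgb.Booster(model_file=os.path.join(in_dir, "model.txt"))
        residuals = pd.read_csv(os.path.join(in_dir, "residuals.csv"))[
            "abs_residual"
        ].to_numpy()
        return cls(
            booster=booster,
            landmark_genes=schema["landmark_genes"],
            n_fp_bits=schema["n_fp_bits"],
            residuals=residuals,
            params=schema["params"],
            cv_repeats=schema["cv_repeats"],
            cv_folds=schema["cv_folds"],
            seed=schema["seed"],
            quantile=schema["quantile"],
            feature_names=schema["feature_names"],
        )


def _grouped_folds(groups: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Yield (train_idx, test_idx) with whole groups held out, seed-shuffled."""
    uniq = np.unique(groups)
    perm = rng.permutation(uniq)
    chunks = np.array_split(perm, n_folds)
    group_to_fold = {g: f for f, chunk in enumerate(chunks) for g in chunk}
    fold_of_row = np.array([group_to_fold[g] for g in groups])
    for f in range(n_folds):
        test = np.flatnonzero(fold_of_row == f)
        train = np.flatnonzero(fold_of_row != f)
        yield train, test


def _make_regressor(params: dict, seed: int) -> lgb.LGBMRegressor:
    return lgb.LGBMRegressor(**_BASE_PARAMS, random_state=seed, **params)


def fit(
    table: TrainingTable,
    cv_repeats: int = 3,
    cv_folds: int = 10,
    n_search: int = 8,
    tune_folds: int = 3,
    seed: int = 0,
    param_grid: dict | None = None,
) -> InhibitionModel:
    """Tune, calibrate and fit the inhibition regressor.

    Randomized search (``n_search`` draws from ``DEFAULT_PARAM_GRID``) is
    scored by grouped ``tune_folds``-fold CV RMSE; the winning configuration
    is then run through a ``cv_repeats`` x ``cv_folds`` repeated grouped CV
    whose pooled out-of-fold absolute errors become the conformal calibration
    residuals; finally the model is refit on the full table.  Deterministic
    under a fixed seed.
    """
    if len(table) < 100:
        raise InsufficientDataError(f"need >= 100 training rows, got {len(table)}")
    groups = (
        table.meta["drug_id"].astype(str) + "|" + table.meta["cell_line_id"].astype(str)
    ).to_numpy()
    if np.unique(groups).size < cv_folds:
        raise InsufficientDataError(
            f"need >= {cv_folds} distinct (drug, cell line) groups"
        )

    X = table.features.to_numpy(dtype=np.float64)
    y = table.target.to_numpy(dtype=np.float64)
    grid = DEFAULT_PARAM_GRID if param_grid is None else param_grid
    rng = np.random.default_rng(seed)

    # deterministic sort so the fit is invariant to the table's row order
    # (build_training_table already sorts; re-sorting here makes it a contract)
    order = np.lexsort(
        (table.meta["dose_uM"].to_numpy(), table.meta["cell_line_id"].to_numpy(),
         table.meta["drug_id"].to_numpy())
    )
    X, y, groups = X[order], y[order], groups[order]

    # -- randomized hyperparameter search
    keys = sorted(grid)
    draws = []
    seen = set()
    for _ in range(n_search * 4):
        cand = tuple(grid[k][rng.integers(len(grid[k]))] for k in keys)
        if cand not in seen:
            seen.add(cand)
            draws.append(dict(zip(keys, cand)))
        if len(draws) == n_search:
            break

    best_params, best_rmse = None, np.inf
    tune_rng = np.random.default_rng(seed + 1)
    tune_splits = list(_grouped_folds(groups, tune_folds, tune_rng))
    for params in draws:
        sq_err, n = 0.0, 0
        for train, test in tune_splits:
            reg = _make_regressor(params, seed)
            reg.fit(X[train], y[train])
            pred = np.clip(reg.predict(X[test]), 0.0, 100.0)
            sq_err += float(np.sum((pred - y[test]) ** 2))
            n += test.size
        rmse = np.sqrt(sq_err / n)
        if rmse < best_rmse:
            best_rmse, best_params = rmse, params
    log.info("selected params %s (tuning RMSE %.2f)", best_params, best_rmse)

    # -- repeated grouped CV for conformal calibration residuals
    residuals: list[np.ndarray] = []
    for r in range(cv_repeats):
        rep_rng = np.random.default_rng(seed + 100 + r)
        for train, test in _grouped_folds(groups, cv_folds, rep_rng):
            reg = _make_regressor(best_params, seed)
            reg.fit(X[train], y[train])
            pred = np.clip(reg.predict(X[test]), 0.0, 100.0)
            residuals.append(np.abs(pred - y[test]))
    pooled = np.sort(np.concatenate(residuals))

    final = _make_regressor(best_params, seed)
    final.fit(X, y)
    return InhibitionModel(
        booster=final.booster_,
        landmark_genes=list(table.landmark_genes),
        n_fp_bits=table.n_fp_bits,
        residuals=pooled,
        params=best_params,
        cv_repeats=cv_repeats,
        cv_folds=cv_folds,
        seed=seed,
        feature_names=list(table.features.columns),
    )


def _signature_to_vector(model: InhibitionModel, signature) -> np.ndarray:
    """Map a signature (array in panel order, or gene -> value mapping) to the
    model's landmark order; genes absent from a mapping are imputed 0."""
    if isinstance(signature, (pd.Series, dict)):
        sig = pd.Series(signature, dtype=float)
        return sig.reindex(model.landmark_genes).fillna(0.0).to_numpy()
    vec = np.asarray(signature, dtype=float)
    if vec.shape != (len(model.landmark_genes),):
        raise SchemaMismatchError(
            f"signature length {vec.shape} != landmark panel "
            f"({len(model.landmark_genes)},)"
        )
    return vec


def predict_matrix(
    model: InhibitionModel,
    signature,
    fingerprints: pd.DataFrame,
    dose_grid_uM,
) -> pd.DataFrame:
    """Predict inhibition for every (drug, dose) pair against one signature.

    ``fingerprints`` is a table with a ``drug_id`` column plus bit columns.
    Returns a tidy frame (drug_id, dose_uM, predicted_inhibition_pct,
    halfwidth_pct, confidence).
    """
    sig = _signature_to_vector(model, signature)
    doses = np.sort(np.unique(np.asarray(dose_grid_uM, dtype=float)))
    if np.any(doses <= 0):
        raise ValueError("doses must be positive (uM)")
    bit_cols = [c for c in fingerprints.columns if c != "drug_id"]
    if len(bit_cols) != model.n_fp_bits:
        raise SchemaMismatchError(
            f"fingerprint length {len(bit_cols)} != training schema {model.n_fp_bits}"
        )
    drug_ids = fingerprints["drug_id"].to_numpy()
    fp = fingerprints[bit_cols].to_numpy(dtype=float)

    n_drugs, n_doses = len(drug_ids), doses.size
    d = len(sig) + model.n_fp_bits + 1
    X = np.empty((n_drugs * n_doses, d))
    X[:, : len(sig)] = sig
    X[:, len(sig):-1] = np.repeat(fp, n_doses, axis=0)
    X[:, -1] = np.tile(np.log10(doses), n_drugs)

    pred = np.clip(model.booster.predict(X), 0.0, 100.0)
    hw = model.halfwidth()
    return pd.DataFrame(
        {
            "drug_id": np.repeat(drug_ids, n_doses),
            "dose_uM": np.tile(doses, n_drugs),
            "predicted_inhibition_pct": pred,
            "halfwidth_pct": hw,
            "confidence": 1.0 - hw / 100.0,
        }
    )


def predict(
    model: InhibitionModel,
    signature,
    fingerprint,
    dose_grid_uM,
    drug_id: str = "query",
) -> list[PredictionRecord]:
    """Predict one drug over a dose grid; one record per dose."""
    fp = np.asarray(fingerprint, dtype=float).ravel()
    if fp.size != model.n_fp_bits:
        raise SchemaMismatchError(
            f"fingerprint length {fp.size} != training schema {model.n_fp_bits}"
        )
    table = pd.DataFrame([fp], columns=[f"bit_{i}" for i in range(fp.size)])
    table.insert(0, "drug_id", drug_id)
    tidy = predict_matrix(model, signature, table, dose_grid_uM)
    return [
        PredictionRecord(
            drug_id=row.drug_id,
            dose_uM=float(row.dose_uM),
            predicted_inhibition_pct=float(row.predicted_inhibition_pct),
            halfwidth_pct=float(row.halfwidth_pct),
            confidence=float(row.confidence),
        )
        for row in tidy.itertuples()
    ]


def conformal_filter(records, threshold: float = 0.8):
    """Keep records with confidence >= ``threshold`` (boundary inclusive)."""
    if isinstance(records, pd.DataFrame):
        return records[records["confidence"] >= threshold].reset_index(drop=True)
    return [r for r in records if r.confidence >= threshold]


def apply_dose_cap(records, cap_uM: float = 1.0):
    """Drop records whose dose exceeds ``cap_uM`` (boundary inclusive)."""
    if isinstance(records, pd.DataFrame):
        out = records[records["dose_uM"] <= cap_uM].reset_index(drop=True)
        empty = out.empty and not records.empty
    else:
        out = [r for r in records if r.dose_uM <= cap_uM]
        empty = not out and bool(records)
    if empty:
        log.warning("dose cap %.3g uM removed every prediction", cap_uM)
    return out
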