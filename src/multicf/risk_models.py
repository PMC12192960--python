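"""Train, score and select one probability model per disease.

The optimizer only ever sees the :class:`RiskModel` adapter: a feature order,
a fitted preprocessing transform and a ``predict_probability`` contract
returning a number in [0, 1]. Which estimator sits behind it is irrelevant to
the search, so the candidate zoo is pluggable; the default mirrors the usual
tabular-risk line-up (logistic regression plus gradient-boosting variants),
and the winner per disease is the candidate with the highest test ROC AUC.

Error metrics (MAE/MSE/RMSE/R^2) are computed on thresholded 0/1 predictions,
which makes MAE = MSE = 1 - accuracy an exact identity; ROC AUC uses the
continuous scores.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, GradientBoostingClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import (
    accuracy_score,
    mean_absolute_error,
    mean_squared_error,
    r2_score,
    roc_auc_score,
)

from .exceptions import ContractViolationError, DataError
from .feature_space import BINARY, CATEGORICAL, CONTINUOUS

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# preprocessing


@dataclass
class Preprocessor:
    """Fitted tabular transform: id dropping, median imputation, one-hot.

    Re-applying the transform to its own output is a no-op: raw categorical
    columns are expanded only when present, numeric imputation reuses the
    stored training medians, and already-expanded indicator columns pass
    through untouched.
    """

    medians: dict[str, float]
    category_maps: dict[str, list[str]]
    dropped: tuple[str, ...]
    output_columns: list[str]

    def apply(self, table: pd.DataFrame) -> pd.DataFrame:
        df = table.drop(columns=[c for c in self.dropped if c in table.columns])
        pieces: dict[str, pd.Series] = {}
        for col in df.columns:
            if col in self.category_maps:
                values = df[col]
                seen = values.isin(self.category_maps[col]) | values.isna()
                if not seen.all():
                    unseen = sorted(set(values[~seen].astype(str)))
                    logger.warning(
                        "column %r: unseen categories %s mapped to all-zero block",
                        col,
                        unseen,
                    )
                for cat in self.category_maps[col]:
                    pieces[f"{col}={cat}"] = (values == cat).astype(float)
            elif col in self.medians:
                pieces[col] = pd.to_numeric(df[col]).fillna(self.medians[col])
            else:
                pieces[col] = df[col]
        out = pd.DataFrame(pieces, index=df.index)
        # keep the training column order for every column the output defines
        ordered = [c for c in self.output_columns if c in out.columns]
        extra = [c for c in out.columns if c not in ordered]
        return out[ordered + extra]

    def to_dict(self) -> dict:
        return {
            "medians": self.medians,
            "category_maps": self.category_maps,
            "dropped": list(self.dropped),
            "output_columns": self.output_columns,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Preprocessor":
        return cls(
            medians=dict(d["medians"]),
            category_maps={k: list(v) for k, v in d["category_maps"].items()},
            dropped=tuple(d["dropped"]),
            output_columns=list(d["output_columns"]),
        )


def fit_preprocessor(
    table: pd.DataFrame,
    schema: Mapping[str, str],
    outcome: str,
    id_columns: Sequence[str] = ("id",),
) -> tuple[Preprocessor, pd.DataFrame]:
    """Fit the median-imputation + one-hot transform on a training table.

    ``schema`` maps feature names to kinds; declared categorical columns are
    one-hot expanded with a recorded category map, numeric columns have nulls
    replaced by the training median, and identifier columns are dropped.
    """
    if outcome not in table.columns:
        raise DataError(f"outcome column {outcome!r} missing from table")
    y = pd.to_numeric(table[outcome], errors="coerce")
    if not y.dropna().isin([0, 1]).all():
        raise DataError(f"outcome column {outcome!r} is not binary 0/1")

    dropped = tuple(c for c in id_columns if c in table.columns)
    medians: dict[str, float] = {}
    category_maps: dict[str, list[str]] = {}
    for col in table.columns:
        if col in dropped or col == outcome:
            continue
        kind = schema.get(col, CONTINUOUS)
        if kind == CATEGORICAL:
            cats = sorted(table[col].dropna().astype(str).unique().tolist())
            category_maps[col] = cats
        else:
            medians[col] = float(pd.to_numeric(table[col]).median())
    pre = Preprocessor(
        medians=medians, category_maps=category_maps, dropped=dropped, output_columns=[]
    )
    transformed = pre.apply(table)
    pre.output_columns = [c for c in transformed.columns]
    return pre, transformed


# ---------------------------------------------------------------------------
# splitting and metrics


def split_train_test(
    table: pd.DataFrame, ratio: float = 0.80, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded shuffled row partition with ``|train| = round(ratio * n)``."""
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    n = len(table)
    if n < 2:
        raise DataError("need at least 2 rows to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(ratio * n))
    n_train = min(max(n_train, 1), n - 1)
    return table.iloc[perm[:n_train]], table.iloc[perm[n_train:]]


@dataclass(frozen=True)
class MetricReport:
    """One row of the model-comparison table."""

    label: str
    mae: float
    mse: float
    rmse: float
    r2: float
    roc_auc: float | None
    accuracy: float

    def to_dict(self) -> dict:
        return {
            "Model": self.label,
            "MAE": self.mae,
            "MSE": self.mse,
            "RMSE": self.rmse,
            "R2 score": self.r2,
            "ROC AUC score": self.roc_auc,
            "Accuracy": self.accuracy,
        }


def score_metrics(
    truth: np.ndarray,
    scores: np.ndarray,
    hard_predictions: np.ndarray,
    label: str = "model",
) -> MetricReport:
    """Compute the metric suite: errors on hard predictions, AUC on scores.

    A single-class truth vector leaves ROC AUC undefined (``None``); no
    number is substituted.
    """
    truth = np.asarray(truth, dtype=float)
    scores = np.asarray(scores, dtype=float)
    hard = np.asarray(hard_predictions, dtype=float)
    if not (len(truth) == len(scores) == len(hard)):
        raise ValueError("truth, scores and hard_predictions must have equal length")
    mae = float(mean_absolute_error(truth, hard))
    mse = float(mean_squared_error(truth, hard))
    auc = float(roc_auc_score(truth, scores)) if len(np.unique(truth)) > 1 else None
    return MetricReport(
        label=label,
        mae=mae,
        mse=mse,
        rmse=float(np.sqrt(mse)),
        r2=float(r2_score(truth, hard)),
        roc_auc=auc,
        accuracy=float(accuracy_score(truth, hard)),
    )


# ---------------------------------------------------------------------------
# the adapter and training


@dataclass
class RiskModel:
    """Uniform adapter around a fitted per-disease probability model.

    ``predict_probability`` takes raw feature values in ``feature_order``
    (labels for categorical features), applies the fitted preprocessing and
    returns the positive-class probability. Output outside [0, 1] is a
    contract violation, not a value.
    """

    disease: str
    feature_order: tuple[str, ...]
    preprocessor: Preprocessor
    estimator: object
    label: str = "model"
    threshold: float = 0.5
    report: MetricReport | None = None

    def _matrix(self, frame: pd.DataFrame) -> np.ndarray:
        transformed = self.preprocessor.apply(frame)
        cols = [c for c in self.preprocessor.output_columns]
        transformed = transformed.reindex(columns=cols, fill_value=0.0)
        return transformed.to_numpy(dtype=float)

    def predict_frame(self, frame: pd.DataFrame) -> np.ndarray:
        """Vectorised probabilities for a frame with ``feature_order`` columns."""
        probs = np.asarray(
            self.estimator.predict_proba(
                _named_matrix(self._matrix(frame[list(self.feature_order)]))
            )
        )[:, 1]
        if np.any(probs < 0.0) or np.any(probs > 1.0) or np.any(~np.isfinite(probs)):
            raise ContractViolationError(
                f"model {self.label!r} for {self.disease!r} produced a probability "
                "outside [0, 1]"
            )
        return probs

    def predict_probability(self, values: Sequence) -> float:
        frame = pd.DataFrame([list(values)], columns=list(self.feature_order))
        return float(self.predict_frame(frame)[0])

    # -- persistence (model state via pickle, everything else as JSON) ------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "format_version": 1,
            "disease": self.disease,
            "feature_order": list(self.feature_order),
            "label": self.label,
            "threshold": self.threshold,
            "preprocessor": self.preprocessor.to_dict(),
            "report": self.report.to_dict() if self.report else None,
        }
        (directory / "bundle.json").write_text(json.dumps(meta, indent=2))
        with open(directory / "model.pkl", "wb") as fh:
            pickle.dump(self.estimator, fh)
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "RiskModel":
        directory = Path(directory)
        meta = json.loads((directory / "bundle.json").read_text())
        with open(directory / "model.pkl", "rb") as fh:
            estimator = pickle.load(fh)
        report = None
        if meta.get("report"):
            r = meta["report"]
            report = MetricReport(
                label=r["Model"], mae=r["MAE"], mse=r["MSE"], rmse=r["RMSE"],
                r2=r["R2 score"], roc_auc=r["ROC AUC score"], accuracy=r["Accuracy"],
            )
        return cls(
            disease=meta["disease"],
            feature_order=tuple(meta["feature_order"]),
            preprocessor=Preprocessor.from_dict(meta["preprocessor"]),
            estimator=estimator,
            label=meta["label"],
            threshold=meta["threshold"],
            report=report,
        )


def _named_matrix(X: np.ndarray) -> pd.DataFrame:
    """Positional column names, used consistently at fit and predict time so
    estimators that track feature names (e.g. LightGBM) stay quiet."""
    return pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])


CandidateBuilder = tuple[str, Callable[[int], object]]


def default_candidates() -> list[CandidateBuilder]:
    """The default candidate zoo: (label, seed -> unfitted estimator)."""
    from lightgbm import LGBMClassifier
    from xgboost import XGBClassifier

    return [
        ("Logistic Regression", lambda seed: LogisticRegression(max_iter=2000)),
        ("Gradient Boosting", lambda seed: GradientBoostingClassifier(random_state=seed)),
        ("XGBoost", lambda seed: XGBClassifier(
            eval_metric="logloss", random_state=seed, n_jobs=1, verbosity=0)),
        ("AdaBoost", lambda seed: AdaBoostClassifier(random_state=seed)),
        ("LightGBM", lambda seed: LGBMClassifier(
            random_state=seed, n_jobs=1, verbose=-1)),
    ]


def logistic_candidates() -> list[CandidateBuilder]:
    """Single-candidate zoo: logistic regression only (fast, well-specified
    when the data-generating risk surface is itself logistic)."""
    return [("Logistic Regression", lambda seed: LogisticRegression(max_iter=2000))]


def _oversample(X: pd.DataFrame, y: pd.Series, seed: int) -> tuple[pd.DataFrame, pd.Series]:
    """Random minority oversampling to a balanced class ratio."""
    rng = np.random.default_rng(seed)
    counts = y.value_counts()
    minority = counts.idxmin()
    deficit = int(counts.max() - counts.min())
    if deficit == 0:
        return X, y
    pool = np.flatnonzero(y.to_numpy() == minority)
    extra = rng.choice(pool, size=deficit, replace=True)
    idx = np.concatenate([np.arange(len(y)), extra])
    return X.iloc[idx].reset_index(drop=True), y.iloc[idx].reset_index(drop=True)


def train_and_select(
    train: pd.DataFrame,
    test: pd.DataFrame,
    candidates: Sequence[CandidateBuilder],
    disease: str,
    outcome: str,
    schema: Mapping[str, str],
    feature_order: Sequence[str] | None = None,
    threshold: float = 0.5,
    oversample: bool = False,
    seed: int = 0,
) -> tuple[RiskModel, list[MetricReport]]:
    """Train every candidate, score on the test split, pick the AUC winner.

    Selection: highest ROC AUC, ties broken by higher accuracy, then by
    candidate order. Returns the winner wrapped as :class:`RiskModel` plus
    the full report table.
    """
    if not candidates:
        raise ValueError("need at least one candidate builder")
    pre, train_t = fit_preprocessor(train, schema, outcome)
    test_t = pre.apply(test).reindex(columns=pre.output_columns, fill_value=0.0)
    X_cols = [c for c in pre.output_columns if c != outcome]
    Xtr, ytr = train_t[X_cols], train_t[outcome].astype(int)
    Xte, yte = test_t[X_cols], test_t[outcome].astype(int)
    if oversample:
        Xtr, ytr = _oversample(Xtr, ytr, seed)

    if feature_order is None:
        feature_order = tuple(
            c for c in train.columns if c != outcome and c not in pre.dropped
        )

    fitted: list[tuple[MetricReport, object]] = []
    failures: list[str] = []
    for label, build in candidates:
        try:
            est = build(seed)
            est.fit(_named_matrix(Xtr.to_numpy(dtype=float)), ytr.to_numpy())
            scores = np.asarray(
                est.predict_proba(_named_matrix(Xte.to_numpy(dtype=float)))
            )[:, 1]
            hard = (scores >= threshold).astype(int)
            fitted.append((score_metrics(yte, scores, hard, label=label), est))
        except Exception as exc:  # noqa: BLE001 - aggregate and report
            logger.warning("candidate %r failed to train: %s", label, exc)
            failures.append(f"{label}: {exc}")
    if not fitted:
        raise RuntimeError(
            "all candidates failed to train: " + "; ".join(failures)
        )

    def sort_key(item: tuple[int, tuple[MetricReport, object]]):
        i, (rep, _) = item
        auc = rep.roc_auc if rep.roc_auc is not None else -1.0
        return (-auc, -rep.accuracy, i)

    best_i, (best_report, best_est) = min(enumerate(fitted), key=sort_key)
    # drop the outcome column from the prediction-time transform
    pre_predict = Preprocessor(
        medians={k: v for k, v in pre.medians.items() if k != outcome},
        category_maps=dict(pre.category_maps),
        dropped=pre.dropped,
        output_columns=X_cols,
    )
    model = RiskModel(
        disease=disease,
        feature_order=tuple(feature_order),
        preprocessor=pre_predict,
        estimator=best_est,
        label=best_report.label,
        threshold=threshold,
        report=best_report,
    )
    return model, [rep for rep, _ in fitted]
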