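"""Next-week workload regression.

Stage 2 of the prediction model: a supervised regressor maps each active
patient-week's features (plus the k-prototypes cluster id) to the number
of navigator encounters the patient will need in the coming week.  Three
model families are supported — gradient-boosted trees (XGBoost), random
forest, and a small neural network — each tuned by a 15-combination random
search over its hyperparameter space with 3-fold patient-grouped
cross-validation, selecting the combination with the smallest mean CV MSE.
Families are then compared by test-set MSE.  The shipped default pipeline
trains only the boosted-tree family plus a predict-the-mean baseline.

Two leakage rules are structural: tuning sees only the training table, and
cross-validation folds are split by patient so no patient straddles folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import product as _iterproduct

import numpy as np
import pandas as pd
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupKFold
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import OneHotEncoder, StandardScaler
from xgboost import XGBRegressor

__all__ = [
    "FAMILY_ORDER",
    "DEFAULT_SEARCH_SPACES",
    "EXCLUDED_FEATURES",
    "NUMERIC_FEATURES",
    "CATEGORICAL_FEATURES",
    "TuningResult",
    "sample_configs",
    "random_search_cv",
    "fit_and_score",
    "select_model",
    "predict_week",
    "MeanBaseline",
    "WorkloadPredictor",
]

FAMILY_ORDER = ("gradient_boosted_trees", "random_forest", "neural_network")

#: Feature columns fed to the regressor.  Days since the last navigator
#: interaction and days since cancer diagnosis are deliberately excluded;
#: the cluster id is appended by the pipeline.
NUMERIC_FEATURES = [
    "age",
    "adi",
    "rucc",
    "weeks_since_enrollment",
    "util_1wk",
    "util_4wk",
    "util_12wk",
    "util_trend_4wk",
]
CATEGORICAL_FEATURES = ["sex", "insurance", "cancer_type", "specialty_id"]
EXCLUDED_FEATURES = ("days_since_last_interaction", "days_since_diagnosis")

#: Hyperparameter search spaces.  Each entry is (kind, *args) with kind in
#: {"int", "uniform", "loguniform", "choice"}.
DEFAULT_SEARCH_SPACES = {
    "gradient_boosted_trees": {
        "max_depth": ("int", 2, 8),
        "learning_rate": ("loguniform", 0.01, 0.3),
        "n_estimators": ("int", 50, 500),
        "subsample": ("uniform", 0.6, 1.0),
    },
    "random_forest": {
        "n_estimators": ("int", 100, 500),
        "max_depth": ("int", 4, 16),
        "min_samples_leaf": ("int", 1, 8),
    },
    "neural_network": {
        "n_layers": ("int", 1, 2),
        "hidden_units": ("int", 8, 64),
        "alpha": ("loguniform", 1e-5, 1e-2),
    },
}


@dataclass
class TuningResult:
    family: str
    configs: list
    cv_mse: list
    best_config: dict
    best_cv_mse: float
    seed: int
    test_mse: float | None = None

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "configs": self.configs,
            "cv_mse": self.cv_mse,
            "best_config": self.best_config,
            "best_cv_mse": self.best_cv_mse,
            "seed": self.seed,
            "test_mse": self.test_mse,
        }


def _space_size(space: dict) -> float:
    size = 1.0
    for kind, *args in space.values():
        if kind == "int":
            size *= args[1] - args[0] + 1
        elif kind == "choice":
            size *= len(args[0])
        else:
            return np.inf
    return size


def sample_configs(space: dict, n: int, rng: np.random.Generator) -> list[dict]:
    """Draw ``n`` distinct hyperparameter combinations from a search space.

    If the space holds fewer than ``n`` distinct combinations, all of them
    are returned (with a warning), in sampled order.
    """
    size = _space_size(space)
    if size < n:
        warnings.warn(
            f"search space has only {int(size)} distinct configs; using all of them"
        )
        axes = []
        for name, (kind, *args) in space.items():
            if kind == "int":
                axes.append([(name, v) for v in range(args[0], args[1] + 1)])
            else:
                axes.append([(name, v) for v in args[0]])
        configs = [dict(items) for items in _iterproduct(*axes)]
        order = rng.permutation(len(configs))
        return [configs[i] for i in order]

    configs: list[dict] = []
    seen = set()
    while len(configs) < n:
        cfg = {}
        for name, (kind, *args) in space.items():
            if kind == "int":
                cfg[name] = int(rng.integers(args[0], args[1] + 1))
            elif kind == "uniform":
                cfg[name] = float(rng.uniform(args[0], args[1]))
            elif kind == "loguniform":
                cfg[name] = float(np.exp(rng.uniform(np.log(args[0]), np.log(args[1]))))
            elif kind == "choice":
                cfg[name] = args[0][rng.integers(len(args[0]))]
            else:
                raise ValueError(f"unknown distribution kind {kind!r}")
        key = tuple(sorted(cfg.items()))
        if key in seen and size != np.inf:
            continue
        seen.add(key)
        configs.append(cfg)
    return configs


def make_model(family: str, config: dict, seed: int = 0):
    """Build an (untrained) sklearn-style regressor pipeline for a family."""
    cat = [c for c in CATEGORICAL_FEATURES + ["cluster_id"]]
    encoder = ColumnTransformer(
        [
            ("cat", OneHotEncoder(handle_unknown="ignore", sparse_output=False), cat),
            ("num", "passthrough", NUMERIC_FEATURES),
        ],
        verbose_feature_names_out=False,
    )
    if family == "gradient_boosted_trees":
        reg = XGBRegressor(
            max_depth=int(config.get("max_depth", 4)),
            learning_rate=float(config.get("learning_rate", 0.1)),
            n_estimators=int(config.get("n_estimators", 200)),
            subsample=float(config.get("subsample", 1.0)),
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
            verbosity=0,
        )
    elif family == "random_forest":
        reg = RandomForestRegressor(
            n_estimators=int(config.get("n_estimators", 200)),
            max_depth=int(config.get("max_depth", 8)),
            min_samples_leaf=int(config.get("min_samples_leaf", 1)),
            random_state=seed,
            n_jobs=1,
        )
    elif family == "neural_network":
        units = int(config.get("hidden_units", 32))
        layers = (units,) * int(config.get("n_layers", 1))
        reg = Pipeline(
            [
                ("scale", StandardScaler()),
                (
                    "mlp",
                    MLPRegressor(
                        hidden_layer_sizes=layers,
                        alpha=float(config.get("alpha", 1e-4)),
                        max_iter=300,
                        random_state=seed,
                    ),
                ),
            ]
        )
    else:
        raise ValueError(f"unknown model family {family!r}")
    return Pipeline([("encode", encoder), ("reg", reg)])


def _feature_frame(table: pd.DataFrame) -> pd.DataFrame:
    cols = NUMERIC_FEATURES + CATEGORICAL_FEATURES + ["cluster_id"]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature columns missing from table: {missing}")
    X = table[cols].copy()
    X["cluster_id"] = X["cluster_id"].astype(str)
    return X


def random_search_cv(
    train_table: pd.DataFrame,
    family: str = "gradient_boosted_trees",
    search_space: dict | None = None,
    n_samples: int = 15,
    folds: int = 3,
    seed: int = 0,
) -> TuningResult:
    """Random hyperparameter search with patient-grouped K-fold CV.

    Returns the sampled configs, their mean fold MSEs, and the best config
    (smallest mean CV MSE; ties go to the first sampled).  Only the training
    table is ever touched.
    """
    space = DEFAULT_SEARCH_SPACES[family] if search_space is None else search_space
    rng = np.random.default_rng(seed)
    configs = sample_configs(space, n_samples, rng)

    X = _feature_frame(train_table)
    y = train_table["target"].to_numpy(dtype=float)
    groups = train_table["patient_id"].to_numpy()
    gkf = GroupKFold(n_splits=folds)
    splits = list(gkf.split(X, y, groups))

    cv_mse = []
    for cfg in configs:
        fold_mse = []
        for tr_idx, va_idx in splits:
            model = make_model(family, cfg, seed=seed)
            model.fit(X.iloc[tr_idx], y[tr_idx])
            pred = np.clip(model.predict(X.iloc[va_idx]), 0.0, None)
            fold_mse.append(float(np.mean((pred - y[va_idx]) ** 2)))
        cv_mse.append(float(np.mean(fold_mse)))

    best_idx = int(np.argmin(cv_mse))  # argmin ties -> first sampled
    return TuningResult(
        family=family,
        configs=configs,
        cv_mse=cv_mse,
        best_config=configs[best_idx],
        best_cv_mse=cv_mse[best_idx],
        seed=seed,
    )


def fit_and_score(
    train_table: pd.DataFrame,
    test_table: pd.DataFrame,
    family: str = "gradient_boosted_trees",
    config: dict | None = None,
    seed: int = 0,
) -> float:
    """Fit on the training table, return MSE of clipped predictions on test."""
    if len(test_table) == 0:
        raise ValueError("empty test table")
    overlap = set(train_table["patient_id"]) & set(test_table["patient_id"])
    if overlap:
        raise ValueError(f"train/test patient overlap: {sorted(overlap)[:5]} ...")
    model = make_model(family, config or {}, seed=seed)
    model.fit(_feature_frame(train_table), train_table["target"].to_numpy(dtype=float))
    pred = np.clip(model.predict(_feature_frame(test_table)), 0.0, None)
    actual = test_table["target"].to_numpy(dtype=float)
    return float(np.mean((pred - actual) ** 2))


def select_model(results: list[TuningResult]) -> str:
    """Family with the smallest test MSE (ties -> fixed family order)."""
    if not results:
        raise ValueError("no tuning results to select from")
    scored = [(r.test_mse, FAMILY_ORDER.index(r.family), r.family) for r in results]
    if any(s[0] is None for s in scored):
        raise ValueError("all results need a test_mse before selection")
    return min(scored)[2]


class MeanBaseline:
    """Predict the training-set mean target for every row."""

    def __init__(self) -> None:
        self.mean_: float | None = None

    def fit(self, X, y):
        self.mean_ = float(np.mean(y))
        return self

    def predict(self, X):
        if self.mean_ is None:
            raise ValueError("MeanBaseline is not fitted")
        n = len(X)
        return np.full(n, self.mean_)


def predict_week(model, rows: pd.DataFrame) -> np.ndarray:
    """Non-negative next-week workload predictions for active patient rows."""
    if isinstance(model, MeanBaseline):
        raw = model.predict(rows)
    else:
        raw = model.predict(_feature_frame(rows))
    return np.clip(np.asarray(raw, dtype=float), 0.0, None)


class WorkloadPredictor:
    """The full two-stage predictor: cluster assignment + tuned regressor.

    ``fit`` clusters the training rows (k-prototypes, excluding the
    days-since-diagnosis field), appends the cluster id, tunes the chosen
    family by random search, and refits the best config on the full
    training table.  ``predict`` returns clipped non-negative workloads.
    """

    CLUSTER_NUMERIC = [
        "age",
        "adi",
        "rucc",
        "weeks_since_enrollment",
        "util_1wk",
        "util_4wk",
        "util_12wk",
        "util_trend_4wk",
    ]
    CLUSTER_CATEGORICAL = ["sex", "insurance", "cancer_type", "specialty_id"]

    def __init__(
        self,
        family: str = "gradient_boosted_trees",
        k: int = 7,
        n_samples: int = 15,
        folds: int = 3,
        seed: int = 0,
        tune: bool = True,
        cluster_sample: int | None = 50_000,
    ) -> None:
        self.family = family
        self.k = k
        self.n_samples = n_samples
        self.folds = folds
        self.seed = seed
        self.tune = tune
        self.cluster_sample = cluster_sample
        self.cluster_model = None
        self.model = None
        self.tuning: TuningResult | None = None
        self.train_patient_ids: frozenset = frozenset()

    # -- clustering stage ---------------------------------------------------
    def _cluster_ids(self, table: pd.DataFrame) -> np.ndarray:
        from .clustering import assign_cluster

        return assign_cluster(
            self.cluster_model, table[self.CLUSTER_NUMERIC], table[self.CLUSTER_CATEGORICAL]
        )

    def fit(self, train_table: pd.DataFrame) -> "WorkloadPredictor":
        from .clustering import fit_kprototypes

        fit_rows = train_table
        if self.cluster_sample is not None and len(train_table) > self.cluster_sample:
            rng = np.random.default_rng(self.seed)
            idx = rng.choice(len(train_table), size=self.cluster_sample, replace=False)
            fit_rows = train_table.iloc[idx]
        self.cluster_model = fit_kprototypes(
            fit_rows[self.CLUSTER_NUMERIC],
            fit_rows[self.CLUSTER_CATEGORICAL],
            k=self.k,
            seed=self.seed,
        )
        table = train_table.copy()
        table["cluster_id"] = self._cluster_ids(table)

        if self.tune:
            self.tuning = random_search_cv(
                table,
                family=self.family,
                n_samples=self.n_samples,
                folds=self.folds,
                seed=self.seed,
            )
            config = self.tuning.best_config
        else:
            config = {}
        self.model = make_model(self.family, config, seed=self.seed)
        self.model.fit(_feature_frame(table), table["target"].to_numpy(dtype=float))
        self.train_patient_ids = frozenset(table["patient_id"])
        return self

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        if self.model is None:
            raise ValueError("WorkloadPredictor is not fitted")
        rows = rows.copy()
        rows["cluster_id"] = self._cluster_ids(rows)
        return predict_week(self.model, rows)
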