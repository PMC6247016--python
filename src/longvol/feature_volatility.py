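"""Supervised-regression pipeline identifying features predictive of time.

A regressor (random forest by default) learns to predict each sample's
state (e.g. host age) from its feature composition.  Features important
to an accurate model change over time — their abundance carries temporal
information — whereas averages over time smooth such structure away.
Importance does not imply statistical significance; this is an
exploratory screen for temporally informative features.

Pipeline order: (1) seeded random train/test split (4:1 by default,
optionally grouped by subject to prevent within-subject leakage);
(2) optional cross-validated hyperparameter tuning on the training set;
(3) cross-validated recursive feature elimination (RFE) on the training
set, keeping the feature subset with the best CV score; (4) final model
on the selected features; (5) importances extracted and normalized;
(6) MSE and R^2 measured on the untouched test set; (7) per-feature
descriptive statistics; (8) volatility + importance-bar plot specs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import (
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.feature_selection import RFECV
from sklearn.linear_model import ElasticNet
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import (
    GridSearchCV,
    GroupShuffleSplit,
    KFold,
    train_test_split,
)

from .io_formats import FeatureTable, SampleMetadata
from .volatility import volatility_stats, volatility_plot_spec

logger = logging.getLogger(__name__)

ESTIMATORS = ("random-forest", "extra-trees", "gradient-boosting", "elastic-net")

_TUNING_GRIDS = {
    "random-forest": {"max_features": ["sqrt", 0.5, 1.0], "max_depth": [None, 10]},
    "extra-trees": {"max_features": ["sqrt", 0.5, 1.0], "max_depth": [None, 10]},
    "gradient-boosting": {"learning_rate": [0.03, 0.1, 0.3], "max_depth": [2, 3, 5]},
    "elastic-net": {"alpha": [0.01, 0.1, 1.0], "l1_ratio": [0.2, 0.5, 0.8]},
}


@dataclass
class RegressorConfig:
    """Configuration of the regression pipeline.

    ``rfe_step`` is the fraction of features removed per elimination
    round; ``test_fraction`` the held-out proportion (default 0.2, i.e.
    a 4:1 train:test ratio).  A seed is required — there is no silent
    nondeterminism.
    """

    seed: int
    estimator: str = "random-forest"
    n_estimators: int = 100
    parameter_tuning: bool = False
    cv_folds: int = 5
    rfe_step: float = 0.05
    test_fraction: float = 0.2
    group_by_subject: bool = False
    relative_frequency: bool = False

    def __post_init__(self) -> None:
        if self.estimator not in ESTIMATORS:
            raise ValueError(f"unknown estimator {self.estimator!r}; choose from {ESTIMATORS}")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.rfe_step <= 1.0:
            raise ValueError("rfe_step must be in (0, 1]")


@dataclass
class FeatureVolatilityResult:
    """Importances, held-out accuracy, and per-feature descriptive stats."""

    importances: pd.Series  # retained features, descending importance
    mse: float
    r2: float
    stats: pd.DataFrame  # descriptive stats for retained features
    n_important_features: int
    n_train: int
    n_test: int
    test_sample_ids: list[str]
    config: RegressorConfig = field(repr=False)

    def top_features(self, n: int = 10) -> list[str]:
        """Top-n by importance descending, ties broken by feature ID."""
        order = sorted(
            self.importances.items(), key=lambda kv: (-kv[1], kv[0])
        )
        return [k for k, _ in order[:n]]


def _make_estimator(config: RegressorConfig):
    seed = config.seed
    if config.estimator == "random-forest":
        return RandomForestRegressor(
            n_estimators=config.n_estimators, random_state=seed, n_jobs=1
        )
    if config.estimator == "extra-trees":
        return ExtraTreesRegressor(
            n_estimators=config.n_estimators, random_state=seed, n_jobs=1
        )
    if config.estimator == "gradient-boosting":
        return GradientBoostingRegressor(
            n_estimators=config.n_estimators, random_state=seed
        )
    return ElasticNet(random_state=seed, max_iter=10000)


def _importances(model) -> np.ndarray:
    if hasattr(model, "feature_importances_"):
        raw = np.asarray(model.feature_importances_, dtype=float)
    else:  # linear models: magnitude of coefficients
        raw = np.abs(np.asarray(model.coef_, dtype=float))
    total = raw.sum()
    return raw / total if total > 0 else raw


def _align(table: FeatureTable, metadata: SampleMetadata) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    df = metadata.longitudinal_frame()
    shared = [s for s in table.sample_ids if s in df.index]
    if len(shared) < len(table.sample_ids):
        logger.warning(
            "dropping %d table sample(s) without usable metadata",
            len(table.sample_ids) - len(shared),
        )
    X = table.data.loc[shared]
    y = df.loc[shared, metadata.state_column].astype(float)
    groups = df.loc[shared, metadata.subject_column].astype(str)
    return X, y, groups


def feature_volatility(
    table: FeatureTable,
    metadata: SampleMetadata,
    config: RegressorConfig,
) -> FeatureVolatilityResult:
    """Run the full pipeline; see the module docstring for the stages."""
    X, y, groups = _align(table, metadata)
    if len(X) < 20:
        raise ValueError(f"need >= 20 samples, got {len(X)}")
    if y.nunique() < 2:
        raise ValueError("state (regression target) is constant")
    if config.relative_frequency:
        X = FeatureTable(X).to_relative().data

    if config.group_by_subject:
        splitter = GroupShuffleSplit(
            n_splits=1, test_size=config.test_fraction, random_state=config.seed
        )
        (train_idx, test_idx), = splitter.split(X, y, groups=groups)
        X_train, X_test = X.iloc[train_idx], X.iloc[test_idx]
        y_train, y_test = y.iloc[train_idx], y.iloc[test_idx]
    else:
        X_train, X_test, y_train, y_test = train_test_split(
            X, y, test_size=config.test_fraction, random_state=config.seed
        )

    estimator = _make_estimator(config)
    cv = KFold(n_splits=config.cv_folds, shuffle=True, random_state=config.seed)
    if config.parameter_tuning:
        search = GridSearchCV(
            estimator, _TUNING_GRIDS[config.estimator], cv=cv, n_jobs=1
        )
        search.fit(X_train.to_numpy(), y_train.to_numpy())
        estimator = clone(search.best_estimator_)

    selector = RFECV(
        estimator,
        step=config.rfe_step,
        cv=cv,
        min_features_to_select=1,
        n_jobs=1,
    )
    selector.fit(X_train.to_numpy(), y_train.to_numpy())
    selected = list(X.columns[selector.support_])
    if not selected:
        raise ValueError(
            "recursive feature elimination retained no features; "
            "the table may carry no signal for the state column"
        )
    final_model = selector.estimator_  # refit on selected training features

    imp = pd.Series(_importances(final_model), index=selected)
    imp = imp.sort_values(ascending=False)

    predictions = final_model.predict(X_test[selected].to_numpy())
    mse = float(mean_squared_error(y_test, predictions))
    r2 = float(r2_score(y_test, predictions))

    stats = feature_descriptive_stats(
        FeatureTable(X[selected]), metadata
    )
    return FeatureVolatilityResult(
        importances=imp,
        mse=mse,
        r2=r2,
        stats=stats,
        n_important_features=len(selected),
        n_train=len(X_train),
        n_test=len(X_test),
        test_sample_ids=list(X_test.index),
        config=config,
    )


def feature_descriptive_stats(
    table: FeatureTable, metadata: SampleMetadata
) -> pd.DataFrame:
    """Per-feature descriptive statistics over the aligned samples.

    Per feature: mean, median, variance, SD (sample, ddof=1), coefficient
    of variation (SD/mean; missing when the mean is 0), and — from the
    per-state mean abundances m_f(t) over ascending states — the net
    average change m_f(t_k) - m_f(t_1), the cumulative average increase
    sum(max(0, step)) and the cumulative average decrease
    sum(min(0, step)), so increase + decrease = net exactly.
    """
    X, y, _ = _align(table, metadata)
    states = np.sort(y.unique())
    if len(states) < 2:
        logger.warning("single state observed; change statistics reported as 0")
    rows = []
    state_means = X.groupby(y).mean().sort_index()  # states x features
    for feature in X.columns:
        v = X[feature].to_numpy(dtype=float)
        mean = float(v.mean())
        sd = float(v.std(ddof=1)) if len(v) > 1 else 0.0
        m = state_means[feature].to_numpy(dtype=float)
        steps = np.diff(m) if len(m) > 1 else np.array([])
        rows.append(
            {
                "feature-id": feature,
                "mean": mean,
                "median": float(np.median(v)),
                "variance": sd**2,
                "std": sd,
                "cv": sd / mean if mean != 0 else np.nan,
                "net_avg_change": float(m[-1] - m[0]) if len(m) > 1 else 0.0,
                "cumulative_avg_increase": float(np.maximum(steps, 0).sum()),
                "cumulative_avg_decrease": float(np.minimum(steps, 0).sum()),
            }
        )
    return pd.DataFrame(rows).set_index("feature-id")


def feature_volatility_plot_spec(
    result: FeatureVolatilityResult,
    table: FeatureTable,
    metadata: SampleMetadata,
    group_column: str | None = None,
    top_n: int = 10,
) -> dict:
    """Combined document: per-feature volatility charts for the top
    features plus an importance/descriptive-stat bar chart over all
    retained features."""
    top = result.top_features(top_n)
    X, _, _ = _align(table, metadata)
    charts = []
    for feature in top:
        enriched = metadata.frame.copy()
        enriched[feature] = X[feature]
        md = SampleMetadata(
            enriched, metadata.state_column, metadata.subject_column,
            {**metadata.column_types, feature: "numeric"},
        )
        stats = volatility_stats(md, feature, group_column)
        charts.append(volatility_plot_spec(stats, title=f"Abundance of {feature}"))
    bars = {
        "mark": "bar",
        "role": "feature-metadata",
        "fields": ["importance", *result.stats.columns],
        "rows": [
            {
                "feature-id": f,
                "importance": float(result.importances[f]),
                **{k: _json_safe(v) for k, v in result.stats.loc[f].items()},
            }
            for f in result.importances.index
        ],
    }
    return {
        "$schema": "longvol/feature-volatility/v1",
        "accuracy": {"mse": result.mse, "r2": result.r2},
        "n_important_features": result.n_important_features,
        "volatility_charts": charts,
        "feature_bars": bars,
    }


def _json_safe(v):
    v = float(v)
    return None if np.isnan(v) else v
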