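"""Multi-horizon demand regression: lagged datasets, model fits, comparison.

Predictors observed on day t are paired with the help-seeking count at day
t + L for horizons L in {1, 3, 7, 14}.  Five regressor families are
compared — ordinary least squares, ridge, lasso, linear-kernel support
vector regression, and random forest — under out-of-fold 10-fold
cross-validation, scored by mean absolute error (MAE), the Pearson
correlation between out-of-fold predictions and truth, and the
MAE-to-mean ratio in percent.  A feature-set combination search evaluates
all 15 non-empty subsets of the four predictor blocks (liwc, topic,
temporal, covid) plus the decomposition forecast baseline.

The modelling surface is statsmodels-shaped: :class:`DemandModel` is built
from data and ``fit()`` returns a :class:`DemandModelResults` carrying the
scores, out-of-fold predictions, the refitted estimator, a ``summary()``
table, and Shapley-attribution accessors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LassoCV, LinearRegression, RidgeCV
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .temporal import DecompositionConfig, fit_decomposition

__all__ = [
    "BLOCK_NAMES",
    "ALGORITHMS",
    "HORIZONS",
    "FeatureBundle",
    "LaggedDataset",
    "ModelConfig",
    "DemandModel",
    "DemandModelResults",
    "mae",
    "pearson",
    "mae_to_mean_ratio",
    "build_lagged_dataset",
    "fit_and_evaluate",
    "compare_feature_sets",
    "mean_baseline_mae",
]

BLOCK_NAMES = ("liwc", "topic", "temporal", "covid")
ALGORITHMS = ("lr", "ridge", "lasso", "svr", "rf")
HORIZONS = (1, 3, 7, 14)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def mae(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Mean absolute error; translation-equivariant and non-negative."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("mae needs two equal-length vectors of length >= 2")
    if not (np.all(np.isfinite(y_true)) and np.all(np.isfinite(y_pred))):
        raise ValueError("mae inputs must be finite")
    return float(np.mean(np.abs(y_true - y_pred)))


def pearson(y_true: Sequence[float], y_pred: Sequence[float]) -> float:
    """Sample Pearson correlation; raises if either vector is constant."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 3:
        raise ValueError("pearson needs two equal-length vectors of length >= 3")
    if np.std(y_true) == 0 or np.std(y_pred) == 0:
        raise ValueError("pearson undefined: zero variance input")
    return float(stats.pearsonr(y_true, y_pred)[0])


def mae_to_mean_ratio(mae_value: float, mean_value: float) -> float:
    """MAE divided by the target mean, in percent."""
    if mean_value == 0:
        raise ValueError("mean of the target is zero; ratio undefined")
    return 100.0 * float(mae_value) / float(mean_value)


# ---------------------------------------------------------------------------
# Feature bundle and lagged dataset
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureBundle:
    """The four named predictor blocks aligned on one daily calendar.

    Block columns are prefixed ``<block>__<column>`` so provenance survives
    concatenation; missing values are zero-filled at construction (epidemic
    covariates before the outbreak start are zero).
    """

    blocks: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("bundle needs at least one block")
        index = None
        prefixed = {}
        for name, frame in self.blocks.items():
            if index is None:
                index = frame.index
            elif not frame.index.equals(index):
                raise ValueError(f"block {name!r} is not aligned on the shared calendar")
            frame = frame.fillna(0.0)
            frame = frame.rename(
                columns={
                    c: c if str(c).startswith(f"{name}__") else f"{name}__{c}"
                    for c in frame.columns
                }
            )
            prefixed[name] = frame
        object.__setattr__(self, "blocks", prefixed)

    @property
    def calendar(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(next(iter(self.blocks.values())).index)

    def frame(self, blocks: Sequence[str] | None = None) -> pd.DataFrame:
        names = tuple(blocks) if blocks is not None else tuple(self.blocks)
        unknown = [b for b in names if b not in self.blocks]
        if unknown:
            raise KeyError(f"unknown blocks {unknown}; have {list(self.blocks)}")
        return pd.concat([self.blocks[b] for b in names], axis=1)


@dataclass(frozen=True)
class LaggedDataset:
    """Aligned design: X at predictor day t, y at target day t + horizon."""

    horizon: int
    X: pd.DataFrame
    y: pd.Series          # indexed by predictor date, values from t + horizon
    target_dates: pd.DatetimeIndex

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.X.columns)


def build_lagged_dataset(
    bundle: FeatureBundle,
    target: pd.Series,
    horizon: int,
    blocks: Sequence[str] | None = None,
) -> LaggedDataset:
    """Pair the chosen blocks' features at day t with the count at day t + L."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    calendar = bundle.calendar
    if not calendar.is_monotonic_increasing:
        raise ValueError("bundle calendar must be date-sorted")
    target = target.reindex(calendar)
    if target.isna().any():
        raise ValueError("target does not cover the bundle calendar")
    m = len(calendar)
    if horizon >= m:
        raise ValueError(f"horizon {horizon} >= calendar length {m}: empty dataset")
    X = bundle.frame(blocks).iloc[: m - horizon]
    y = pd.Series(
        target.to_numpy()[horizon:], index=X.index, name=f"count_t+{horizon}"
    )
    return LaggedDataset(
        horizon=int(horizon),
        X=X,
        y=y,
        target_dates=calendar[horizon:],
    )


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelConfig:
    """Regressor hyperparameters and evaluation settings."""

    n_splits: int = 10
    rf_n_estimators: int = 500
    rf_max_depth: int | None = None
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    inner_cv: int = 5
    alpha_grid: tuple[float, ...] = tuple(np.logspace(-3, 3, 13))
    log_target: bool = False
    temporal_mode: str = "full"   # "full" (optimistic, fits on all days) or "causal"

    def __post_init__(self) -> None:
        if self.temporal_mode not in ("full", "causal"):
            raise ValueError("temporal_mode must be 'full' or 'causal'")


def _make_estimator(algorithm: str, config: ModelConfig, seed: int):
    if algorithm == "lr":
        core = LinearRegression()
    elif algorithm == "ridge":
        core = RidgeCV(alphas=config.alpha_grid, cv=config.inner_cv)
    elif algorithm == "lasso":
        core = LassoCV(
            alphas=config.alpha_grid,
            cv=config.inner_cv,
            random_state=seed,
            max_iter=50_000,
        )
    elif algorithm == "svr":
        core = SVR(kernel="linear", C=config.svr_c, epsilon=config.svr_epsilon)
    elif algorithm == "rf":
        return RandomForestRegressor(
            n_estimators=config.rf_n_estimators,
            max_depth=config.rf_max_depth,
            random_state=seed,
            n_jobs=1,
        )
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    # Linear-family models see standardised features; the forest sees raw ones.
    return Pipeline([("scale", StandardScaler()), ("model", core)])


def _split_indices(n: int, split: str, n_splits: int, seed: int):
    if split == "kfold10":
        yield from KFold(n_splits=n_splits, shuffle=True, random_state=seed).split(
            np.arange(n)
        )
    elif split == "blocked":
        bounds = np.linspace(0, n, n_splits + 1).astype(int)
        all_idx = np.arange(n)
        for a, b in zip(bounds[:-1], bounds[1:]):
            test = all_idx[a:b]
            train = np.concatenate([all_idx[:a], all_idx[b:]])
            yield train, test
    else:
        raise ValueError(f"unknown split scheme {split!r}")


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class DemandModel:
    """A demand regression bound to one lagged dataset and one algorithm.

    Parameters
    ----------
    dataset : LaggedDataset
        Aligned predictors and lagged target.
    algorithm : str
        One of ``lr``, ``ridge``, ``lasso``, ``svr``, ``rf``.
    config : ModelConfig, optional
        Hyperparameters; defaults follow the package's documented choices.
    """

    def __init__(
        self,
        dataset: LaggedDataset,
        algorithm: str = "rf",
        config: ModelConfig | None = None,
        _bundle: FeatureBundle | None = None,
        _target: pd.Series | None = None,
        _blocks: Sequence[str] | None = None,
    ) -> None:
        if algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
        self.dataset = dataset
        self.algorithm = algorithm
        self.config = config or ModelConfig()
        self._bundle = _bundle
        self._target = _target
        self._blocks = tuple(_blocks) if _blocks is not None else None

    @classmethod
    def from_bundle(
        cls,
        bundle: FeatureBundle,
        target: pd.Series,
        horizon: int,
        blocks: Sequence[str] | None = None,
        algorithm: str = "rf",
        config: ModelConfig | None = None,
    ) -> "DemandModel":
        dataset = build_lagged_dataset(bundle, target, horizon, blocks)
        return cls(
            dataset,
            algorithm=algorithm,
            config=config,
            _bundle=bundle,
            _target=target,
            _blocks=blocks,
        )

    # -- causal temporal features -------------------------------------------------

    def _causal_X(self, train_idx: np.ndarray) -> pd.DataFrame:
        """Rebuild the temporal block with a decomposition fitted on training days only."""
        if self._bundle is None or self._target is None:
            raise ValueError(
                "temporal_mode='causal' requires a model built via from_bundle()"
            )
        X = self.dataset.X
        temporal_cols = [c for c in X.columns if c.startswith("temporal__")]
        if not temporal_cols:
            return X
        calendar = self._bundle.calendar
        mask = np.zeros(len(calendar), dtype=bool)
        mask[train_idx] = True  # predictor days of the training rows
        model = fit_decomposition(
            self._target.reindex(calendar), fit_mask=mask
        )
        comp = model.components(pd.DatetimeIndex(X.index))
        X = X.copy()
        for col in temporal_cols:
            X[col] = comp[col.split("__", 1)[1]].to_numpy()
        return X

    # -- fitting -------------------------------------------------------------

    def fit(self, split: str = "kfold10", seed: int = 0) -> "DemandModelResults":
        """Out-of-fold evaluation plus a final refit on all rows."""
        X_full = self.dataset.X
        y = self.dataset.y.to_numpy(dtype=float)
        n = len(y)
        if n < 20:
            raise ValueError(f"dataset has {n} rows; need >= 20 for cross-validation")
        y_fit = np.log1p(y) if self.config.log_target else y

        oof = np.full(n, np.nan)
        for train_idx, test_idx in _split_indices(
            n, split, self.config.n_splits, seed
        ):
            X = (
                self._causal_X(train_idx)
                if self.config.temporal_mode == "causal"
                else X_full
            )
            est = _make_estimator(self.algorithm, self.config, seed)
            est.fit(X.iloc[train_idx], y_fit[train_idx])
            oof[test_idx] = est.predict(X.iloc[test_idx])
        if self.config.log_target:
            oof = np.expm1(oof)

        estimator = _make_estimator(self.algorithm, self.config, seed)
        estimator.fit(X_full, y_fit)

        mae_value = mae(y, oof)
        try:
            r = pearson(y, oof)
            p = float(stats.pearsonr(y, oof)[1])
        except ValueError:
            warnings.warn("constant predictions or target: Pearson r undefined")
            r, p = float("nan"), float("nan")
        return DemandModelResults(
            model=self,
            estimator_=estimator,
            oof_pred=pd.Series(oof, index=self.dataset.X.index, name="oof_pred"),
            mae=mae_value,
            pearson_r=r,
            pearson_p=p,
            mae_ratio_pct=mae_to_mean_ratio(mae_value, float(np.mean(y))),
            split=split,
            seed=seed,
        )


@dataclass
class DemandModelResults:
    """Fit results: scores, out-of-fold predictions, and the refit estimator."""

    model: DemandModel
    estimator_: object
    oof_pred: pd.Series
    mae: float
    pearson_r: float
    pearson_p: float
    mae_ratio_pct: float
    split: str
    seed: int

    @property
    def dataset(self) -> LaggedDataset:
        return self.model.dataset

    def predict(self, X: pd.DataFrame | None = None) -> np.ndarray:
        X = self.dataset.X if X is None else X
        pred = self.estimator_.predict(X)
        return np.expm1(pred) if self.model.config.log_target else pred

    def shap_values(
        self,
        method: str = "exact",
        background: pd.DataFrame | None = None,
        seed: int = 0,
        **kwargs,
    ):
        """Shapley attributions of the refit estimator over the design matrix."""
        from .interpretation import shapley_attributions

        estimator = self.estimator_
        if method == "tree":
            if not isinstance(estimator, RandomForestRegressor):
                raise ValueError("method='tree' requires the rf algorithm")
        return shapley_attributions(
            estimator,
            self.dataset.X,
            method=method,
            background=background,
            seed=seed,
            **kwargs,
        )

    def feature_sets(self) -> dict[str, list[str]]:
        """Feature names grouped by predictor block (for set-level SHAP)."""
        groups: dict[str, list[str]] = {}
        for name in self.dataset.feature_names:
            block = name.split("__", 1)[0] if "__" in name else "other"
            groups.setdefault(block, []).append(name)
        return groups

    def summary(self) -> str:
        lines = [
            "Demand regression results",
            "=" * 46,
            f"{'algorithm':<22}{self.model.algorithm}",
            f"{'horizon (days)':<22}{self.dataset.horizon}",
            f"{'rows':<22}{self.dataset.n_rows}",
            f"{'features':<22}{len(self.dataset.feature_names)}",
            f"{'split':<22}{self.split} (seed {self.seed})",
            f"{'MAE (out-of-fold)':<22}{self.mae:.3f}",
            f"{'Pearson r':<22}{self.pearson_r:.3f}",
            f"{'MAE / mean (%)':<22}{self.mae_ratio_pct:.2f}",
            "=" * 46,
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Spec-surface wrappers
# ---------------------------------------------------------------------------


def fit_and_evaluate(
    dataset: LaggedDataset,
    algorithm: str,
    split: str = "kfold10",
    seed: int = 0,
    config: ModelConfig | None = None,
) -> tuple[dict, DemandModelResults]:
    """Fit one regressor on one lagged dataset; return a report row + results."""
    results = DemandModel(dataset, algorithm=algorithm, config=config).fit(
        split=split, seed=seed
    )
    row = {
        "algorithm": algorithm,
        "horizon": dataset.horizon,
        "blocks": "+".join(
            sorted({c.split("__", 1)[0] for c in dataset.feature_names})
        ),
        "mae": results.mae,
        "pearson_r": results.pearson_r,
        "mae_ratio_pct": results.mae_ratio_pct,
        "split": split,
        "seed": seed,
    }
    return row, results


def mean_baseline_mae(
    dataset: LaggedDataset, split: str = "kfold10", seed: int = 0, n_splits: int = 10
) -> float:
    """Out-of-fold MAE of the train-fold-mean predictor (the no-skill floor)."""
    y = dataset.y.to_numpy(dtype=float)
    oof = np.full(len(y), np.nan)
    for train_idx, test_idx in _split_indices(len(y), split, n_splits, seed):
        oof[test_idx] = np.mean(y[train_idx])
    return mae(y, oof)


def compare_feature_sets(
    bundle: FeatureBundle,
    target: pd.Series,
    horizons: Iterable[int] = HORIZONS,
    algorithm: str = "rf",
    split: str = "kfold10",
    seed: int = 0,
    config: ModelConfig | None = None,
    include_baseline: bool = True,
) -> pd.DataFrame:
    """Evaluate all 15 non-empty block combinations per horizon.

    Returns one row per (combination, horizon), plus — when
    ``include_baseline`` — one decomposition-baseline row per horizon whose
    forecasts are the fitted yhat at the target days.  The best-MAE
    combination per horizon is flagged ``optimal``.
    """
    config = config or ModelConfig()
    available = [b for b in BLOCK_NAMES if b in bundle.blocks]
    combos = [
        combo
        for size in range(1, len(available) + 1)
        for combo in combinations(available, size)
    ]
    rows = []
    for horizon in horizons:
        for combo in combos:
            dataset = build_lagged_dataset(bundle, target, horizon, combo)
            model = DemandModel(
                dataset,
                algorithm=algorithm,
                config=config,
                _bundle=bundle,
                _target=target,
                _blocks=combo,
            )
            results = model.fit(split=split, seed=seed)
            rows.append(
                {
                    "algorithm": algorithm,
                    "horizon": horizon,
                    "blocks": "+".join(combo),
                    "mae": results.mae,
                    "pearson_r": results.pearson_r,
                    "mae_ratio_pct": results.mae_ratio_pct,
                    "split": split,
                    "seed": seed,
                }
            )
        if include_baseline:
            rows.append(
                _decomposition_baseline_row(bundle, target, horizon, split, seed)
            )
    report = pd.DataFrame(rows)
    report["optimal"] = False
    fitted = report["algorithm"] == algorithm
    for horizon in set(report["horizon"]):
        sub = report[fitted & (report["horizon"] == horizon)]
        report.loc[sub["mae"].idxmin(), "optimal"] = True
    return report


def _decomposition_baseline_row(
    bundle: FeatureBundle, target: pd.Series, horizon: int, split: str, seed: int
) -> dict:
    calendar = bundle.calendar
    y_series = target.reindex(calendar)
    model = fit_decomposition(y_series)
    yhat = model.components(calendar)["yhat"].to_numpy()
    y = y_series.to_numpy(dtype=float)[horizon:]
    pred = yhat[horizon:]
    mae_value = mae(y, pred)
    return {
        "algorithm": "decomposition_baseline",
        "horizon": horizon,
        "blocks": "",
        "mae": mae_value,
        "pearson_r": pearson(y, pred),
        "mae_ratio_pct": mae_to_mean_ratio(mae_value, float(np.mean(y))),
        "split": "in_sample",
        "seed": seed,
    }
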