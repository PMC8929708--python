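"""Shapley attributions and the cumulative set-level statistic.

Per-day, per-feature Shapley values are computed against a background
sample under the interventional (background-replacement) value function:
the payoff of a feature coalition S at row x is the mean model output over
background rows with the S columns replaced by x's values.  Three routes
are provided:

* ``exact`` — full 2^P coalition enumeration (P <= 12), any model;
* ``tree`` — the same enumeration carried out per tree of a random forest
  through the tree structure, cross-checking the ensemble route;
* ``sampling`` — seeded permutation sampling, usable at any P; each sampled
  permutation's contributions sum exactly to prediction - base, so local
  accuracy holds for the average too.

The set-level summary accumulates all positive (respectively negative)
attributions over the days and member features of each named feature set,
alongside the per-feature count of positive entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AttributionMatrix",
    "SetAttributionSummary",
    "FeatureRanking",
    "LocalExplanation",
    "shapley_attributions",
    "cumulative_set_shap",
    "top_k_features",
    "local_explanation",
]

LOCAL_ACCURACY_TOL = 1e-6
MAX_EXACT_FEATURES = 12


@dataclass(frozen=True)
class AttributionMatrix:
    """M x P Shapley values with the shared base value and per-day predictions.

    Local accuracy — base_value + sum_j SHAP_ij = prediction_i — is enforced
    at construction to within ``1e-6``.
    """

    values: pd.DataFrame
    base_value: float
    predictions: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.predictions.index):
            raise ValueError("attributions and predictions must share an index")
        recon = self.base_value + self.values.sum(axis=1)
        err = np.max(np.abs(recon.to_numpy() - self.predictions.to_numpy()))
        if err > LOCAL_ACCURACY_TOL * max(1.0, float(np.abs(self.predictions).max())):
            raise ValueError(f"local accuracy violated: max error {err:.3g}")

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def n_days(self) -> int:
        return len(self.values)


def _predict_fn(model, columns=None) -> Callable[[np.ndarray], np.ndarray]:
    if callable(model) and not hasattr(model, "predict"):
        return lambda a: np.asarray(model(a), dtype=float)
    if columns is not None:
        # Estimators fitted on DataFrames expect the feature names back.
        return lambda a: np.asarray(
            model.predict(pd.DataFrame(a, columns=list(columns))), dtype=float
        )
    return lambda a: np.asarray(model.predict(a), dtype=float)


def _coalition_values(
    predict: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
) -> dict[int, np.ndarray]:
    """v[S] per foreground row for every coalition bitmask S."""
    m, p = X.shape
    b = background.shape[0]
    tiled = np.tile(background, (m, 1))           # (m*b, p), row blocks per x
    repeat_rows = np.repeat(np.arange(m), b)
    values: dict[int, np.ndarray] = {}
    for mask in range(1 << p):
        hybrid = tiled.copy()
        for j in range(p):
            if mask >> j & 1:
                hybrid[:, j] = X[repeat_rows, j]
        values[mask] = predict(hybrid).reshape(m, b).mean(axis=1)
    return values


def _combine_coalitions(values: Mapping[int, np.ndarray], m: int, p: int) -> np.ndarray:
    """Shapley combination phi_j = sum_S w(|S|) (v[S+j] - v[S])."""
    weights = np.array(
        [1.0 / (p * comb(p - 1, s)) for s in range(p)]
    )  # |S|!(P-|S|-1)!/P! for |S| = s
    phi = np.zeros((m, p))
    for mask, v in values.items():
        size = bin(mask).count("1")
        if size == p:
            continue
        for j in range(p):
            if not mask >> j & 1:
                phi[:, j] += weights[size] * (values[mask | (1 << j)] - v)
    return phi


def _background_matrix(
    X: pd.DataFrame,
    background: pd.DataFrame | None,
    max_background: int,
    background_seed: int,
) -> np.ndarray:
    if background is not None:
        return background.to_numpy(dtype=float)
    array = X.to_numpy(dtype=float)
    if len(array) <= max_background:
        return array
    rng = np.random.default_rng(background_seed)
    idx = np.sort(rng.choice(len(array), size=max_background, replace=False))
    return array[idx]


def shapley_attributions(
    model,
    X: pd.DataFrame,
    method: str = "exact",
    background: pd.DataFrame | None = None,
    seed: int = 0,
    n_permutations: int = 100,
    max_background: int = 100,
    background_seed: int = 0,
) -> AttributionMatrix:
    """Interventional Shapley attributions for every row of ``X``.

    ``model`` is a fitted estimator with ``predict`` (or a bare callable).
    ``background`` defaults to ``X`` itself, subsampled to
    ``max_background`` rows.  The subsample is drawn with its own
    ``background_seed`` — deliberately decoupled from the sampling
    ``seed`` — so the exact, tree and sampling routes explain against the
    same reference distribution by default; the base value is the mean
    prediction over the background sample.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    p = X.shape[1]
    predict = _predict_fn(model, columns=X.columns)
    bg = _background_matrix(X, background, max_background, background_seed)
    x_arr = X.to_numpy(dtype=float)
    m = x_arr.shape[0]

    if method == "exact":
        if p > MAX_EXACT_FEATURES:
            raise ValueError(
                f"exact enumeration supports at most {MAX_EXACT_FEATURES} features "
                f"(got {p}); use method='sampling'"
            )
        values = _coalition_values(predict, x_arr, bg)
        phi = _combine_coalitions(values, m, p)
        base = float(values[0][0])
        preds = values[(1 << p) - 1]
    elif method == "tree":
        phi, base, preds = _tree_attributions(model, x_arr, bg)
    elif method == "sampling":
        phi, base, preds = _sampling_attributions(
            predict, x_arr, bg, seed=seed, n_permutations=n_permutations
        )
    else:
        raise ValueError(f"unknown method {method!r}; choose exact, tree, or sampling")

    return AttributionMatrix(
        values=pd.DataFrame(phi, index=X.index, columns=X.columns),
        base_value=base,
        predictions=pd.Series(preds, index=X.index, name="prediction"),
    )


def _tree_attributions(model, X: np.ndarray, background: np.ndarray):
    """Per-tree coalition enumeration for a random forest.

    Each tree's coalition payoffs are evaluated through its own structure
    and combined into per-tree Shapley values, which are then averaged over
    the ensemble — an independent route whose result must coincide with the
    ensemble-level exact enumeration (by linearity of both the forest and
    the Shapley operator).
    """
    try:
        trees = model.estimators_
    except AttributeError:
        raise ValueError("method='tree' requires a fitted tree ensemble") from None
    m, p = X.shape
    if p > MAX_EXACT_FEATURES:
        raise ValueError(
            f"tree enumeration supports at most {MAX_EXACT_FEATURES} features; "
            "use method='sampling'"
        )
    phi = np.zeros((m, p))
    base = 0.0
    preds = np.zeros(m)
    for tree in trees:
        values = _coalition_values(
            lambda a, _t=tree: _t.predict(a), X, background
        )
        phi += _combine_coalitions(values, m, p)
        base += float(values[0][0])
        preds += values[(1 << p) - 1]
    n = len(trees)
    return phi / n, base / n, preds / n


def _sampling_attributions(
    predict: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    seed: int,
    n_permutations: int,
):
    """Permutation-sampling Shapley estimates.

    For each sampled feature order, features are switched from background to
    foreground one at a time and the mean prediction change is credited to
    the switched feature; contributions along one permutation telescope to
    prediction - base, so the permutation average keeps local accuracy
    exactly.
    """
    rng = np.random.default_rng(seed)
    m, p = X.shape
    b = background.shape[0]
    tiled = np.tile(background, (m, 1))
    repeat_rows = np.repeat(np.arange(m), b)

    base_vec = predict(background)
    base = float(base_vec.mean())
    phi = np.zeros((m, p))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        hybrid = tiled.copy()
        prev = np.full(m, base)
        for j in order:
            hybrid[:, j] = X[repeat_rows, j]
            current = predict(hybrid).reshape(m, b).mean(axis=1)
            phi[:, j] += current - prev
            prev = current
    phi /= n_permutations

    # Telescoping guarantees sum phi = v(full) - base per permutation, and
    # v(full) is exactly the model prediction at x, so local accuracy holds.
    preds = predict(X)
    return phi, base, preds


# ---------------------------------------------------------------------------
# Set-level accumulation, rankings, local explanations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SetAttributionSummary:
    """Cumulative positive/negative attribution per named feature set.

    ``table`` rows: cumulative_positive (sum of positive entries over all
    days and member features), cumulative_negative (sum of negative
    entries, <= 0), and total_absolute = positive - negative.
    ``positive_counts`` holds X_i, the number of positive entries per
    feature.
    """

    table: pd.DataFrame
    positive_counts: pd.Series

    def __post_init__(self) -> None:
        if (self.table["cumulative_positive"] < 0).any():
            raise ValueError("cumulative_positive must be >= 0")
        if (self.table["cumulative_negative"] > 0).any():
            raise ValueError("cumulative_negative must be <= 0")


def cumulative_set_shap(
    attr: AttributionMatrix,
    feature_sets: Mapping[str, Sequence[str]],
) -> SetAttributionSummary:
    """Accumulate positive and negative attributions over each feature set."""
    available = set(attr.feature_names)
    rows = {}
    for set_name, members in feature_sets.items():
        unknown = [f for f in members if f not in available]
        if unknown:
            raise KeyError(
                f"feature set {set_name!r} references unknown features {unknown}"
            )
        block = attr.values[list(members)].to_numpy()
        positive = float(block[block > 0].sum())
        negative = float(block[block < 0].sum())
        rows[set_name] = {
            "cumulative_positive": positive,
            "cumulative_negative": negative,
            "total_absolute": positive - negative,
        }
    counts = (attr.values > 0).sum(axis=0)
    counts.name = "positive_entries"
    return SetAttributionSummary(
        table=pd.DataFrame.from_dict(rows, orient="index"),
        positive_counts=counts,
    )


@dataclass(frozen=True)
class FeatureRanking:
    """Features ordered by mean |SHAP| with running cumulative share."""

    table: pd.DataFrame
    k: int

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.table["feature"])


def top_k_features(attr: AttributionMatrix, k: int) -> FeatureRanking:
    """Rank features by mean |SHAP| over days; ties break alphabetically."""
    p = len(attr.feature_names)
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    mean_abs = attr.values.abs().mean(axis=0)
    ordered = sorted(mean_abs.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(v for _, v in ordered)
    table = pd.DataFrame(ordered[:k], columns=["feature", "mean_abs_shap"])
    if total > 0:
        table["cumulative_share"] = table["mean_abs_shap"].cumsum() / total
    else:
        table["cumulative_share"] = 0.0
    return FeatureRanking(table=table, k=int(k))


@dataclass(frozen=True)
class LocalExplanation:
    """One day's prediction decomposed into signed feature contributions."""

    date: pd.Timestamp
    prediction: float
    base_value: float
    contributions: tuple[tuple[str, float], ...]


def local_explanation(attr: AttributionMatrix, date) -> LocalExplanation:
    """The force-plot data behind a single day: base, prediction, contributions.

    Contributions are ordered by |SHAP| descending; exact zeros are dropped.
    """
    stamp = pd.Timestamp(date)
    if stamp not in attr.values.index:
        raise KeyError(f"date {stamp.date()} not in the attribution calendar")
    row = attr.values.loc[stamp]
    contributions = tuple(
        (name, float(value))
        for name, value in sorted(
            row.items(), key=lambda kv: (-abs(kv[1]), kv[0])
        )
        if value != 0.0
    )
    return LocalExplanation(
        date=stamp,
        prediction=float(attr.predictions.loc[stamp]),
        base_value=attr.base_value,
        contributions=contributions,
    )
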