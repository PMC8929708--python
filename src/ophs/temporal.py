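"""Additive trend/seasonality decomposition and platform lead-lag analysis.

The daily count series y(t) is modelled as

    y(t) = g(t) + s_weekly(t) + s_yearly(t) + noise,

with g a continuous piecewise-linear trend (evenly spaced changepoints) and
the seasonal terms truncated Fourier series with periods 7 and 365.25 days.
Coefficients are estimated by ridge-penalised least squares (the changepoint
slope deltas and Fourier coefficients are penalised; intercept and base
slope are not), so the fit is deterministic and closed-form.  The model
emits the five temporal predictor columns — trend, weekly, yearly,
additive_terms (= weekly + yearly) and yhat (= trend + additive_terms) —
and extrapolates beyond the fit window as a forecast baseline.

Lead-lag analysis correlates the secondary platform's series at day t with
the primary series at day t - L for each candidate lag L: the lag is the
number of days the secondary platform trails the primary community, and the
argmax-|r| lag estimates the coupling delay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DecompositionConfig",
    "DecompositionModel",
    "TEMPORAL_COLUMNS",
    "LeadLagTable",
    "fit_decomposition",
    "extract_temporal_features",
    "forecast_baseline",
    "lead_lag_correlation",
]

TEMPORAL_COLUMNS = ("trend", "weekly", "yearly", "additive_terms", "yhat")

WEEKLY_PERIOD = 7.0
YEARLY_PERIOD = 365.25


@dataclass(frozen=True)
class DecompositionConfig:
    """Decomposition hyperparameters (Prophet-like conventions)."""

    weekly_order: int = 3
    yearly_order: int = 10
    n_changepoints: int = 25
    changepoint_range: float = 0.8
    ridge: float = 0.5

    def __post_init__(self) -> None:
        if self.weekly_order < 0 or self.yearly_order < 0:
            raise ValueError("Fourier orders must be non-negative")
        if not 0.0 < self.changepoint_range <= 1.0:
            raise ValueError("changepoint_range must be in (0, 1]")
        if self.ridge < 0:
            raise ValueError("ridge weight must be non-negative")


def _fourier(t: np.ndarray, period: float, order: int) -> np.ndarray:
    if order == 0:
        return np.empty((t.shape[0], 0))
    cols = []
    for h in range(1, order + 1):
        angle = 2.0 * np.pi * h * t / period
        cols.append(np.sin(angle))
        cols.append(np.cos(angle))
    return np.column_stack(cols)


@dataclass(frozen=True)
class DecompositionModel:
    """Fitted additive decomposition; evaluates components on any calendar."""

    start: pd.Timestamp
    n_fit: int
    changepoints: np.ndarray       # in scaled time tau = t / (n_fit - 1)
    trend_coef: np.ndarray         # [intercept, slope, delta_1..delta_C]
    weekly_coef: np.ndarray
    yearly_coef: np.ndarray
    config: DecompositionConfig

    def _trend_design(self, t: np.ndarray) -> np.ndarray:
        tau = t / max(self.n_fit - 1, 1)
        hinges = np.clip(tau[:, None] - self.changepoints[None, :], 0.0, None)
        return np.column_stack([np.ones_like(tau), tau, hinges])

    def components(self, calendar: pd.DatetimeIndex) -> pd.DataFrame:
        """Evaluate trend/weekly/yearly/additive_terms/yhat on ``calendar``.

        The identities yhat = trend + additive_terms and additive_terms =
        weekly + yearly hold exactly by construction.
        """
        t = (calendar - self.start).days.to_numpy(dtype=float)
        trend = self._trend_design(t) @ self.trend_coef
        weekly = _fourier(t, WEEKLY_PERIOD, self.config.weekly_order) @ self.weekly_coef
        yearly = _fourier(t, YEARLY_PERIOD, self.config.yearly_order) @ self.yearly_coef
        additive = weekly + yearly
        return pd.DataFrame(
            {
                "trend": trend,
                "weekly": weekly,
                "yearly": yearly,
                "additive_terms": additive,
                "yhat": trend + additive,
            },
            index=calendar,
        )

    @property
    def fit_calendar(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.n_fit, freq="D", name="date")


def _fit_penalized(
    values: np.ndarray,
    t: np.ndarray,
    n_fit: int,
    config: DecompositionConfig,
    start: pd.Timestamp,
) -> DecompositionModel:
    tau = t / max(n_fit - 1, 1)
    horizon = config.changepoint_range
    n_cp = min(config.n_changepoints, max(n_fit // 2 - 1, 0))
    if n_cp > 0:
        changepoints = np.linspace(0.0, horizon, n_cp + 2)[1:-1]
    else:
        changepoints = np.empty(0)

    hinges = np.clip(tau[:, None] - changepoints[None, :], 0.0, None)
    trend_block = np.column_stack([np.ones_like(tau), tau, hinges])
    weekly_block = _fourier(t, WEEKLY_PERIOD, config.weekly_order)
    yearly_block = _fourier(t, YEARLY_PERIOD, config.yearly_order)
    design = np.column_stack([trend_block, weekly_block, yearly_block])

    penalty = np.full(design.shape[1], config.ridge)
    penalty[:2] = 0.0  # intercept and base slope are unpenalised
    gram = design.T @ design + np.diag(penalty)
    coef = np.linalg.solve(gram, design.T @ values)

    n_trend = trend_block.shape[1]
    n_weekly = weekly_block.shape[1]
    return DecompositionModel(
        start=start,
        n_fit=n_fit,
        changepoints=changepoints,
        trend_coef=coef[:n_trend],
        weekly_coef=coef[n_trend : n_trend + n_weekly],
        yearly_coef=coef[n_trend + n_weekly :],
        config=config,
    )


def fit_decomposition(
    series: pd.Series,
    config: DecompositionConfig | None = None,
    fit_mask: np.ndarray | None = None,
) -> DecompositionModel:
    """Fit the additive decomposition to a gapless daily count series.

    ``fit_mask`` (boolean, aligned with the series) restricts the rows used
    in estimation while keeping the full calendar as the time reference —
    used by leakage-safe evaluation modes that must not see held-out days.
    """
    config = config or DecompositionConfig()
    if len(series) < 2 * int(WEEKLY_PERIOD):
        raise ValueError(
            f"series has {len(series)} days; need at least {2 * int(WEEKLY_PERIOD)}"
        )
    index = pd.DatetimeIndex(series.index)
    if not (index.to_series().diff().dropna() == pd.Timedelta(days=1)).all():
        raise ValueError("series must be daily with no missing days (zero-fill gaps upstream)")

    values = series.to_numpy(dtype=float)
    t = np.arange(len(series), dtype=float)
    if fit_mask is not None:
        fit_mask = np.asarray(fit_mask, dtype=bool)
        if fit_mask.shape[0] != len(series):
            raise ValueError("fit_mask must align with the series")
        if fit_mask.sum() < 2 * int(WEEKLY_PERIOD):
            raise ValueError("fit_mask keeps too few days to fit the decomposition")
        values, t_fit = values[fit_mask], t[fit_mask]
    else:
        t_fit = t
    return _fit_penalized(values, t_fit, len(series), config, index[0])


def extract_temporal_features(
    model: DecompositionModel,
    calendar: pd.DatetimeIndex | None = None,
) -> pd.DataFrame:
    """The five temporal predictor columns evaluated on ``calendar``."""
    if calendar is None:
        calendar = model.fit_calendar
    return model.components(pd.DatetimeIndex(calendar))


def forecast_baseline(model: DecompositionModel, horizon: int) -> pd.Series:
    """Extrapolated yhat for the ``horizon`` days after the fit window."""
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    if horizon == 0:
        return pd.Series(
            np.empty(0), index=pd.DatetimeIndex([], name="date"), name="yhat"
        )
    future = pd.date_range(
        model.start + pd.Timedelta(days=model.n_fit),
        periods=horizon,
        freq="D",
        name="date",
    )
    return model.components(future)["yhat"]


@dataclass(frozen=True)
class LeadLagTable:
    """Pearson correlation by candidate lag, plus the argmax-|r| lag."""

    table: pd.DataFrame
    best_lag: int


def lead_lag_correlation(
    primary: pd.Series,
    secondary: pd.Series,
    lags: Iterable[int] = (0, 1, 3, 5, 7, 9, 11, 13, 14),
    use_trend: bool = False,
    config: DecompositionConfig | None = None,
) -> LeadLagTable:
    """Correlate the secondary series against the primary at each lag.

    For lag L the pairing is secondary[t] vs primary[t - L]: L counts the
    days by which the secondary platform trails the primary community.  With
    ``use_trend`` both series are first reduced to their fitted trend
    components.  Pearson r is invariant to affine rescaling of either
    series.
    """
    if use_trend:
        primary = fit_decomposition(primary, config).components(
            pd.DatetimeIndex(primary.index)
        )["trend"]
        secondary = fit_decomposition(secondary, config).components(
            pd.DatetimeIndex(secondary.index)
        )["trend"]
    aligned = pd.concat(
        {"primary": primary, "secondary": secondary}, axis=1, join="inner"
    )
    rows = []
    for lag in lags:
        lag = int(lag)
        shifted = aligned["primary"].shift(lag)
        pair = pd.concat([aligned["secondary"], shifted], axis=1).dropna()
        n = len(pair)
        if n <= 2:
            raise ValueError(f"insufficient overlap ({n} days) at lag {lag}")
        x = pair.iloc[:, 0].to_numpy(dtype=float)
        y = pair.iloc[:, 1].to_numpy(dtype=float)
        r, p = stats.pearsonr(x, y)
        rows.append({"lag": lag, "r": float(r), "p": float(p), "n": n})
    table = pd.DataFrame(rows)
    best = table.loc[table["r"].abs().idxmax(), "lag"]
    return LeadLagTable(table=table, best_lag=int(best))
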