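"""Synthetic study-condition generator.

Builds the three coupled data objects the demand-modelling pipeline consumes:

* an epidemic case table (cumulative/new confirmed cases and deaths) whose
  cumulative confirmed counts follow a rounded logistic curve,
* daily help-seeking post counts for two platforms — a primary Q&A community
  (the forecasting target) and a secondary counselling platform that trails
  the primary one by a configurable number of days (13 by default), and
* a post corpus with planted topic structure: each post draws a topic from a
  multinomial, and its tokens mostly from that topic's seed/satellite words
  with a background-vocabulary admixture.

Everything is deterministic under the mandatory seeds, and the ground truth
(model parameters, per-post topic labels, latent intensity) is returned so
downstream recovery tests can score themselves against it.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SEED",
    "DEFAULT_START",
    "DemandModelParams",
    "TopicSpec",
    "PostRecord",
    "SyntheticDemand",
    "generate_epidemic_series",
    "generate_ophs_series",
    "generate_post_corpus",
    "default_topic_specs",
    "default_background_vocab",
    "write_fixture_bundle",
    "read_posts_jsonl",
    "read_daily_csv",
    "read_epidemic_csv",
    "validate_epidemic",
]

#: Documented default seed: the first day of the secondary platform's window.
DEFAULT_SEED = 20200131
DEFAULT_START = "2020-01-31"

EPIDEMIC_COLUMNS = ("cum_confirmed", "cum_deaths", "new_confirmed", "new_deaths")


def _calendar(n_days: int, start: str) -> pd.DatetimeIndex:
    return pd.date_range(start, periods=n_days, freq="D", name="date")


def validate_epidemic(frame: pd.DataFrame) -> None:
    """Raise ``ValueError`` if the epidemic-table invariants are violated."""
    missing = [c for c in EPIDEMIC_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"epidemic table missing columns: {missing}")
    for stem in ("confirmed", "deaths"):
        cum = frame[f"cum_{stem}"].to_numpy()
        new = frame[f"new_{stem}"].to_numpy()
        if np.any(np.diff(cum) < 0):
            raise ValueError(f"cum_{stem} is not non-decreasing")
        if np.any(new < 0):
            raise ValueError(f"new_{stem} has negative entries")
        expected = np.diff(cum, prepend=0)
        if not np.array_equal(new, expected):
            raise ValueError(f"new_{stem} != diff(cum_{stem})")


def generate_epidemic_series(
    n_days: int,
    logistic_params: tuple[float, float, float] = (80_000.0, 40.0, 0.12),
    death_fraction: float = 0.04,
    seed: int = DEFAULT_SEED,
    noise_rate: float = 5.0,
    death_lag_days: int = 7,
    start: str = DEFAULT_START,
) -> pd.DataFrame:
    """Generate an epidemic case table with logistic cumulative counts.

    Parameters
    ----------
    n_days : int
        Length of the daily calendar (>= 2).
    logistic_params : (capacity, midpoint_day, rate)
        Cumulative confirmed cases follow
        ``round(capacity / (1 + exp(-rate * (t - midpoint))))``.
    death_fraction : float
        Cumulative deaths are ``round(death_fraction * cum_confirmed)``
        evaluated ``death_lag_days`` earlier (deaths trail confirmations);
        must lie strictly between 0 and 1.
    noise_rate : float
        Mean of the non-negative integer (Poisson) noise added to the daily
        confirmed increments; 0 disables noise and makes the cumulative curve
        the exact rounded logistic.

    Returns
    -------
    pandas.DataFrame
        Date-indexed table with columns ``cum_confirmed``, ``cum_deaths``,
        ``new_confirmed``, ``new_deaths`` satisfying the cumulative/new
        difference identities.
    """
    capacity, midpoint, rate = (float(x) for x in logistic_params)
    if n_days < 2:
        raise ValueError(f"n_days must be >= 2, got {n_days}")
    if capacity <= 0:
        raise ValueError(f"carrying capacity must be positive, got {capacity}")
    if not 0.0 < death_fraction < 1.0:
        raise ValueError(f"death_fraction must be in (0, 1), got {death_fraction}")

    t = np.arange(n_days, dtype=float)
    logistic = capacity / (1.0 + np.exp(-rate * (t - midpoint)))
    cum_confirmed = np.round(logistic).astype(np.int64)

    if noise_rate > 0:
        rng = np.random.default_rng(seed)
        # Noise enters as extra non-negative daily increments so the
        # cumulative series stays monotone by construction.
        cum_confirmed = cum_confirmed + np.cumsum(
            rng.poisson(noise_rate, size=n_days)
        ).astype(np.int64)

    if death_lag_days < 0:
        raise ValueError("death_lag_days must be >= 0")
    lagged = cum_confirmed[np.clip(np.arange(n_days) - death_lag_days, 0, None)]
    cum_deaths = np.round(death_fraction * lagged).astype(np.int64)
    frame = pd.DataFrame(
        {
            "cum_confirmed": cum_confirmed,
            "cum_deaths": cum_deaths,
            "new_confirmed": np.diff(cum_confirmed, prepend=0),
            "new_deaths": np.diff(cum_deaths, prepend=0),
        },
        index=_calendar(n_days, start),
    )
    validate_epidemic(frame)
    return frame


@dataclass(frozen=True)
class DemandModelParams:
    """Parameters of the latent daily help-seeking intensity.

    intensity(t) = baseline + trend_slope * t
                 + sum_h weekly_amplitudes[h] * sin(2*pi*(h+1)*t/7)
                 + sum_h yearly_amplitudes[h] * sin(2*pi*(h+1)*t/365.25)
                 + sum_c beta_c * covariate_c(t) / max_t covariate_c
                 + drift(t)

    where drift is a slowly mixing AR(1) level process,
    ``drift(t) = level_drift_phi * drift(t-1) + innovation``, with marginal
    standard deviation ``level_drift_sd``.  The drift emulates the
    multi-week level shifts (news cycles, policy events) that real demand
    series show on top of deterministic seasonality; it is what makes
    forecasts genuinely degrade as the horizon grows.  Set
    ``level_drift_sd = 0`` for a fully deterministic intensity.

    Primary counts are ``round(max(0, intensity + Gaussian noise))`` (or
    Poisson(intensity) with ``noise_model="poisson"``); the secondary platform
    is a noisy rescaled copy of the primary counts ``platform_lead_days``
    earlier.  The default effect sizes put the epidemic signal on the
    cumulative counts only: the generated public responds to how large the
    outbreak has become, not to single-day case increments.
    """

    baseline_intensity: float = 30.0
    trend_slope: float = 0.004
    weekly_amplitudes: tuple[float, ...] = (2.5, 1.0)
    yearly_amplitudes: tuple[float, ...] = (4.0,)
    beta_cum_confirmed: float = 12.0
    beta_cum_deaths: float = 8.0
    beta_new_confirmed: float = 0.0
    beta_new_deaths: float = 0.0
    noise_sd: float = 3.0
    noise_model: str = "gaussian"
    level_drift_sd: float = 4.0
    level_drift_phi: float = 0.97
    platform_lead_days: int = 13
    secondary_scale: float = 0.6
    secondary_noise_sd: float = 2.0
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")
        if self.platform_lead_days < 0:
            raise ValueError("platform_lead_days must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if not 0.0 <= self.level_drift_phi < 1.0:
            raise ValueError("level_drift_phi must be in [0, 1)")
        if self.level_drift_sd < 0:
            raise ValueError("level_drift_sd must be >= 0")

    @property
    def betas(self) -> dict[str, float]:
        return {
            "cum_confirmed": self.beta_cum_confirmed,
            "cum_deaths": self.beta_cum_deaths,
            "new_confirmed": self.beta_new_confirmed,
            "new_deaths": self.beta_new_deaths,
        }


@dataclass(frozen=True)
class SyntheticDemand:
    """Generated demand series plus the latent ground truth behind them."""

    primary: pd.Series
    secondary: pd.Series
    intensity: pd.Series
    params: DemandModelParams


def _seasonal(t: np.ndarray, amplitudes: Sequence[float], period: float) -> np.ndarray:
    out = np.zeros_like(t, dtype=float)
    for h, amp in enumerate(amplitudes, start=1):
        out += amp * np.sin(2.0 * np.pi * h * t / period)
    return out


def generate_ophs_series(
    n_days: int,
    epidemic: pd.DataFrame,
    params: DemandModelParams | None = None,
) -> SyntheticDemand:
    """Generate coupled daily help-seeking counts for two platforms.

    The primary platform's counts are a rounded, floored-at-zero noisy
    realisation of the latent intensity; the secondary platform's counts are
    a noisy rescaled copy of the primary counts ``platform_lead_days``
    earlier (the primary community therefore *leads* the secondary platform).
    """
    params = params or DemandModelParams()
    if len(epidemic) != n_days:
        raise ValueError(
            f"epidemic table covers {len(epidemic)} days, expected {n_days}"
        )
    validate_epidemic(epidemic)

    t = np.arange(n_days, dtype=float)
    intensity = (
        params.baseline_intensity
        + params.trend_slope * t
        + _seasonal(t, params.weekly_amplitudes, 7.0)
        + _seasonal(t, params.yearly_amplitudes, 365.25)
    )
    for column, beta in params.betas.items():
        if beta == 0.0:
            continue
        values = epidemic[column].to_numpy(dtype=float)
        top = values.max()
        if top > 0:
            intensity = intensity + beta * values / top

    rng = np.random.default_rng(params.seed)
    if params.level_drift_sd > 0:
        phi = params.level_drift_phi
        innovations = rng.normal(
            0.0, params.level_drift_sd * np.sqrt(1.0 - phi**2), size=n_days
        )
        drift = np.empty(n_days)
        drift[0] = rng.normal(0.0, params.level_drift_sd)
        for i in range(1, n_days):
            drift[i] = phi * drift[i - 1] + innovations[i]
        intensity = intensity + drift

    if params.noise_model == "poisson":
        primary = rng.poisson(np.clip(intensity, 0.0, None)).astype(np.int64)
    else:
        noisy = intensity + (
            rng.normal(0.0, params.noise_sd, size=n_days)
            if params.noise_sd > 0
            else 0.0
        )
        primary = np.round(np.clip(noisy, 0.0, None)).astype(np.int64)

    lead = params.platform_lead_days
    shifted = primary[np.clip(np.arange(n_days) - lead, 0, None)]
    sec = params.secondary_scale * shifted.astype(float)
    if params.secondary_noise_sd > 0:
        sec = sec + rng.normal(0.0, params.secondary_noise_sd, size=n_days)
    secondary = np.round(np.clip(sec, 0.0, None)).astype(np.int64)

    index = epidemic.index
    return SyntheticDemand(
        primary=pd.Series(primary, index=index, name="count"),
        secondary=pd.Series(secondary, index=index, name="count"),
        intensity=pd.Series(intensity, index=index, name="intensity"),
        params=params,
    )


# ---------------------------------------------------------------------------
# Post corpus with planted topics
# ---------------------------------------------------------------------------

#: Word families used for the shared background vocabulary.  The stems mirror
#: common dictionary-category names so the category-dictionary features have
#: matching tokens to count.
BACKGROUND_FAMILIES = (
    "swear", "leisure", "achieve", "body", "ingest", "shehe", "futurem",
    "number", "see", "hear", "friend", "home", "motion", "certain",
    "inhibition", "exclusive", "humans", "deathconcern", "tense", "filler",
)

PROBLEM_TOPICS = (
    ("depression_anxiety", 0.22),
    ("suffering", 0.16),
    ("social_phobia", 0.14),
    ("lack_of_interest", 0.12),
    ("suicidal_tendency", 0.12),
    ("worry", 0.14),
    ("anger", 0.10),
)

FACTOR_TOPICS = (
    ("love", 0.20),
    ("marriage", 0.15),
    ("psychotherapy", 0.13),
    ("work", 0.16),
    ("interpersonal", 0.13),
    ("personality", 0.11),
    ("family", 0.12),
)


def default_background_vocab(words_per_family: int = 5) -> tuple[str, ...]:
    """The shared off-topic vocabulary (ASCII tokens, family-stemmed)."""
    return tuple(
        f"{family}_bg_{i}"
        for family in BACKGROUND_FAMILIES
        for i in range(words_per_family)
    )


@dataclass(frozen=True)
class TopicSpec:
    """A planted topic: seed words, satellite near-synonyms, and its weight."""

    name: str
    seed_words: tuple[str, ...]
    satellite_words: tuple[str, ...]
    background_vocab: tuple[str, ...]
    mixing_weight: float

    def __post_init__(self) -> None:
        topical = set(self.seed_words) | set(self.satellite_words)
        if topical & set(self.background_vocab):
            raise ValueError(
                f"topic {self.name!r}: seed/satellite words overlap background vocab"
            )

    @property
    def topical_words(self) -> tuple[str, ...]:
        return self.seed_words + self.satellite_words


def default_topic_specs(
    kind: str = "problems",
    n_seeds: int = 4,
    n_satellites: int = 8,
) -> list[TopicSpec]:
    """Build the default planted topics ('problems' or 'factors' family)."""
    if kind == "problems":
        names = PROBLEM_TOPICS
    elif kind == "factors":
        names = FACTOR_TOPICS
    else:
        raise ValueError(f"unknown topic family {kind!r}")
    background = default_background_vocab()
    return [
        TopicSpec(
            name=name,
            seed_words=tuple(f"{name}_core_{i}" for i in range(n_seeds)),
            satellite_words=tuple(f"{name}_sat_{i}" for i in range(n_satellites)),
            background_vocab=background,
            mixing_weight=weight,
        )
        for name, weight in names
    ]


@dataclass(frozen=True)
class PostRecord:
    """One help-seeking post: date, whitespace-joined text, optional truth."""

    date: _dt.date
    text: str
    true_topic: str | None = None
    true_companion: str | None = None

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("post text must be non-empty")


def generate_post_corpus(
    daily_counts: pd.Series,
    topics: Sequence[TopicSpec],
    words_per_post: tuple[int, int] = (6, 14),
    seed: int = DEFAULT_SEED,
    topic_token_prob: float = 0.75,
    companion_topics: Sequence[TopicSpec] | None = None,
    companion_token_prob: float = 0.30,
) -> list[PostRecord]:
    """Generate ``daily_counts[t]`` posts on day t with planted topic words.

    Each post draws a topic from the mixing weights; tokens come from the
    topic's seed/satellite pool with probability ``topic_token_prob`` and the
    shared background vocabulary otherwise.  When ``companion_topics`` is
    given (e.g. influential-factor topics alongside problem topics), every
    post additionally draws a companion topic and mixes its words in, so one
    corpus carries both semantic families the way real help-seeking posts do.
    """
    if len(topics) == 0:
        raise ValueError("topic list must be non-empty")
    lo, hi = words_per_post
    if lo < 3:
        raise ValueError(f"minimum words per post must be >= 3, got {lo}")
    if hi < lo:
        raise ValueError("words_per_post must satisfy min <= max")
    weights = np.array([spec.mixing_weight for spec in topics], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"topic mixing weights sum to {weights.sum()}, not 1")
    comp_weights = None
    if companion_topics is not None:
        comp_weights = np.array(
            [spec.mixing_weight for spec in companion_topics], dtype=float
        )
        if abs(comp_weights.sum() - 1.0) > 1e-9:
            raise ValueError("companion mixing weights must sum to 1")

    rng = np.random.default_rng(seed)
    background = topics[0].background_vocab
    posts: list[PostRecord] = []
    for date, count in daily_counts.items():
        day = date.date() if hasattr(date, "date") else date
        for _ in range(int(count)):
            spec = topics[rng.choice(len(topics), p=weights)]
            companion = None
            if companion_topics is not None:
                companion = companion_topics[
                    rng.choice(len(companion_topics), p=comp_weights)
                ]
            n_tokens = int(rng.integers(lo, hi + 1))
            tokens: list[str] = []
            for _ in range(n_tokens):
                u = rng.random()
                if u < topic_token_prob:
                    pool = spec.topical_words
                elif companion is not None and u < topic_token_prob + companion_token_prob:
                    pool = companion.topical_words
                else:
                    pool = background
                tokens.append(pool[rng.integers(len(pool))])
            posts.append(
                PostRecord(
                    date=day,
                    text=" ".join(tokens),
                    true_topic=spec.name,
                    true_companion=None if companion is None else companion.name,
                )
            )
    return posts


# ---------------------------------------------------------------------------
# Fixture bundle I/O
# ---------------------------------------------------------------------------


def write_fixture_bundle(
    out_dir: str | Path,
    epidemic: pd.DataFrame,
    demand: SyntheticDemand,
    posts: Sequence[PostRecord],
    extra_truth: dict | None = None,
) -> dict:
    """Write the generated artifacts as a plain-text bundle; return the manifest.

    Files: ``posts.jsonl``, ``epidemic.csv``, ``counts_primary.csv``,
    ``counts_secondary.csv``, ``truth.json``, ``manifest.json``.  The bundle
    round-trips losslessly through :func:`read_posts_jsonl` /
    :func:`read_daily_csv` / :func:`read_epidemic_csv` and is byte-identical
    under a fixed seed.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "posts.jsonl", "w", encoding="utf-8") as fh:
            for post in posts:
                record = {"date": post.date.isoformat(), "text": post.text}
                if post.true_topic is not None:
                    record["true_topic"] = post.true_topic
                if post.true_companion is not None:
                    record["true_companion"] = post.true_companion
                fh.write(json.dumps(record, sort_keys=True) + "\n")

        epidemic.to_csv(out / "epidemic.csv", date_format="%Y-%m-%d")
        demand.primary.to_frame().to_csv(
            out / "counts_primary.csv", date_format="%Y-%m-%d"
        )
        demand.secondary.to_frame().to_csv(
            out / "counts_secondary.csv", date_format="%Y-%m-%d"
        )

        truth = {
            "params": asdict(demand.params),
            "intensity": [round(v, 10) for v in demand.intensity.tolist()],
            "true_topics": [p.true_topic for p in posts],
        }
        if extra_truth:
            truth.update(extra_truth)
        (out / "truth.json").write_text(
            json.dumps(truth, sort_keys=True, indent=1), encoding="utf-8"
        )

        manifest = {
            "files": [
                "posts.jsonl",
                "epidemic.csv",
                "counts_primary.csv",
                "counts_secondary.csv",
                "truth.json",
            ],
            "n_days": int(len(demand.primary)),
            "n_posts": int(len(posts)),
            "seeds": {"demand": demand.params.seed},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=1), encoding="utf-8"
        )
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"failed writing fixture bundle under {out}: {exc}") from exc
    return manifest


def read_posts_jsonl(path: str | Path) -> list[PostRecord]:
    posts = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            record = json.loads(line)
            posts.append(
                PostRecord(
                    date=_dt.date.fromisoformat(record["date"]),
                    text=record["text"],
                    true_topic=record.get("true_topic"),
                    true_companion=record.get("true_companion"),
                )
            )
    return posts


def _restore_freq(frame: pd.DataFrame) -> pd.DataFrame:
    try:
        frame.index.freq = frame.index.inferred_freq
    except ValueError:  # gaps: leave the index as-is
        pass
    return frame


def read_daily_csv(path: str | Path) -> pd.Series:
    frame = _restore_freq(pd.read_csv(path, parse_dates=["date"], index_col="date"))
    return frame.iloc[:, 0]


def read_epidemic_csv(path: str | Path) -> pd.DataFrame:
    frame = _restore_freq(pd.read_csv(path, parse_dates=["date"], index_col="date"))
    validate_epidemic(frame)
    return frame
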