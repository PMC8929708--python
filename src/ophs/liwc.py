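"""Dictionary-category linguistic features (a LIWC-style stand-in).

A category dictionary maps category names (NegEmo, Anx, Body, ...) to word
lists; a terminal ``*`` makes an entry a prefix pattern, and a word may
belong to several categories.  The daily feature for a category is the
proportion of that day's pooled tokens matching the category, in [0, 1]
(days with no tokens score 0 everywhere).  The licensed LIWC lexicon itself
is out of scope; the bundled default dictionary targets the synthetic
vocabulary with category names mirroring common LIWC dimensions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import pandas as pd

from .synthetic import PostRecord

__all__ = [
    "CategoryDictionary",
    "load_category_dictionary",
    "save_category_dictionary",
    "default_category_dictionary",
    "daily_category_features",
]


@dataclass(frozen=True)
class CategoryDictionary:
    """Validated category -> word-list mapping with terminal-wildcard support."""

    categories: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for name, words in self.categories.items():
            if not words:
                raise ValueError(f"category {name!r} has an empty word list")
            for word in words:
                stem = word.rstrip("*")
                if "*" in stem:
                    raise ValueError(
                        f"category {name!r}: wildcard must be terminal in {word!r}"
                    )
                if not stem:
                    raise ValueError(f"category {name!r}: bare wildcard not allowed")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.categories)

    def matchers(self) -> dict[str, tuple[frozenset, tuple[str, ...]]]:
        """Per category: (exact-word set, prefix tuple)."""
        compiled = {}
        for name, words in self.categories.items():
            exact = frozenset(w for w in words if not w.endswith("*"))
            prefixes = tuple(w[:-1] for w in words if w.endswith("*"))
            compiled[name] = (exact, prefixes)
        return compiled

    def matches(self, token: str, category: str) -> bool:
        exact, prefixes = self.matchers()[category]
        return token in exact or any(token.startswith(p) for p in prefixes)


def _reject_duplicates(pairs):
    seen = set()
    for key, _ in pairs:
        if key in seen:
            raise ValueError(f"duplicate category name {key!r}")
        seen.add(key)
    return dict(pairs)


def load_category_dictionary(path: str | Path) -> CategoryDictionary:
    """Load a JSON ``{"Category": ["word", "stem*"]}`` dictionary file."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        raw = json.loads(text, object_pairs_hook=_reject_duplicates)
    except (json.JSONDecodeError, ValueError) as exc:
        raise ValueError(f"malformed category dictionary {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ValueError(f"category dictionary {path} must be a JSON object")
    return CategoryDictionary(
        categories={name: tuple(words) for name, words in raw.items()}
    )


def save_category_dictionary(dictionary: CategoryDictionary, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(
            {name: list(words) for name, words in dictionary.categories.items()},
            sort_keys=True,
            indent=1,
        ),
        encoding="utf-8",
    )


def default_category_dictionary() -> CategoryDictionary:
    """A ~20-category stand-in dictionary keyed to the synthetic vocabulary.

    Category names mirror familiar LIWC dimensions so downstream
    interpretation tables are comparable in kind with dictionary-based
    linguistic analyses; word lists are prefix patterns over the generator's
    ASCII token families.
    """
    return CategoryDictionary(
        categories={
            "NegEmo": ("depression_anxiety*", "suffering*", "anger*", "worry*"),
            "Anx": ("worry*", "depression_anxiety*"),
            "Sad": ("suffering*", "lack_of_interest*"),
            "Swear": ("swear*",),
            "Leisure": ("leisure*",),
            "Achieve": ("achieve*",),
            "Body": ("body*",),
            "Bio": ("body*", "ingest*"),
            "Ingest": ("ingest*",),
            "SheHe": ("shehe*",),
            "FutureM": ("futurem*",),
            "Number": ("number*",),
            "See": ("see*",),
            "Hear": ("hear*",),
            "Friend": ("friend*", "interpersonal*"),
            "Home": ("home*", "family*"),
            "Motion": ("motion*",),
            "Certain": ("certain*",),
            "Inhibition": ("inhibition*",),
            "Exclusive": ("exclusive*",),
            "Humans": ("humans*",),
            "Death": ("deathconcern*", "suicidal_tendency*"),
            "Love": ("love*",),
            "Work": ("work*",),
        }
    )


def daily_category_features(
    posts: Sequence[PostRecord],
    dictionary: CategoryDictionary,
    calendar: pd.DatetimeIndex,
    tokenizer: Callable[[str], list[str]] | None = None,
    per_post_average: bool = False,
) -> pd.DataFrame:
    """Daily token proportion per dictionary category, in [0, 1].

    By default all tokens posted on a day are pooled before counting
    (token-weighted, robust to very short posts); ``per_post_average``
    averages each post's own proportion instead.  Days with no tokens score
    0 for every category.
    """
    split = tokenizer or str.split
    cal_days = set(calendar.date)
    for post in posts:
        if post.date not in cal_days:
            raise ValueError(f"post dated {post.date} outside the calendar")

    compiled = dictionary.matchers()
    names = dictionary.names

    def proportions(tokens: list[str]) -> dict[str, float]:
        total = len(tokens)
        if total == 0:
            return {name: 0.0 for name in names}
        out = {}
        for name in names:
            exact, prefixes = compiled[name]
            hits = sum(
                1
                for tok in tokens
                if tok in exact or any(tok.startswith(p) for p in prefixes)
            )
            out[name] = hits / total
        return out

    frame = pd.DataFrame(0.0, index=calendar, columns=list(names))
    if per_post_average:
        sums: dict = {}
        counts: dict = {}
        for post in posts:
            p = proportions(split(post.text))
            day = pd.Timestamp(post.date)
            if day not in sums:
                sums[day] = {name: 0.0 for name in names}
                counts[day] = 0
            for name in names:
                sums[day][name] += p[name]
            counts[day] += 1
        for day, total in counts.items():
            for name in names:
                frame.loc[day, name] = sums[day][name] / total
    else:
        pooled: dict = {}
        for post in posts:
            pooled.setdefault(pd.Timestamp(post.date), []).extend(split(post.text))
        for day, tokens in pooled.items():
            for name, value in proportions(tokens).items():
                frame.loc[day, name] = value
    return frame
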