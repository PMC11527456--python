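"""Standard ratings and the geometry of the rating space.

Each participant rates every adjective twice on a 0-100 visual-analog
scale: once for how well it describes themself (*self rating*) and once for
how well it describes a well-known other (*other rating*).  These ratings
are the ground-truth standard for the subsequent two-alternative judgments.

The pair (self, other) places each word in the [0,100]^2 *rating space*.
The signed *evidence* a word carries is

    e = self_rating - other_rating  in [-100, 100],

positive favouring the "self" response.  The major (anti-)diagonal of the
rating space, self + other = 100, traverses every value of e; all adaptive
stimulus control happens along it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .lexicon import Lexicon

RATINGS_COLUMNS = ["word", "self_rating", "other_rating"]


def evidence(self_rating: float, other_rating: float) -> float:
    """Signed evidence e = self_rating - other_rating; both ratings in [0, 100]."""
    s = np.asarray(self_rating, dtype=float)
    o = np.asarray(other_rating, dtype=float)
    if np.any((s < 0) | (s > 100) | (o < 0) | (o > 100)):
        raise ValidationError("ratings must lie in [0, 100]")
    out = s - o
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DiagonalPoint:
    """A point on the major diagonal, addressed by its evidence value."""

    position: float
    self_coord: float
    other_coord: float


def diagonal_point(position: float) -> DiagonalPoint:
    """Map an evidence value onto the major diagonal of the rating space.

    Solves self + other = 100 and self - other = position, giving
    self = (100 + position) / 2 and other = (100 - position) / 2.
    """
    if not -100 <= position <= 100:
        raise ValidationError(f"diagonal position {position} outside [-100, 100]")
    return DiagonalPoint(
        position=float(position),
        self_coord=(100.0 + position) / 2.0,
        other_coord=(100.0 - position) / 2.0,
    )


class StandardRatings:
    """Per-word (self, other) ratings aligned with a :class:`Lexicon`."""

    def __init__(self, words, self_ratings, other_ratings):
        self.words = list(words)
        self.self_ratings = np.asarray(self_ratings, dtype=float)
        self.other_ratings = np.asarray(other_ratings, dtype=float)
        if not (len(self.words) == len(self.self_ratings) == len(self.other_ratings)):
            raise ValidationError("ratings arrays must match the word list in length")
        if np.any((self.self_ratings < 0) | (self.self_ratings > 100)) or np.any(
            (self.other_ratings < 0) | (self.other_ratings > 100)
        ):
            raise ValidationError("ratings must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.words)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, StandardRatings)
            and self.words == other.words
            and np.allclose(self.self_ratings, other.self_ratings)
            and np.allclose(self.other_ratings, other.other_ratings)
        )

    @property
    def e(self) -> np.ndarray:
        """Evidence e = self - other for every word."""
        return self.self_ratings - self.other_ratings

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "word": self.words,
                "self_rating": self.self_ratings,
                "other_rating": self.other_ratings,
            }
        )


def read_ratings(path, lexicon: Lexicon, sep: str = "\t") -> StandardRatings:
    """Read a ratings file and align it with ``lexicon`` (one row per word)."""
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing_cols = [c for c in RATINGS_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"ratings table missing column(s): {missing_cols}")
    by_word = df.set_index("word")
    missing = [w for w in lexicon.words if w not in by_word.index]
    extra = [w for w in by_word.index if w not in set(lexicon.words)]
    if missing or extra:
        raise ValidationError(
            f"ratings/lexicon word mismatch; missing from ratings: {missing}, "
            f"not in lexicon: {extra}"
        )
    aligned = by_word.loc[lexicon.words]
    return StandardRatings(
        lexicon.words,
        aligned["self_rating"].to_numpy(),
        aligned["other_rating"].to_numpy(),
    )


def write_ratings(ratings: StandardRatings, path, sep: str = "\t") -> None:
    # VAS values carry two decimals in the file format
    ratings.to_frame().to_csv(path, sep=sep, index=False, float_format="%.2f")
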