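"""Adjective lexica: reading, validation, filtering, synthesis, display timing.

A lexicon is the pool of personality-describing adjectives a trait-judgment
session draws its stimuli from.  Each entry carries the surface properties
used for stimulus filtering (valence, corpus frequency, length) and for
predicting how long a word must stay on screen to be read (letters,
syllables, frequency).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

LEXICON_COLUMNS = ["word", "n_letters", "n_syllables", "log10_freq", "valence"]


@dataclass(frozen=True)
class Adjective:
    """A single adjective with the surface properties used downstream.

    Parameters
    ----------
    word : str
        The adjective itself; unique within a lexicon.
    n_letters : int
        Orthographic length, >= 1.
    n_syllables : int
        Syllable count, >= 1.
    log10_freq : float
        log10 corpus frequency (larger = more common).
    valence : float
        Signed valence rating; strongly valenced words are filtered out
        before an experiment because they invite stereotyped judgments.
    """

    word: str
    n_letters: int
    n_syllables: int
    log10_freq: float
    valence: float

    def __post_init__(self) -> None:
        if not self.word:
            raise ValidationError("adjective word must be non-empty")
        if self.n_letters < 1:
            raise ValidationError(f"{self.word!r}: n_letters must be >= 1")
        if self.n_syllables < 1:
            raise ValidationError(f"{self.word!r}: n_syllables must be >= 1")
        if not (np.isfinite(self.log10_freq) and np.isfinite(self.valence)):
            raise ValidationError(f"{self.word!r}: non-finite surface property")


class Lexicon:
    """An ordered collection of unique :class:`Adjective` entries."""

    def __init__(self, entries: Iterable[Adjective]):
        self.entries: list[Adjective] = list(entries)
        words = [a.word for a in self.entries]
        dupes = {w for w in words if words.count(w) > 1}
        if dupes:
            raise ValidationError(f"duplicate words in lexicon: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[Adjective]:
        return iter(self.entries)

    def __getitem__(self, i: int) -> Adjective:
        return self.entries[i]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Lexicon) and self.entries == other.entries

    @property
    def words(self) -> list[str]:
        return [a.word for a in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(a) for a in self.entries], columns=LEXICON_COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Lexicon":
        missing = [c for c in LEXICON_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"lexicon table missing column(s): {missing}")
        entries = [
            Adjective(
                word=str(r.word),
                n_letters=int(r.n_letters),
                n_syllables=int(r.n_syllables),
                log10_freq=float(r.log10_freq),
                valence=float(r.valence),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(entries)


def read_lexicon(path, sep: str = "\t") -> Lexicon:
    """Read a delimited lexicon file (header row, UTF-8; TSV by default)."""
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    return Lexicon.from_frame(df)


def write_lexicon(lex: Lexicon, path, sep: str = "\t") -> None:
    lex.to_frame().to_csv(path, sep=sep, index=False)


def filter_lexicon(
    lex: Lexicon,
    max_abs_valence: float = 1.6,
    min_log10_freq: float = 0.5,
    max_letters: int = 14,
    exclusion_list: Sequence[str] = (),
) -> Lexicon:
    """Apply the stimulus-material inclusion rules.

    A word is retained iff |valence| <= ``max_abs_valence`` (drop the most
    strongly valenced items), log10 frequency is strictly above
    ``min_log10_freq`` (drop rare words), length is strictly below
    ``max_letters``, and the word is not on the explicit exclusion list.
    Original order is preserved.
    """
    for v in (max_abs_valence, min_log10_freq):
        if not np.isfinite(v):
            raise ValidationError("filter thresholds must be finite")
    excluded = set(exclusion_list)
    kept = [
        a
        for a in lex
        if abs(a.valence) <= max_abs_valence
        and a.log10_freq > min_log10_freq
        and a.n_letters < max_letters
        and a.word not in excluded
    ]
    if not kept:
        warnings.warn("filter_lexicon removed every word", stacklevel=2)
    return Lexicon(kept)


@dataclass(frozen=True)
class DisplayModelCoeffs:
    """Full-factorial linear model of lexical decision time (ms).

    Intercept plus weights for the three main effects of letters, syllables
    and log10 frequency, their three two-way interactions, and the three-way
    interaction.
    """

    intercept: float
    b_letters: float = 0.0
    b_syllables: float = 0.0
    b_freq: float = 0.0
    b_letters_syllables: float = 0.0
    b_letters_freq: float = 0.0
    b_syllables_freq: float = 0.0
    b_letters_syllables_freq: float = 0.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if not np.isfinite(getattr(self, f.name)):
                raise ValidationError(f"non-finite display-model coefficient {f.name}")

    def predict(self, n_letters: float, n_syllables: float, log10_freq: float) -> float:
        L, S, F = n_letters, n_syllables, log10_freq
        return (
            self.intercept
            + self.b_letters * L
            + self.b_syllables * S
            + self.b_freq * F
            + self.b_letters_syllables * L * S
            + self.b_letters_freq * L * F
            + self.b_syllables_freq * S * F
            + self.b_letters_syllables_freq * L * S * F
        )


def display_duration(
    adj: Adjective,
    coeffs: DisplayModelCoeffs,
    offset_ms: float = 117.0,
    floor_ms: float = 200.0,
) -> float:
    """Predicted on-screen duration: predicted lexical decision time minus
    ``offset_ms``, floored at ``floor_ms`` so arbitrary coefficients cannot
    produce unreadably short (or negative) durations."""
    ldt = coeffs.predict(adj.n_letters, adj.n_syllables, adj.log10_freq)
    return max(ldt - offset_ms, floor_ms)


def fit_display_model(adjectives: Sequence[Adjective], ldt_ms: Sequence[float]) -> DisplayModelCoeffs:
    """Ordinary least squares fit of the full-factorial decision-time model
    to a corpus of (adjective, lexical decision time) pairs."""
    L = np.array([a.n_letters for a in adjectives], dtype=float)
    S = np.array([a.n_syllables for a in adjectives], dtype=float)
    F = np.array([a.log10_freq for a in adjectives], dtype=float)
    X = np.column_stack([np.ones_like(L), L, S, F, L * S, L * F, S * F, L * S * F])
    beta, *_ = np.linalg.lstsq(X, np.asarray(ldt_ms, dtype=float), rcond=None)
    return DisplayModelCoeffs(*beta)


# Syllable inventory for pronounceable synthetic word labels.
_ONSETS = ["b", "d", "f", "g", "k", "l", "m", "n", "r", "s", "t", "v", "z", "st", "sch", "tr", "gr", "kl"]
_NUCLEI = ["a", "e", "i", "o", "u", "ei", "au", "ie"]
_CODAS = ["", "", "n", "r", "l", "s", "t", "ch"]


def _synthesize_word(rng: np.random.Generator, n_syllables: int) -> tuple[str, int]:
    parts = []
    for _ in range(n_syllables):
        parts.append(rng.choice(_ONSETS) + rng.choice(_NUCLEI) + rng.choice(_CODAS))
    word = "".join(parts)
    return word, len(word)


def generate_fixture_lexicon(
    n_words: int,
    rng_seed: int,
    cluster_spec: Sequence[tuple[float, float, float]] | None = None,
) -> Lexicon:
    """Synthesize a lexicon of pronounceable pseudo-adjectives.

    Stands in for a published trait-adjective pool.  Surface properties stay
    inside the default inclusion filters by construction (4-13 letters, 1-5
    syllables, log10 frequency > 0.5, |valence| <= 1.6), so a generated
    lexicon passes :func:`filter_lexicon` unchanged.

    ``cluster_spec`` optionally shapes the valence distribution as a mixture
    of (center, sd, weight) components, mimicking pools where mildly
    positive and mildly negative adjectives dominate; the default is uniform
    on [-1.6, 1.6].
    """
    if n_words < 8:
        raise ValidationError("fixture lexicon needs at least 8 words")
    rng = np.random.default_rng(rng_seed)
    entries: list[Adjective] = []
    seen: set[str] = set()
    while len(entries) < n_words:
        n_syl = int(rng.integers(2, 5))
        word, n_let = _synthesize_word(rng, n_syl)
        if word in seen or not (4 <= n_let <= 13):
            continue
        seen.add(word)
        freq = float(rng.uniform(0.6, 4.5))
        if cluster_spec:
            weights = np.array([w for _, _, w in cluster_spec], dtype=float)
            k = rng.choice(len(cluster_spec), p=weights / weights.sum())
            c, sd, _ = cluster_spec[k]
            val = float(np.clip(rng.normal(c, sd), -1.6, 1.6))
        else:
            val = float(rng.uniform(-1.6, 1.6))
        entries.append(Adjective(word, n_let, n_syl, freq, val))
    return Lexicon(entries)
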