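"""Simulated participants.

An observer supplies the three behaviours a session needs: standard
ratings for every word, a two-alternative choice per trial, and a 0-100
confidence report.  Choices follow a balanced-evidence rule — the sign of
the mean evidence of the four words plus Gaussian decision noise — which
is the generative counterpart of the symmetric decision weights seen in
reverse correlation.  Confidence follows one of two rules:

``balanced``
    confidence increases with the absolute balance of evidence |d|; both
    the chosen and the non-chosen dimension inform it symmetrically.
``positive_evidence``
    confidence depends only on how strongly the *chosen* dimension's
    ratings exceed their expected (staircase-centre) value — a
    decision-congruent rule that discounts non-chosen information and
    produces the positive evidence bias in confidence weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .lexicon import Lexicon
from .ratings import StandardRatings

CONFIDENCE_MODELS = ("balanced", "positive_evidence")


@dataclass
class ObserverParams:
    """Generative parameters of a simulated participant.

    choice_noise_sd : Gaussian noise on the mean-evidence decision variable
        (evidence units).  15 puts the 70%-correct point of the resulting
        psychometric curve comfortably inside the staircase's range.
    confidence_model : "balanced" or "positive_evidence".
    confidence_gain : confidence units per unit of the confidence signal.
    confidence_offset : baseline confidence on the 0-100 scale.
    confidence_noise_sd : Gaussian report noise (confidence units).
    rating_correlation : correlation of self and other ratings across
        words — the other is similar to, but different from, the self.
    rating_mean, rating_sd : marginal location and spread of the generated
        ratings before clipping to [0, 100].  The default spread of 35
        covers the whole visual-analog scale (with realistic mass at the
        endpoints), giving an evidence distribution wide enough that the
        staircases operate well inside the word cloud's support.
    rating_bias : constant added to self ratings (a biased standard);
        defaults to 0.
    """

    choice_noise_sd: float = 15.0
    confidence_model: str = "balanced"
    confidence_gain: float = 2.0
    confidence_offset: float = 50.0
    confidence_noise_sd: float = 10.0
    rating_correlation: float = 0.3
    rating_mean: float = 50.0
    rating_sd: float = 35.0
    rating_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.choice_noise_sd < 0 or self.confidence_noise_sd < 0:
            raise ValidationError("noise SDs must be >= 0")
        if not -1.0 <= self.rating_correlation <= 1.0:
            raise ValidationError("rating_correlation must lie in [-1, 1]")
        if self.confidence_model not in CONFIDENCE_MODELS:
            raise ValidationError(
                f"confidence_model must be one of {CONFIDENCE_MODELS}"
            )


def generate_standard_ratings(
    lexicon: Lexicon,
    params: ObserverParams,
    rng: np.random.Generator,
    max_attempts: int = 5,
) -> StandardRatings:
    """Draw (self, other) ratings for every word of ``lexicon``.

    Bivariate normal with the configured marginals and correlation, clipped
    to the 0-100 scale.  Regenerates (up to ``max_attempts``) if one side
    of e = 0 ends up empty, since both staircases need at least one
    favouring word.
    """
    n = len(lexicon)
    m, s, r = params.rating_mean, params.rating_sd, params.rating_correlation
    cov = s**2 * np.array([[1.0, r], [r, 1.0]])
    for attempt in range(max_attempts):
        draws = rng.multivariate_normal([m, m], cov, size=n)
        self_r = np.clip(draws[:, 0] + params.rating_bias, 0.0, 100.0)
        other_r = np.clip(draws[:, 1], 0.0, 100.0)
        e = self_r - other_r
        if np.any(e > 0) and np.any(e < 0):
            return StandardRatings(lexicon.words, self_r, other_r)
        warnings.warn(
            f"degenerate evidence spread on attempt {attempt + 1}; regenerating",
            stacklevel=2,
        )
    raise ValidationError(
        f"could not generate ratings with words on both sides of e=0 "
        f"in {max_attempts} attempts"
    )


def decision_variable(
    self_ratings: np.ndarray, other_ratings: np.ndarray
) -> float:
    """Noise-free balance of evidence: mean over words of (self - other)."""
    return float(np.mean(np.asarray(self_ratings) - np.asarray(other_ratings)))


def choose(
    self_ratings: np.ndarray,
    other_ratings: np.ndarray,
    params: ObserverParams,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Balanced-evidence choice.

    d = mean(self - other) + Gaussian noise; "self" if d > 0, "other" if
    d < 0, a fair coin exactly at 0.  Returns (choice, noisy d).
    """
    d = decision_variable(self_ratings, other_ratings)
    if params.choice_noise_sd > 0:
        d += rng.normal(0.0, params.choice_noise_sd)
    if d > 0:
        return "self", d
    if d < 0:
        return "other", d
    return ("self" if rng.random() < 0.5 else "other"), d


def report_confidence(
    self_ratings: np.ndarray,
    other_ratings: np.ndarray,
    choice: str,
    d: float,
    expected_self: float,
    expected_other: float,
    params: ObserverParams,
    rng: np.random.Generator,
) -> float:
    """Confidence on the 0-100 scale under the configured model.

    balanced: offset + gain * |d|.  positive_evidence: offset + gain *
    (mean rating on the chosen dimension, centred at that dimension's
    expected staircase value).  Gaussian report noise, then clamping.
    """
    if params.confidence_model == "balanced":
        signal = abs(d)
    else:
        if choice == "self":
            signal = float(np.mean(self_ratings)) - expected_self
        else:
            signal = float(np.mean(other_ratings)) - expected_other
    conf = params.confidence_offset + params.confidence_gain * signal
    if params.confidence_noise_sd > 0:
        conf += rng.normal(0.0, params.confidence_noise_sd)
    return float(np.clip(conf, 0.0, 100.0))
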