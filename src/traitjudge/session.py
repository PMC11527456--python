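"""Full simulated sessions: schedule, staircase updates, trial logging.

A session interleaves the self- and other-condition staircases in a seeded
random order (exactly half the trials per condition).  Each trial: read
the condition's staircase position, sample four words from the Gaussian at
that diagonal position, query the observer for a choice and a confidence
report, score the choice against the condition, and move that condition's
staircase.  Everything is deterministic given the session seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import observer as obs
from . import sampler as smp
from . import staircase as stc
from .errors import FormatError, ValidationError
from .lexicon import Lexicon
from .observer import ObserverParams
from .ratings import StandardRatings, diagonal_point
from .sampler import SamplerConfig

LOG_SCHEMA_VERSION = 1
CONDITIONS = ("self", "other")


@dataclass
class TrialRecord:
    """One logged trial of the trait judgment task."""

    participant_id: str
    trial_index: int
    condition: str
    staircase_position_before: float
    words: tuple[str, str, str, str]
    self_ratings: tuple[float, ...]
    other_ratings: tuple[float, ...]
    expected_self: float
    expected_other: float
    choice: str
    correct: bool
    confidence: float

    def __post_init__(self) -> None:
        if self.correct != (self.choice == self.condition):
            raise ValidationError("correct flag inconsistent with choice/condition")
        if len(set(self.words)) != len(self.words):
            raise ValidationError("trial words must be distinct")
        if abs(self.expected_self + self.expected_other - 100.0) > 1e-9:
            raise ValidationError("expected ratings must lie on the major diagonal")


@dataclass
class SessionConfig:
    """Parameters of one simulated session."""

    n_trials: int = 306
    words_per_trial: int = 4
    step_divisor: int = 20
    use_empirical_range: bool = False
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    calibrate: bool = True
    calibration_tolerance: float = 0.1
    calibration_max_iter: int = 20
    break_every: int = 50  # logged as metadata only; no computational effect
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials % 2 != 0:
            raise ValidationError("n_trials must be even (half per condition)")
        self.sampler.words_per_trial = self.words_per_trial


def run_session(
    lexicon: Lexicon,
    ratings: StandardRatings,
    observer_params: ObserverParams,
    config: SessionConfig,
    participant_id: str = "sim",
    rng: np.random.Generator | None = None,
) -> list[TrialRecord]:
    """Simulate a complete staircase-controlled session."""
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    # balanced, seeded-random condition schedule
    half = config.n_trials // 2
    schedule = np.array([0] * half + [1] * half)
    rng.shuffle(schedule)

    stairs = {
        c: stc.init_staircase(
            c, ratings, config.step_divisor, config.use_empirical_range
        )
        for c in CONDITIONS
    }

    density = smp.estimate_density(ratings, config.sampler.kde_bandwidth)
    start_centers = {c: diagonal_point(stairs[c].position) for c in CONDITIONS}
    start_dist = float(
        np.hypot(
            start_centers["self"].self_coord - start_centers["other"].self_coord,
            start_centers["self"].other_coord - start_centers["other"].other_coord,
        )
    )
    initial_sigma = max(config.sampler.sigma_scale * start_dist, 1e-6)
    sigmas = {c: config.sampler.sigma.get(c, initial_sigma) for c in CONDITIONS}
    if config.calibrate and not config.sampler.sigma:
        sigmas = smp.calibrate_sigma(
            ratings,
            config.sampler,
            rng,
            start_centers,
            initial_sigma,
            tolerance=config.calibration_tolerance,
            max_iter=config.calibration_max_iter,
        )

    records: list[TrialRecord] = []
    for t, cond_idx in enumerate(schedule):
        cond = CONDITIONS[cond_idx]
        state = stairs[cond]
        center = diagonal_point(state.position)
        idx = smp.sample_trial_words(
            ratings, center, config.sampler, rng, density=density, sigma=sigmas[cond]
        )
        s_r = ratings.self_ratings[idx]
        o_r = ratings.other_ratings[idx]
        choice, d = obs.choose(s_r, o_r, observer_params, rng)
        correct = choice == cond
        conf = obs.report_confidence(
            s_r,
            o_r,
            choice,
            d,
            center.self_coord,
            center.other_coord,
            observer_params,
            rng,
        )
        records.append(
            TrialRecord(
                participant_id=participant_id,
                trial_index=t,
                condition=cond,
                staircase_position_before=state.position,
                words=tuple(ratings.words[i] for i in idx),
                self_ratings=tuple(float(x) for x in s_r),
                other_ratings=tuple(float(x) for x in o_r),
                expected_self=center.self_coord,
                expected_other=center.other_coord,
                choice=choice,
                correct=correct,
                confidence=conf,
            )
        )
        stairs[cond] = stc.update(state, correct)
    return records


# ---------------------------------------------------------------------------
# trial-log I/O (CSV, one row per trial, schema-versioned)

_BASE_COLUMNS = [
    "schema_version",
    "participant_id",
    "trial_index",
    "condition",
    "staircase_position_before",
    "expected_self",
    "expected_other",
    "choice",
    "correct",
    "confidence",
]


def _word_columns(k: int) -> list[str]:
    cols = []
    for j in range(1, k + 1):
        cols += [f"word{j}", f"self{j}", f"other{j}"]
    return cols


def records_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {c: getattr(r, c) for c in _BASE_COLUMNS if c != "schema_version"}
        row["schema_version"] = LOG_SCHEMA_VERSION
        for j, (w, s, o) in enumerate(zip(r.words, r.self_ratings, r.other_ratings), 1):
            row[f"word{j}"] = w
            row[f"self{j}"] = s
            row[f"other{j}"] = o
        rows.append(row)
    k = len(records[0].words) if records else 4
    return pd.DataFrame(rows, columns=_BASE_COLUMNS + _word_columns(k))


def write_log(records: list[TrialRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def frame_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    k = sum(1 for c in df.columns if c.startswith("word"))
    expected = set(_BASE_COLUMNS) | set(_word_columns(k)) if k else set(_BASE_COLUMNS)
    missing = sorted(expected - set(df.columns))
    if missing or k == 0:
        raise FormatError(f"trial log missing column(s): {missing or ['word1']}")
    records = []
    for r in df.itertuples(index=False):
        records.append(
            TrialRecord(
                participant_id=str(r.participant_id),
                trial_index=int(r.trial_index),
                condition=str(r.condition),
                staircase_position_before=float(r.staircase_position_before),
                words=tuple(getattr(r, f"word{j}") for j in range(1, k + 1)),
                self_ratings=tuple(float(getattr(r, f"self{j}")) for j in range(1, k + 1)),
                other_ratings=tuple(float(getattr(r, f"other{j}")) for j in range(1, k + 1)),
                expected_self=float(r.expected_self),
                expected_other=float(r.expected_other),
                choice=str(r.choice),
                correct=bool(r.correct),
                confidence=float(r.confidence),
            )
        )
    return records


def read_log(path) -> list[TrialRecord]:
    return frame_to_records(pd.read_csv(path, float_precision="round_trip"))


def accuracy(records: list[TrialRecord]) -> float:
    """Fraction of trials whose choice matched the condition."""
    return float(np.mean([r.correct for r in records]))
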