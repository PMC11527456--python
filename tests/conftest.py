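"""Shared fixtures: synthetic lexica, ratings and simulated sessions.

Everything is generated programmatically with fixed seeds; the heavier
simulated batches are session-scoped so several tests can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

import traitjudge as tj


@pytest.fixture(scope="session")
def lexicon104() -> tj.Lexicon:
    return tj.generate_fixture_lexicon(104, rng_seed=1)


@pytest.fixture()
def small_lexicon() -> tj.Lexicon:
    entries = [
        tj.Adjective(f"word{i}", 5 + i % 4, 2, 1.0 + 0.1 * i, 0.1 * i - 0.4)
        for i in range(8)
    ]
    return tj.Lexicon(entries)


def make_ratings_with_e(e_values, prefix="w") -> tj.StandardRatings:
    """Ratings lying exactly on the major diagonal with the given evidence."""
    e = np.asarray(e_values, dtype=float)
    words = [f"{prefix}{i}" for i in range(e.size)]
    return tj.StandardRatings(words, (100.0 + e) / 2.0, (100.0 - e) / 2.0)


@pytest.fixture()
def diagonal_ratings() -> tj.StandardRatings:
    return make_ratings_with_e([10, 20, 30, -15, -25])


@pytest.fixture(scope="session")
def ratings104(lexicon104) -> tj.StandardRatings:
    rng = np.random.default_rng(7)
    return tj.generate_standard_ratings(lexicon104, tj.ObserverParams(), rng)


@pytest.fixture(scope="session")
def one_session(lexicon104, ratings104):
    """One 800-trial balanced-observer session, reused across analysis tests."""
    params = tj.ObserverParams()
    rng = np.random.default_rng(42)
    cfg = tj.SessionConfig(n_trials=800, rng_seed=42)
    return tj.run_session(lexicon104, ratings104, params, cfg,
                          participant_id="p0", rng=rng)


def simulate_batch(lexicon, n_observers, n_trials, confidence_model, seed0):
    """One independent observer (own ratings, own session) per seed."""
    sessions = []
    for i in range(n_observers):
        params = tj.ObserverParams(confidence_model=confidence_model)
        rng = np.random.default_rng(seed0 + i)
        ratings = tj.generate_standard_ratings(lexicon, params, rng)
        cfg = tj.SessionConfig(n_trials=n_trials)
        sessions.append(
            tj.run_session(lexicon, ratings, params, cfg,
                           participant_id=f"p{i:02d}", rng=rng)
        )
    return sessions


@pytest.fixture(scope="session")
def balanced_batch(lexicon104):
    """20 balanced-evidence observers, 2000 trials each."""
    return simulate_batch(lexicon104, 20, 2000, "balanced", 500)


@pytest.fixture(scope="session")
def positive_evidence_batch(lexicon104):
    """20 positive-evidence (decision-congruent confidence) observers."""
    return simulate_batch(lexicon104, 20, 2000, "positive_evidence", 900)


def per_participant_median_labels(records):
    pids = np.array([r.participant_id for r in records])
    confs = np.array([r.confidence for r in records])
    labels = np.empty(len(records), dtype=object)
    for pid in np.unique(pids):
        m = pids == pid
        labels[m] = tj.median_split(confs[m])
    return labels
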