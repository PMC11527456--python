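"""Reverse correlation of choices and confidence.

Each presented word deviates from the trial's expected rating (the
staircase-centre coordinates) by a random *fluctuation* on the self and
other dimension.  Normalised by their standard deviation over all trials,
and averaged conditional on the response, these fluctuations become
*decision weights*: a 2 (chosen / non-chosen dimension) x 4 (word
position) matrix per participant.  A balance-of-evidence decision rule
yields symmetric weights — positive for the chosen, mirror-negative for
the non-chosen dimension.

*Confidence weights* are the decision weights computed separately on
high- and low-confidence trials (per-participant median split), high
minus low.  An asymmetry — chosen weights positive, non-chosen near
zero — is the signature of decision-congruent, positive-evidence-biased
confidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .session import TrialRecord

CONGRUENCE = ("chosen", "nonchosen")


@dataclass
class WeightMatrix:
    """2 x 4 weights for one participant.

    ``values[0]`` is the chosen row, ``values[1]`` the non-chosen row;
    columns are word positions 1-4 (presentation order).  ``n_trials``
    holds the per-cell trial counts.
    """

    participant_id: str
    kind: str  # "decision" or "confidence"
    values: np.ndarray
    n_trials: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != 2:
            raise ValidationError("weight matrix must have a chosen and non-chosen row")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("weight matrix contains non-finite values")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, cong in enumerate(CONGRUENCE):
            for pos in range(self.values.shape[1]):
                rows.append(
                    {
                        "participant_id": self.participant_id,
                        "kind": self.kind,
                        "congruence": cong,
                        "position": pos + 1,
                        "value": self.values[ci, pos],
                        "n": int(self.n_trials[ci, pos]),
                    }
                )
        return pd.DataFrame(rows)


def fluctuations(record: TrialRecord) -> np.ndarray:
    """Per-word rating deviations from the trial's expected (centre) ratings.

    Returns a (words, 2) array; column 0 is the self dimension, column 1
    the other dimension.
    """
    if record.expected_self is None or record.expected_other is None:
        raise ValidationError("trial record lacks expected ratings")
    s = np.asarray(record.self_ratings) - record.expected_self
    o = np.asarray(record.other_ratings) - record.expected_other
    return np.column_stack([s, o])


def _weights_one_participant(
    records: list[TrialRecord], normalize: bool
) -> tuple[np.ndarray, np.ndarray]:
    k = len(records[0].words)
    fl = np.stack([fluctuations(r) for r in records])  # (trials, k, 2)
    if normalize:
        # SD per dimension, pooled over trials and word positions
        sd = fl.std(axis=(0, 1), ddof=1)
        if np.any(sd == 0):
            raise ValidationError("zero fluctuation SD; cannot normalise")
        fl = fl / sd
    chose_self = np.array([r.choice == "self" for r in records])
    # chosen dimension: self (col 0) when "self" was chosen, else other
    chosen = np.where(chose_self[:, None], fl[:, :, 0], fl[:, :, 1])
    nonchosen = np.where(chose_self[:, None], fl[:, :, 1], fl[:, :, 0])
    values = np.stack([chosen.mean(axis=0), nonchosen.mean(axis=0)])
    n = np.full((2, k), len(records))
    return values, n


def decision_weights(
    records: list[TrialRecord],
    normalize: bool = True,
    min_trials: int = 20,
) -> list[WeightMatrix]:
    """Per-participant choice-conditioned mean normalised fluctuations."""
    out = []
    for pid, recs in _by_participant(records).items():
        if len(recs) < min_trials:
            raise ValidationError(
                f"participant {pid!r}: {len(recs)} trials < min_trials={min_trials}"
            )
        values, n = _weights_one_participant(recs, normalize)
        out.append(WeightMatrix(pid, "decision", values, n))
    return out


def confidence_weights(
    records: list[TrialRecord],
    split_labels: np.ndarray,
    normalize: bool = True,
    min_trials: int = 20,
) -> list[WeightMatrix]:
    """High-confidence minus low-confidence decision weights, cell-wise.

    ``split_labels`` assigns every record to "high" or "low" (typically a
    per-participant median split of confidence).
    """
    split_labels = np.asarray(split_labels)
    if split_labels.shape[0] != len(records):
        raise ValidationError("split labels must match records in length")
    out = []
    groups = _by_participant(records)
    labels_by_pid: dict[str, list[str]] = {}
    for r, lab in zip(records, split_labels):
        labels_by_pid.setdefault(r.participant_id, []).append(str(lab))
    for pid, recs in groups.items():
        if len(recs) < min_trials:
            raise ValidationError(
                f"participant {pid!r}: {len(recs)} trials < min_trials={min_trials}"
            )
        labs = np.array(labels_by_pid[pid])
        parts = {}
        for lvl in ("high", "low"):
            sel = [r for r, l in zip(recs, labs) if l == lvl]
            if not sel:
                raise ValidationError(f"participant {pid!r}: no {lvl}-confidence trials")
            parts[lvl], _ = _weights_one_participant(sel, normalize)
        values = parts["high"] - parts["low"]
        k = values.shape[1]
        n = np.full((2, k), min(sum(labs == "high"), sum(labs == "low")))
        out.append(WeightMatrix(pid, "confidence", values, n))
    return out


def weights_to_frame(weights: list[WeightMatrix]) -> pd.DataFrame:
    return pd.concat([w.to_frame() for w in weights], ignore_index=True)


def weights_to_table(weights: list[WeightMatrix]) -> np.ndarray:
    """Stack per-participant matrices into (subjects, congruence, position)
    — the table shape the repeated-measures ANOVA consumes."""
    return np.stack([w.values for w in weights])


def _by_participant(records: list[TrialRecord]) -> dict[str, list[TrialRecord]]:
    groups: dict[str, list[TrialRecord]] = {}
    for r in records:
        groups.setdefault(r.participant_id, []).append(r)
    return groups
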