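"""Psychometric choice functions.

Per trial, *stimulus strength* is the mean rating on the trial's target
dimension (self ratings in self-condition trials, other ratings otherwise)
minus the mean rating on the non-target dimension, scaled by its
within-participant standard deviation (zero stays neutral).  The choice function models the log-odds of a correct
response as a logistic function of stimulus strength:

    logit P(correct) = intercept + slope * strength

fit per participant, per condition, and per confidence level (low / high,
from a per-participant median split of the confidence reports).  The
intercept indexes response bias at neutral stimuli (logistic(intercept) is
P(correct) at zero strength); the slope indexes sensitivity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .errors import ValidationError
from .session import TrialRecord


@dataclass
class PsychometricFit:
    participant_id: str
    condition: str  # "self", "other" or "all"
    confidence_level: str  # "low", "high" or "all"
    intercept: float
    slope: float
    n_trials: int
    converged: bool
    note: str = ""


def stimulus_strength(records: list[TrialRecord]) -> np.ndarray:
    """Per-trial stimulus strength, standardised within participant.

    Raw value: mean(target-dimension ratings) - mean(non-target ratings).
    Standardisation divides by the participant's sample SD (n-1) of the raw
    values *without* re-centering: zero strength keeps its meaning as a
    neutral stimulus, so the fitted intercept indexes the probability of a
    correct response to non-informative stimuli.  (Mean-centering would
    relocate zero to the staircase-held average difficulty, where accuracy
    is ~0.7 by design, and the intercept would no longer measure bias.)
    """
    pids = np.array([r.participant_id for r in records])
    raw = np.empty(len(records))
    for i, r in enumerate(records):
        s = np.mean(r.self_ratings)
        o = np.mean(r.other_ratings)
        raw[i] = s - o if r.condition == "self" else o - s
    out = np.empty_like(raw)
    for pid in np.unique(pids):
        m = pids == pid
        if m.sum() < 2 or np.std(raw[m], ddof=1) == 0:
            raise ValidationError(
                f"participant {pid!r}: need >= 2 trials with nonzero strength variance"
            )
        out[m] = raw[m] / np.std(raw[m], ddof=1)
    return out


def raw_stimulus_strength(record: TrialRecord) -> float:
    """Un-normalised strength of a single trial (target minus non-target mean)."""
    s = float(np.mean(record.self_ratings))
    o = float(np.mean(record.other_ratings))
    return s - o if record.condition == "self" else o - s


def fit_choice_function(
    strengths: np.ndarray,
    corrects: np.ndarray,
    participant_id: str = "",
    condition: str = "all",
    confidence_level: str = "all",
    min_trials: int = 10,
) -> PsychometricFit:
    """Maximum-likelihood logistic regression of correctness on strength."""
    strengths = np.asarray(strengths, dtype=float)
    corrects = np.asarray(corrects, dtype=float)
    n = strengths.size
    meta = dict(
        participant_id=participant_id,
        condition=condition,
        confidence_level=confidence_level,
        n_trials=n,
    )
    if n < min_trials:
        return PsychometricFit(**meta, intercept=np.nan, slope=np.nan,
                               converged=False, note="too few trials")
    if corrects.min() == corrects.max():
        return PsychometricFit(**meta, intercept=np.nan, slope=np.nan,
                               converged=False, note="single outcome class")
    X = sm.add_constant(strengths)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(corrects, X).fit(disp=0, maxiter=200)
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError):
        direction = "+" if np.corrcoef(strengths, corrects)[0, 1] > 0 else "-"
        return PsychometricFit(**meta, intercept=np.nan, slope=np.nan,
                               converged=False, note=f"separation ({direction})")
    b0, b1 = res.params
    # complete separation shows up as runaway coefficients rather than an
    # exception in some statsmodels versions
    if not res.mle_retvals.get("converged", True) or abs(b1) > 50:
        direction = "+" if b1 > 0 else "-"
        return PsychometricFit(**meta, intercept=np.nan, slope=np.nan,
                               converged=False, note=f"separation ({direction})")
    return PsychometricFit(**meta, intercept=float(b0), slope=float(b1), converged=True)


def median_split(confidences: np.ndarray) -> np.ndarray:
    """Label each trial "high" (strictly above the median confidence) or
    "low" (at or below).  Ties go to low, which is deterministic and
    conservative for the high-confidence contrast."""
    confidences = np.asarray(confidences, dtype=float)
    if confidences.size < 2:
        raise ValidationError("median split needs >= 2 trials")
    med = np.median(confidences)
    labels = np.where(confidences > med, "high", "low")
    if (labels == "low").all():
        warnings.warn("all-equal confidence: every trial labelled low", stacklevel=2)
    return labels


def fit_all_choice_functions(
    records: list[TrialRecord],
    split_by_condition: bool = True,
    split_by_confidence: bool = True,
    min_trials: int = 10,
) -> list[PsychometricFit]:
    """Per participant (x condition) (x confidence level) logistic fits.

    Strength is z-scored per participant over *all* their trials; the
    median split of confidence is also per participant over all trials.
    """
    pids = np.array([r.participant_id for r in records])
    strengths = stimulus_strength(records)
    corrects = np.array([r.correct for r in records], dtype=float)
    conds = np.array([r.condition for r in records])
    confs = np.array([r.confidence for r in records], dtype=float)

    fits = []
    for pid in pd.unique(pids):
        pm = pids == pid
        levels = median_split(confs[pm]) if split_by_confidence else None
        cond_groups = ("self", "other") if split_by_condition else ("all",)
        conf_groups = ("low", "high") if split_by_confidence else ("all",)
        for cond in cond_groups:
            cm = pm if cond == "all" else pm & (conds == cond)
            for lvl in conf_groups:
                if lvl == "all":
                    m = cm
                else:
                    lm = np.zeros_like(pm)
                    lm[pm] = levels == lvl
                    m = cm & lm
                fits.append(
                    fit_choice_function(
                        strengths[m], corrects[m],
                        participant_id=str(pid), condition=cond,
                        confidence_level=lvl, min_trials=min_trials,
                    )
                )
    return fits


def fits_to_frame(fits: list[PsychometricFit]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in fits])


def aggregate_fits(fits: list[PsychometricFit]) -> dict:
    """Cell means of intercepts and slopes plus the paired contrasts.

    Non-converged fits are dropped (and counted).  Paired t-tests compare
    high vs low confidence within condition and self vs other within
    confidence level, on the participants present in both cells.
    """
    df = fits_to_frame(fits)
    n_dropped = int((~df["converged"]).sum())
    ok = df[df["converged"]].copy()
    cells = (
        ok.groupby(["condition", "confidence_level"])[["intercept", "slope"]]
        .agg(["mean", "std", "count"])
    )

    def paired(field: str, fixed: str, fixed_val: str, vary: str, a: str, b: str):
        sub = ok[ok[fixed] == fixed_val]
        wide = sub.pivot_table(index="participant_id", columns=vary, values=field)
        if a not in wide.columns or b not in wide.columns:
            return None
        wide = wide.dropna(subset=[a, b])
        if len(wide) < 2:
            return None
        from .inference import paired_t

        res = paired_t(wide[a].to_numpy(), wide[b].to_numpy())
        return {"t": res.t, "p": res.p, "n": int(len(wide)),
                "mean_diff": res.mean}

    contrasts = {}
    for cond in ok["condition"].unique():
        contrasts[f"slope_high_vs_low[{cond}]"] = paired(
            "slope", "condition", cond, "confidence_level", "high", "low")
        contrasts[f"intercept_high_vs_low[{cond}]"] = paired(
            "intercept", "condition", cond, "confidence_level", "high", "low")
    for lvl in ok["confidence_level"].unique():
        contrasts[f"slope_self_vs_other[{lvl}]"] = paired(
            "slope", "confidence_level", lvl, "condition", "self", "other")
    return {"cells": cells, "contrasts": contrasts, "n_dropped": n_dropped}


def implied_accuracy_at_zero(intercepts: np.ndarray) -> np.ndarray:
    """P(correct) at zero stimulus strength implied by fitted intercepts."""
    return expit(np.asarray(intercepts, dtype=float))
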