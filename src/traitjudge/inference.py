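"""Within-subject statistics for weights and fits.

Implements the classical two-way repeated-measures ANOVA decomposition
(subject, A, B, A x B, and the three error strata A x subject,
B x subject, A x B x subject), with generalized eta squared as the effect
size,

    eta_g^2 = SS_effect / (SS_effect + SS_subject + SS_err(A) + SS_err(B)
                           + SS_err(AB)),

the Olejnik-Algina form whose denominator pools the subject variance with
every within-subject error stratum.  No sphericity correction is applied:
the critical congruence factor has two levels (needing none), and position
effects are reported uncorrected.

The symmetry test asks whether non-chosen weights are the mirror image of
chosen weights: the congruence effect should be large on the raw weights
and vanish (tiny eta_g^2) once the non-chosen row is multiplied by -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass
class EffectResult:
    F: float
    df: tuple[float, float]
    p: float
    eta_g_sq: float
    ss: float
    ss_error: float
    exact_fit: bool = False  # zero error SS: effect fits the data exactly


@dataclass
class AnovaResult:
    effects: dict[str, EffectResult]
    ss_subject: float
    ss_total: float
    ss_components: dict[str, float] = field(default_factory=dict)


def rm_anova_2way(table: np.ndarray, factor_names: tuple[str, str] = ("A", "B")) -> AnovaResult:
    """Two-way fully within-subject ANOVA on a (subjects, a, b) table."""
    y = np.asarray(table, dtype=float)
    if y.ndim != 3:
        raise ValidationError("expected a (subjects, levelA, levelB) array")
    if np.any(~np.isfinite(y)):
        raise ValidationError("missing or non-finite cells; no imputation is done")
    n, a, b = y.shape
    if n < 3:
        raise ValidationError("need at least 3 subjects")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))  # subject means
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)  # (n, a)
    m_sb = y.mean(axis=1)  # (n, b)
    m_ab = y.mean(axis=0)  # (a, b)

    ss_total = ((y - grand) ** 2).sum()
    ss_subj = a * b * ((m_s - grand) ** 2).sum()
    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_abs = ss_total - (ss_subj + ss_a + ss_b + ss_ab + ss_as + ss_bs)
    ss_abs = max(ss_abs, 0.0)  # guard tiny negative rounding

    denom_noise = ss_subj + ss_as + ss_bs + ss_abs

    def effect(name: str, ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> EffectResult:
        if ss_err <= 1e-12 * max(ss_total, 1.0):
            # error stratum vanished: report as an exact fit, not a crash
            F = 0.0 if ss_eff <= 1e-12 * max(ss_total, 1.0) else np.inf
            p = 1.0 if F == 0.0 else 0.0
            return EffectResult(F=F, df=(df_eff, df_err), p=p,
                                eta_g_sq=ss_eff / (ss_eff + denom_noise) if (ss_eff + denom_noise) > 0 else 0.0,
                                ss=ss_eff, ss_error=ss_err, exact_fit=True)
        F = (ss_eff / df_eff) / (ss_err / df_err)
        p = float(stats.f.sf(F, df_eff, df_err))
        eta = ss_eff / (ss_eff + denom_noise) if (ss_eff + denom_noise) > 0 else 0.0
        return EffectResult(F=float(F), df=(df_eff, df_err), p=p,
                            eta_g_sq=float(eta), ss=float(ss_eff), ss_error=float(ss_err))

    na, nb = factor_names
    effects = {
        na: effect(na, ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        nb: effect(nb, ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        f"{na}x{nb}": effect("ab", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)),
    }
    return AnovaResult(
        effects=effects,
        ss_subject=float(ss_subj),
        ss_total=float(ss_total),
        ss_components={
            "subject": float(ss_subj), na: float(ss_a), nb: float(ss_b),
            f"{na}x{nb}": float(ss_ab), f"{na}_error": float(ss_as),
            f"{nb}_error": float(ss_bs), f"{na}x{nb}_error": float(ss_abs),
        },
    )


@dataclass
class SymmetryReport:
    raw: AnovaResult
    inverted: AnovaResult
    symmetric: bool
    smallness_threshold: float

    @property
    def raw_congruence(self) -> EffectResult:
        return self.raw.effects["congruence"]

    @property
    def inverted_congruence(self) -> EffectResult:
        return self.inverted.effects["congruence"]


def symmetry_test(table: np.ndarray, smallness_threshold: float = 0.01) -> SymmetryReport:
    """Mirror-image test of chosen vs non-chosen weights.

    ``table`` is (subjects, 2, positions) with row 0 = chosen, row 1 =
    non-chosen.  Runs the congruence x position RM-ANOVA on the raw table
    and again after inverting (negating) the non-chosen row.  Symmetry is
    supported when the raw congruence effect is present but the
    post-inversion congruence eta_g^2 falls below the smallness threshold.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 3 or table.shape[1] != 2:
        raise ValidationError("expected a (subjects, 2, positions) weight table")
    names = ("congruence", "position")
    raw = rm_anova_2way(table, names)
    inv = table.copy()
    inv[:, 1, :] *= -1.0
    inverted = rm_anova_2way(inv, names)
    symmetric = inverted.effects["congruence"].eta_g_sq < smallness_threshold
    return SymmetryReport(raw=raw, inverted=inverted, symmetric=symmetric,
                          smallness_threshold=smallness_threshold)


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean: float


def one_sample_t(x: np.ndarray, popmean: float = 0.0) -> TTestResult:
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValidationError("one-sample t-test needs n >= 2")
    if np.std(x, ddof=1) == 0:
        raise ValidationError("zero variance in t-test input")
    t, p = stats.ttest_1samp(x, popmean)
    return TTestResult(float(t), x.size - 1, float(p), float(x.mean()))


def paired_t(x: np.ndarray, y: np.ndarray) -> TTestResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired samples must have equal length")
    d = x - y
    if d.size < 2:
        raise ValidationError("paired t-test needs n >= 2")
    if np.std(d, ddof=1) == 0 and d.mean() == 0:
        return TTestResult(0.0, d.size - 1, 1.0, 0.0)
    if np.std(d, ddof=1) == 0:
        raise ValidationError("zero variance of paired differences")
    t, p = stats.ttest_rel(x, y)
    return TTestResult(float(t), d.size - 1, float(p), float(d.mean()))


def positions_t_tests(table: np.ndarray, row: int = 1) -> list[TTestResult]:
    """One-sample t-test against zero at each word position of one
    congruence row (default: the non-chosen row) across subjects."""
    table = np.asarray(table, dtype=float)
    return [one_sample_t(table[:, row, j]) for j in range(table.shape[2])]
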