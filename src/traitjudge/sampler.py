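"""Per-trial adjective selection.

Words for a trial are drawn from the lexicon with probability proportional
to their value under an isotropic two-dimensional Gaussian in the rating
space, centred on the staircase's current diagonal position, divided by a
kernel-density estimate of how crowded the evidence scale is at each word.
The density correction prevents over-populated regions of e from being
over-represented: with it, the evidence values of the sampled words track
the Gaussian's own e-marginal rather than the lexicon's occupancy.

The Gaussian is circular (zero covariance), so the self- and other ratings
of the words within a trial are uncorrelated in expectation.  Four words
are drawn per trial without replacement (sequentially, renormalising after
each draw) and finally shuffled in place so every word-position pairing is
equally likely.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .ratings import DiagonalPoint, StandardRatings

log = logging.getLogger(__name__)


@dataclass
class SamplerConfig:
    """Tunables of the Gaussian selection kernel.

    ``sigma`` is the per-condition isotropic standard deviation in rating
    units.  If unset it is initialised as ``sigma_scale`` times the
    Euclidean distance between the two staircases' start positions.
    ``kde_bandwidth`` is the Gaussian-KDE bandwidth on the evidence scale
    ("silverman" for Silverman's rule, or a scalar factor).
    """

    sigma: dict = field(default_factory=dict)  # condition -> rating units
    sigma_scale: float = 0.5
    kde_bandwidth: object = "silverman"
    words_per_trial: int = 4

    def __post_init__(self) -> None:
        if self.words_per_trial < 1:
            raise ValidationError("words_per_trial must be >= 1")
        for cond, s in self.sigma.items():
            if s <= 0:
                raise ValidationError(f"sigma for {cond!r} must be positive")


def estimate_density(ratings: StandardRatings, bandwidth="silverman") -> np.ndarray:
    """Gaussian-kernel density of the lexicon's e values, evaluated at each
    word's own e.  Strictly positive; degenerate (all-equal e) input falls
    back to a uniform density with a warning."""
    e = ratings.e
    if np.unique(e).size < 2:
        warnings.warn("degenerate evidence values; using uniform density", stacklevel=2)
        return np.full(e.size, 1.0 / max(e.size, 1))
    kde = stats.gaussian_kde(e, bw_method=bandwidth)
    dens = kde(e)
    # KDE of finite data is positive everywhere, but guard against underflow
    return np.maximum(dens, np.finfo(float).tiny)


def selection_probabilities(
    ratings: StandardRatings,
    center: DiagonalPoint,
    cfg: SamplerConfig,
    density: np.ndarray,
    sigma: float,
) -> np.ndarray:
    """Per-word selection probabilities: isotropic Gaussian at ``center``
    divided by the per-word evidence density, normalised to sum to 1.

    Computed in log space so that a centre far from every word degrades
    gracefully toward the nearest words instead of underflowing; if the
    weights still vanish, falls back to uniform mass on the nearest word.
    """
    if np.any(density <= 0):
        raise ValidationError("density must be strictly positive")
    ds = ratings.self_ratings - center.self_coord
    do = ratings.other_ratings - center.other_coord
    logw = -(ds**2 + do**2) / (2.0 * sigma**2) - np.log(density)
    logw -= logw.max()
    w = np.exp(logw)
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        log.warning("all selection weights underflowed; falling back to nearest word")
        w = np.zeros_like(w)
        w[np.argmin(ds**2 + do**2)] = 1.0
        total = 1.0
    return w / total


def sample_trial_words(
    ratings: StandardRatings,
    center: DiagonalPoint,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    density: np.ndarray | None = None,
    sigma: float | None = None,
) -> np.ndarray:
    """Indices of the words for one trial.

    Sequential draws without replacement, renormalising the remaining
    probabilities after each draw, followed by a uniform in-place shuffle.
    Deterministic given ``rng``.
    """
    n = len(ratings)
    k = cfg.words_per_trial
    if n < k:
        raise ValidationError(f"lexicon of {n} words cannot supply {k} per trial")
    if density is None:
        density = estimate_density(ratings, cfg.kde_bandwidth)
    if sigma is None:
        sigma = cfg.sigma.get("self") or next(iter(cfg.sigma.values()), None)
        if sigma is None:
            raise ValidationError("no sigma available; configure or pass one")
    p = selection_probabilities(ratings, center, cfg, density, sigma).copy()
    chosen = np.empty(k, dtype=int)
    for j in range(k):
        p = p / p.sum()
        idx = rng.choice(n, p=p)
        chosen[j] = idx
        p[idx] = 0.0
    rng.shuffle(chosen)
    return chosen


def calibrate_sigma(
    ratings: StandardRatings,
    cfg: SamplerConfig,
    rng: np.random.Generator,
    start_centers: dict[str, DiagonalPoint],
    initial_sigma: float,
    tolerance: float = 0.1,
    max_iter: int = 20,
    n_draws: int = 2000,
) -> dict[str, float]:
    """Per-condition Gaussian widths equalising the spread of sampled words.

    Because words occupy the rating space non-uniformly, the same sigma at
    the two conditions' start positions generally yields different
    variances of the sampled words' ratings.  This rescales each
    condition's sigma, by simulated draws at its start centre, until the
    two empirical variances agree within ``tolerance`` (relative).  Returns
    the best iterate if ``max_iter`` is exhausted, with a warning.
    """
    density = estimate_density(ratings, cfg.kde_bandwidth)
    sigmas = {c: float(initial_sigma) for c in start_centers}

    def sampled_variance(cond: str, sig: float) -> float:
        p = selection_probabilities(ratings, start_centers[cond], cfg, density, sig)
        idx = rng.choice(len(ratings), size=n_draws, p=p)
        vals = np.concatenate([ratings.self_ratings[idx], ratings.other_ratings[idx]])
        return float(np.var(vals, ddof=1))

    best = dict(sigmas)
    best_ratio = np.inf
    for _ in range(max_iter):
        v = {c: sampled_variance(c, s) for c, s in sigmas.items()}
        conds = list(v)
        ratio = max(v.values()) / min(v.values())
        if ratio < best_ratio:
            best_ratio, best = ratio, dict(sigmas)
        if ratio - 1.0 <= tolerance:
            return dict(sigmas)
        target = float(np.sqrt(np.prod(list(v.values()))))  # geometric mean
        for c in conds:
            sigmas[c] *= float(np.sqrt(target / v[c])) ** 0.5  # damped update
    warnings.warn(
        f"sigma calibration did not converge (best variance ratio {best_ratio:.3f})",
        stacklevel=2,
    )
    return best
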