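import numpy as np
import pytest
from scipy import stats

import traitjudge as tj
from traitjudge.sampler import SamplerConfig, estimate_density, selection_probabilities
from conftest import make_ratings_with_e


def clustered_diagonal_ratings(n, seed) -> tj.StandardRatings:
    """Words on the major diagonal with strongly non-uniform e-density:
    a dense Gaussian cluster near 0 plus a sparse uniform background
    (peak-to-background density ratio of roughly 4-5)."""
    rng = np.random.default_rng(seed)
    n_cluster = int(0.7 * n)
    e = np.concatenate([
        np.clip(rng.normal(0, 18, n_cluster), -95, 95),
        rng.uniform(-70, 70, n - n_cluster),
    ])
    return make_ratings_with_e(e)


def truncated_gaussian_e_marginal(ratings, center_e, sigma, size, rng):
    """Oracle draws from the selection Gaussian's evidence marginal,
    restricted to the lexicon's support.  For an isotropic Gaussian with
    per-dimension sd sigma the e = self - other marginal has sd
    sigma * sqrt(2)."""
    sd_e = sigma * np.sqrt(2)
    lo, hi = ratings.e.min(), ratings.e.max()
    a, b = (lo - center_e) / sd_e, (hi - center_e) / sd_e
    return stats.truncnorm.rvs(a, b, loc=center_e, scale=sd_e, size=size,
                               random_state=rng)


class TestSelectionProbabilities:
    def test_normalized_and_single_word(self):
        r = make_ratings_with_e([10.0])
        p = selection_probabilities(r, tj.diagonal_point(0), SamplerConfig(),
                                    np.array([1.0]), sigma=10.0)
        assert p == pytest.approx([1.0])

    def test_mirror_symmetric_words_get_equal_mass(self):
        r = make_ratings_with_e([-30.0, 30.0])
        p = selection_probabilities(r, tj.diagonal_point(0), SamplerConfig(),
                                    np.array([0.5, 0.5]), sigma=10.0)
        assert p == pytest.approx([0.5, 0.5])
        assert p.sum() == pytest.approx(1.0)

    def test_relabeling_invariance(self):
        e = np.array([-20.0, 5.0, 40.0])
        r = make_ratings_with_e(e)
        dens = estimate_density(r)
        p = selection_probabilities(r, tj.diagonal_point(10), SamplerConfig(), dens, 8.0)
        perm = [2, 0, 1]
        r2 = make_ratings_with_e(e[perm])
        p2 = selection_probabilities(r2, tj.diagonal_point(10), SamplerConfig(),
                                     dens[perm], 8.0)
        assert p2 == pytest.approx(p[perm])

    def test_non_positive_density_rejected(self):
        r = make_ratings_with_e([0.0, 10.0])
        with pytest.raises(tj.ValidationError):
            selection_probabilities(r, tj.diagonal_point(0), SamplerConfig(),
                                    np.array([0.0, 1.0]), 10.0)


class TestDensity:
    def test_symmetric_clusters_have_equal_density(self):
        e = np.concatenate([np.full(10, -50.0), np.full(10, 50.0),
                            [-49, -51, 49, 51]])
        dens = estimate_density(make_ratings_with_e(e))
        assert dens[0] == pytest.approx(dens[10], rel=1e-6)

    def test_uniform_grid_near_constant_away_from_edges(self):
        e = np.linspace(-80, 80, 81)
        dens = estimate_density(make_ratings_with_e(e))
        interior = dens[20:-20]
        # analytic uniform density over [-80, 80]
        assert np.all(np.abs(interior - 1 / 160.0) / (1 / 160.0) < 0.10)

    def test_kde_integrates_to_one(self):
        r = make_ratings_with_e([-40, -10, 0, 5, 30, 60])
        kde = stats.gaussian_kde(r.e)
        grid = np.linspace(-200, 200, 2001)
        assert np.trapezoid(kde(grid), grid) == pytest.approx(1.0, abs=1e-3)

    def test_degenerate_equal_e_warns_uniform(self):
        with pytest.warns(UserWarning):
            dens = estimate_density(make_ratings_with_e([10.0, 10.0, 10.0]))
        assert dens == pytest.approx([1 / 3] * 3)


class TestSampleTrialWords:
    def test_four_word_lexicon_exhaustive_and_uniform_order(self):
        r = make_ratings_with_e([-30, -10, 10, 30])
        cfg = SamplerConfig(words_per_trial=4)
        rng = np.random.default_rng(0)
        dens = estimate_density(r)
        counts = {}
        n = 3000
        for _ in range(n):
            idx = tuple(tj.sample_trial_words(r, tj.diagonal_point(0), cfg, rng,
                                              density=dens, sigma=15.0))
            assert sorted(idx) == [0, 1, 2, 3]
            counts[idx] = counts.get(idx, 0) + 1
        freqs = np.array([counts.get(p, 0) for p in counts])
        assert len(counts) == 24
        chi, p = stats.chisquare(list(counts.values()), [n / 24] * 24)
        assert p > 0.001

    def test_no_repeats_within_trials(self, ratings104):
        cfg = SamplerConfig()
        rng = np.random.default_rng(1)
        dens = estimate_density(ratings104)
        for _ in range(500):
            idx = tj.sample_trial_words(ratings104, tj.diagonal_point(5), cfg, rng,
                                        density=dens, sigma=12.0)
            assert len(set(idx)) == 4

    def test_seeded_determinism(self, ratings104):
        cfg = SamplerConfig()

        def draw(seed):
            rng = np.random.default_rng(seed)
            return [tuple(tj.sample_trial_words(ratings104, tj.diagonal_point(0),
                                                cfg, rng, sigma=12.0))
                    for _ in range(20)]

        assert draw(3) == draw(3)
        assert draw(3) != draw(4)

    def test_lexicon_too_small(self):
        r = make_ratings_with_e([0.0, 10.0])
        with pytest.raises(tj.ValidationError):
            tj.sample_trial_words(r, tj.diagonal_point(0), SamplerConfig(),
                                  np.random.default_rng(0), sigma=10.0)


class TestDensityCorrection:
    def test_corrected_marginal_matches_gaussian_uncorrected_does_not(self):
        """On a clustered-e lexicon the density-corrected sampler reproduces
        the Gaussian's e-marginal (two-sample KS vs draws from the truncated
        Gaussian) while the uncorrected sampler is pulled toward the
        over-populated cluster.

        The KDE bandwidth must resolve the cluster scale for the correction
        to be accurate (Silverman's rule over-smooths mixtures), so the
        fixture uses a fixed 0.15 bandwidth factor and a lexicon dense
        enough that discretisation is negligible against the KS resolution.
        """
        r = clustered_diagonal_ratings(n=2000, seed=2)
        center_e, sigma = 25.0, 12.0
        center = tj.diagonal_point(center_e)
        cfg = SamplerConfig(words_per_trial=4)
        dens = estimate_density(r, bandwidth=0.15)
        uniform = np.full(len(r), 1.0 / len(r))

        def pooled_e(density, rng, n_trials):
            out = []
            for _ in range(n_trials):
                idx = tj.sample_trial_words(r, center, cfg, rng,
                                            density=density, sigma=sigma)
                out.append(r.e[idx])
            return np.concatenate(out)

        n_trials = 500  # 2000 pooled draws
        corrected = pooled_e(dens, np.random.default_rng(10), n_trials)
        uncorrected = pooled_e(uniform, np.random.default_rng(11), n_trials)
        oracle = truncated_gaussian_e_marginal(
            r, center_e, sigma, 2000, np.random.default_rng(12))
        assert stats.ks_2samp(corrected, oracle).pvalue > 0.01
        assert stats.ks_2samp(uncorrected, oracle).pvalue < 0.01

    def test_within_trial_ratings_uncorrelated_under_circular_kernel(self):
        """The circular (zero-covariance) selection Gaussian leaves the self
        and other ratings of sampled words uncorrelated around the trial
        centre; the 1-D density correction may add only a mild anti-diagonal
        correlation on top."""
        big = tj.generate_fixture_lexicon(3000, rng_seed=4)
        params = tj.ObserverParams(rating_sd=25.0)
        r = tj.generate_standard_ratings(big, params, np.random.default_rng(8))
        cfg = SamplerConfig()
        center = tj.diagonal_point(0)

        def pooled_corr(density, seed):
            rng = np.random.default_rng(seed)
            fl = []
            for _ in range(1500):
                idx = tj.sample_trial_words(r, center, cfg, rng,
                                            density=density, sigma=10.0)
                fl.append(np.column_stack([
                    r.self_ratings[idx] - center.self_coord,
                    r.other_ratings[idx] - center.other_coord,
                ]))
            fl = np.concatenate(fl)
            return np.corrcoef(fl[:, 0], fl[:, 1])[0, 1]

        assert abs(pooled_corr(np.full(len(r), 1.0 / len(r)), 5)) < 0.05
        assert abs(pooled_corr(estimate_density(r), 6)) < 0.2


class TestCalibration:
    def test_infinite_tolerance_is_noop(self, ratings104):
        cfg = SamplerConfig()
        out = tj.calibrate_sigma(
            ratings104, cfg, np.random.default_rng(0),
            {"self": tj.diagonal_point(20), "other": tj.diagonal_point(-20)},
            initial_sigma=10.0, tolerance=np.inf,
        )
        assert out == {"self": 10.0, "other": 10.0}

    def test_mirror_symmetric_lexicon_keeps_equal_sigmas(self):
        e = np.concatenate([np.linspace(5, 60, 20), -np.linspace(5, 60, 20)])
        r = make_ratings_with_e(e)
        out = tj.calibrate_sigma(
            r, SamplerConfig(), np.random.default_rng(1),
            {"self": tj.diagonal_point(30), "other": tj.diagonal_point(-30)},
            initial_sigma=10.0,
        )
        assert out["self"] == pytest.approx(out["other"], rel=0.2)

    def test_one_sided_density_calibrates_within_tolerance(self):
        # dense on the self side, sparse on the other side
        rng = np.random.default_rng(6)
        e = np.concatenate([rng.uniform(5, 60, 80), rng.uniform(-60, -5, 12)])
        r = make_ratings_with_e(e)
        cfg = SamplerConfig()
        centers = {"self": tj.diagonal_point(30), "other": tj.diagonal_point(-30)}
        out = tj.calibrate_sigma(r, cfg, np.random.default_rng(2), centers,
                                 initial_sigma=8.0, tolerance=0.1)
        # post-hoc check with an independent rng and larger n
        dens = estimate_density(r)
        v = {}
        rng2 = np.random.default_rng(99)
        for cond, sig in out.items():
            p = selection_probabilities(r, centers[cond], cfg, dens, sig)
            idx = rng2.choice(len(r), size=10_000, p=p)
            v[cond] = np.var(np.concatenate([r.self_ratings[idx],
                                             r.other_ratings[idx]]), ddof=1)
        assert max(v.values()) / min(v.values()) < 1.25
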