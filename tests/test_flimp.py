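"""Rician separation posteriors, mixture decomposition and post-analysis."""

import numpy as np
import pytest
import scipy.stats

from oligoscope import (
    ChainGeometry,
    FLImPDataset,
    LabelingScheme,
    Localization,
    OligomerComposition,
    SeparationMeasurement,
    filter_ci,
    fit_mixture,
    range_fractions,
    select_K,
    separation_posterior,
    simulate_flimp_measurements,
    simulate_spot_movie,
)
from oligoscope.flimp import (
    NotAPairError,
    bootstrap_errors,
    extract_two_emitter_positions,
    measurement_from_movie,
    rice_logpdf,
)

from conftest import rice_sample


def _dataset(r, sigma):
    sigma = np.broadcast_to(np.asarray(sigma, float), np.shape(r))
    return FLImPDataset(
        [SeparationMeasurement(float(ri), float(si), (0.0, 60.0)) for ri, si in zip(r, sigma)]
    )


class TestRiceLikelihood:
    def test_matches_scipy_rice(self):
        # independent implementation of the same density
        r = np.linspace(0.5, 30, 40)
        for nu, sigma in [(0.0, 2.0), (5.0, 2.0), (13.0, 3.0)]:
            ours = np.exp(rice_logpdf(r, nu, sigma))
            ref = scipy.stats.rice.pdf(r, b=nu / sigma, scale=sigma)
            np.testing.assert_allclose(ours, ref, rtol=1e-9)

    def test_reduces_to_rayleigh_at_zero_separation(self):
        r = np.linspace(0.1, 10, 20)
        ours = np.exp(rice_logpdf(r, 0.0, 2.0))
        ref = scipy.stats.rayleigh.pdf(r, scale=2.0)
        np.testing.assert_allclose(ours, ref, rtol=1e-9)


class TestSeparationPosterior:
    def test_noise_free_degenerate_interval(self):
        m = separation_posterior(Localization(0, 0, 0.0), Localization(10, 0, 0.0))
        assert m.r_obs == 10.0
        assert m.ci69 == (10.0, 10.0)

    def test_coincident_emitters_interval_starts_at_zero(self):
        m = separation_posterior(Localization(0, 0, 2.0), Localization(0, 0, 2.0))
        assert m.ci69[0] == 0.0
        assert m.ci69[1] > 0.0

    def test_posterior_mode_matches_grid_search_oracle(self):
        m = separation_posterior(Localization(0, 0, 2.0), Localization(13, 0, 2.0))
        sigma = np.hypot(2.0, 2.0)
        nu_grid = np.linspace(0.0, 40.0, 200001)
        oracle = nu_grid[
            np.argmax(scipy.stats.rice.pdf(13.0, b=nu_grid / sigma, scale=sigma))
        ]
        # the mode must fall inside the HDI and near the oracle
        assert m.ci69[0] <= oracle <= m.ci69[1]
        mid = 0.5 * (m.ci69[0] + m.ci69[1])
        assert mid == pytest.approx(oracle, abs=0.5)

    def test_interval_width_shrinks_with_sigma(self):
        widths = [
            separation_posterior(
                Localization(0, 0, s), Localization(13, 0, s)
            ).ci_width
            for s in (4.0, 2.0, 1.0, 0.5)
        ]
        assert np.all(np.diff(widths) < 0)

    def test_posterior_mean_approaches_nu_in_gaussian_limit(self):
        # at nu / sigma >= 10 the Rice posterior centres on nu within 1%
        sigma = 1.0
        m = separation_posterior(Localization(0, 0, sigma / np.sqrt(2)),
                                 Localization(15.0, 0, sigma / np.sqrt(2)))
        mid = 0.5 * (m.ci69[0] + m.ci69[1])
        assert mid == pytest.approx(15.0, rel=0.01)


class TestCiFilter:
    def test_boundary_inclusive(self):
        ms = [
            SeparationMeasurement(10.0, 2.0, (0.0, w)) for w in (6.0, 7.0, 8.0)
        ]
        kept = filter_ci(FLImPDataset(ms), 7.0)
        assert len(kept) == 2

    def test_zero_threshold_keeps_only_degenerate(self):
        ms = [
            SeparationMeasurement(10.0, 0.0, (10.0, 10.0)),
            SeparationMeasurement(10.0, 2.0, (8.0, 12.0)),
        ]
        assert len(filter_ci(FLImPDataset(ms), 0.0)) == 1

    def test_order_preserved(self):
        ms = [SeparationMeasurement(float(i), 1.0, (0.0, 5.0)) for i in range(5)]
        kept = filter_ci(FLImPDataset(ms), 7.0)
        assert [m.r_obs for m in kept.measurements] == [0.0, 1.0, 2.0, 3.0, 4.0]


class TestMovieExtraction:
    def test_noise_free_movie_recovers_separation_exactly(self):
        sep_nm = 5 * 80.0  # 5 px
        movie = simulate_spot_movie(
            sep_nm, noise=False, bleach_frames=(20, 40), image_size_px=21, seed=0
        )
        a, b = extract_two_emitter_positions(movie)
        assert np.hypot(a.x - b.x, a.y - b.y) / 80.0 == pytest.approx(5.0, abs=1e-3)

    def test_single_emitter_movie_raises_not_a_pair(self):
        movie = simulate_spot_movie(0.0, n_emitters=1, noise=False,
                                    bleach_frames=(20,), seed=1)
        with pytest.raises(NotAPairError):
            extract_two_emitter_positions(movie)

    def test_ci_covers_truth_in_most_noisy_replicates(self):
        hits, n = 0, 0
        for s in range(100):
            movie = simulate_spot_movie(160.0, photons_per_frame=2300, seed=s)
            try:
                m = measurement_from_movie(movie)
            except Exception:
                continue
            n += 1
            if m.ci69[0] <= 160.0 <= m.ci69[1]:
                hits += 1
        assert n >= 80
        assert hits / n >= 0.60


class TestMixtureFit:
    def test_single_component_position_recovery(self):
        rng = np.random.default_rng(11)
        r = rice_sample(rng, 13.0, 2.0, 100)
        comps, _ = fit_mixture(_dataset(r, 2.0), K=1, restarts=3, seed=0)
        assert comps[0].nu == pytest.approx(13.0, abs=0.6)  # 3 SE at n=100

    def test_duplicating_measurements_leaves_argmax_unchanged(self):
        rng = np.random.default_rng(12)
        r = rice_sample(rng, 13.0, 2.0, 60)
        ds1 = _dataset(r, 2.0)
        ds2 = _dataset(np.concatenate([r, r]), 2.0)
        c1, _ = fit_mixture(ds1, 1, restarts=2, seed=0)
        c2, _ = fit_mixture(ds2, 1, restarts=2, seed=0)
        assert c1[0].nu == pytest.approx(c2[0].nu, abs=1e-4)

    def test_k_exceeding_dataset_size_rejected(self):
        ds = _dataset([10.0, 12.0], 2.0)
        with pytest.raises(ValueError):
            fit_mixture(ds, K=3)

    def test_overfit_component_gain_below_bic_penalty(self):
        rng = np.random.default_rng(13)
        r = rice_sample(rng, 13.0, 2.0, 150)
        ds = _dataset(r, 2.0)
        _, ll1 = fit_mixture(ds, 1, restarts=3, seed=0)
        _, ll2 = fit_mixture(ds, 2, restarts=3, seed=0)
        assert 2 * (ll2 - ll1) < 2 * np.log(len(ds))


class TestModelSelection:
    def test_two_well_separated_components_selected(self):
        rng = np.random.default_rng(21)
        r = np.concatenate(
            [rice_sample(rng, 5.0, 2.0, 100), rice_sample(rng, 13.0, 2.0, 100)]
        )
        res = select_K(_dataset(r, 2.0), K_max=4, restarts=3, seed=0)
        assert res.K == 2
        nus = sorted(c.nu for c in res.components)
        assert nus[0] == pytest.approx(5.0, abs=1.0)
        assert nus[1] == pytest.approx(13.0, abs=1.0)
        assert sum(c.n_measurements for c in res.components) == len(r)

    def test_single_measurement_forces_k1(self):
        res = select_K(_dataset([10.0], 2.0), K_max=5)
        assert res.K == 1

    def test_truncation_to_first_component_does_not_increase_k(self):
        rng = np.random.default_rng(22)
        r_lo = rice_sample(rng, 5.0, 2.0, 100)
        r_hi = rice_sample(rng, 20.0, 2.0, 100)
        full = select_K(_dataset(np.concatenate([r_lo, r_hi]), 2.0), K_max=3,
                        restarts=2, seed=0)
        trunc = select_K(_dataset(r_lo, 2.0), K_max=3, restarts=2, seed=0)
        assert trunc.K <= full.K

    def test_bic_table_is_complete(self):
        rng = np.random.default_rng(23)
        r = rice_sample(rng, 10.0, 2.0, 50)
        res = select_K(_dataset(r, 2.0), K_max=3, restarts=2, seed=0)
        assert sorted(res.bic_table) == [1, 2, 3]
        assert res.bic_table[res.K] == min(res.bic_table.values())


class TestBootstrap:
    def test_degenerate_dataset_zero_sd(self):
        ds = _dataset(np.full(20, 10.0), 1e-6)
        sds, _ = bootstrap_errors(ds, K=1, n_boot=10, seed=0)
        assert sds[0] == pytest.approx(0.0, abs=1e-3)

    def test_sd_decreases_with_sample_size(self):
        rng = np.random.default_rng(31)
        small = _dataset(rice_sample(rng, 13.0, 2.0, 50), 2.0)
        large = _dataset(rice_sample(rng, 13.0, 2.0, 400), 2.0)
        sd_small, _ = bootstrap_errors(small, 1, n_boot=40, seed=1)
        sd_large, _ = bootstrap_errors(large, 1, n_boot=40, seed=1)
        assert sd_large[0] < sd_small[0]

    def test_bootstrap_sd_calibrated_against_replicates(self):
        # bootstrap SD should approximate the across-replicate SD of nu_hat
        rng = np.random.default_rng(32)
        n = 80
        nu_hats = []
        for _ in range(60):
            ds = _dataset(rice_sample(rng, 13.0, 2.0, n), 2.0)
            comps, _ = fit_mixture(ds, 1, restarts=1, seed=0)
            nu_hats.append(comps[0].nu)
        true_sd = np.std(nu_hats, ddof=1)
        ds = _dataset(rice_sample(rng, 13.0, 2.0, n), 2.0)
        boot_sd, _ = bootstrap_errors(ds, 1, n_boot=60, seed=2, restarts=1)
        assert abs(boot_sd[0] - true_sd) / true_sd < 0.5


class TestRangeFractions:
    def test_point_and_interval_conventions(self):
        ms = [
            SeparationMeasurement(5.0, 1.0, (4.0, 6.0)),
            SeparationMeasurement(17.0, 1.0, (16.0, 19.0)),
            SeparationMeasurement(18.0, 2.0, (14.0, 22.0)),
        ]
        ds = FLImPDataset(ms)
        point5, dimer_band, oligomer_band = range_fractions(
            ds, [5.0, (0.0, 15.0), (20.0, 60.0)]
        )
        assert point5 == pytest.approx(1 / 3)  # only (4,6) contains 5
        assert dimer_band == pytest.approx(2 / 3)  # (4,6) and (14,22)
        assert oligomer_band == pytest.approx(1 / 3)  # only (14,22); classes overlap

    def test_disjoint_interval_not_counted(self):
        ds = FLImPDataset([SeparationMeasurement(17.0, 1.0, (16.0, 19.0))])
        assert range_fractions(ds, [(20.0, 60.0)]) == [0.0]

    def test_malformed_interval_rejected(self):
        ds = FLImPDataset([SeparationMeasurement(5.0, 1.0, (4.0, 6.0))])
        with pytest.raises(ValueError):
            range_fractions(ds, [(10.0, 5.0)])


class TestGeneratorIntegration:
    def test_noise_free_dimers_reproduce_spacing(self):
        geom = ChainGeometry(9.0, 40.0)
        comp = OligomerComposition([0.0, 1.0])
        scheme = LabelingScheme("internal_1to1", p_label=1.0)
        ds = simulate_flimp_measurements(geom, comp, scheme, 1e-9, 50, seed=0)
        np.testing.assert_allclose(ds.r_obs, 9.0, atol=1e-6)

    def test_coincident_sites_give_rayleigh_distances(self):
        # true separation zero: observed distance is Rayleigh with the
        # combined scale sigma * sqrt(2)
        geom = ChainGeometry(9.0, 0.0)
        comp = OligomerComposition([1.0])
        # single site labelled twice is impossible; emulate via two sites at
        # zero spacing through direct sampling instead
        rng = np.random.default_rng(5)
        r = rice_sample(rng, 0.0, 2.0 * np.sqrt(2), 4000)
        ks = scipy.stats.kstest(r, scipy.stats.rayleigh(scale=2 * np.sqrt(2)).cdf)
        assert ks.pvalue > 0.01
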