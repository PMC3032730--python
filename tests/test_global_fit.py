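import numpy as np
import pytest
from scipy import optimize

from mpflim import (
    ComponentSpec,
    ModelSpec,
    PipelineConfig,
    build_kernels,
    deviance,
    expected_counts,
    fit_amplitudes_batch,
    fit_lifetimes,
    fit_pixel_amplitudes,
    run_pipeline,
    sum_decays,
)
from mpflim.global_fit import FitError, InfiniteDevianceError
from mpflim.segmentation import SegmentMap, segment
from mpflim.simulator import preset_scene, simulate_decay_cube


class TestDeviance:
    def test_zero_iff_model_equals_data(self):
        n = np.array([3.0, 7.0, 0.0])
        assert deviance(n, n) == 0.0

    def test_frozen_arithmetic_example(self):
        # 2 * 10 * ln 2
        assert deviance([10.0, 0.0], [5.0, 5.0]) == pytest.approx(
            20.0 * np.log(2.0), rel=1e-12
        )

    def test_equals_poisson_deviance_under_conservation(self, rng):
        for _ in range(20):
            n = rng.poisson(8.0, size=40).astype(float)
            m = rng.uniform(0.1, 1.0, size=40)
            m *= n.sum() / m.sum()
            pois = 2.0 * np.sum(
                np.where(n > 0, n * np.log(np.maximum(n, 1) / m), 0.0)
                - (n - m)
            )
            assert deviance(n, m) == pytest.approx(pois, rel=1e-9, abs=1e-9)

    def test_requires_conserved_total(self):
        with pytest.raises(ValueError):
            deviance([5.0, 5.0], [2.0, 2.0])

    def test_infinite_deviance_flagged(self):
        with pytest.raises(InfiniteDevianceError):
            deviance([5.0, 5.0], [10.0, 0.0])


class TestSumDecays:
    def test_single_pixel_region_is_that_histogram(self):
        cfg = preset_scene("rhodamine6g", seed=0, shape=(3, 3), photons_per_pixel=60)
        cube, _ = simulate_decay_cube(cfg)
        labels = np.zeros((3, 3), dtype=int)
        labels[1, 2] = 1
        seg = SegmentMap(labels, 0, 8)
        summed = sum_decays(cube, seg, 1)
        np.testing.assert_array_equal(
            summed["532RFP"], cube.channel_counts("532RFP")[1, 2]
        )

    def test_disjoint_regions_are_additive_and_conserving(self):
        cfg = preset_scene("rhodamine6g", seed=1, shape=(4, 6), photons_per_pixel=40)
        cube, _ = simulate_decay_cube(cfg)
        labels = np.ones((4, 6), dtype=int)
        labels[:, 3:] = 2
        seg = SegmentMap(labels, 0, 8)
        total = sum(sum_decays(cube, seg, lab)["532RFP"] for lab in (1, 2))
        np.testing.assert_array_equal(
            total, cube.channel_counts("532RFP").sum(axis=(0, 1))
        )
        assert total.sum() == cube.channel_counts("532RFP").sum()

    def test_empty_region_is_an_error(self):
        cfg = preset_scene("rhodamine6g", seed=0, shape=(2, 2), photons_per_pixel=10)
        cube, _ = simulate_decay_cube(cfg)
        seg = SegmentMap(np.zeros((2, 2), dtype=int), 0, 8)
        with pytest.raises(KeyError):
            sum_decays(cube, seg, 1)


class TestPixelAmplitudes:
    def test_single_component_closed_form(self, ref_small):
        kern = build_kernels(ref_small, [1500.0])
        counts = np.round(expected_counts(kern, [200.0]))
        res = fit_pixel_amplitudes(counts, kern)
        assert res.alpha[0] == pytest.approx(counts.sum())

    def test_noiseless_histogram_recovers_generating_amplitudes(self, ref_small):
        kern = build_kernels(ref_small, [500.0, 3700.0])
        alpha_true = np.array([120.0, 480.0])
        counts = expected_counts(kern, alpha_true)
        res = fit_pixel_amplitudes(counts, kern)
        np.testing.assert_allclose(res.alpha, alpha_true, rtol=1e-6)
        assert res.deviance == pytest.approx(0.0, abs=1e-8)

    def test_sum_constraint_active_exactly(self, ref_small, rng):
        kern = build_kernels(ref_small, [500.0, 3700.0])
        q = expected_counts(kern, [0.1, 0.9])
        counts = rng.multinomial(300, q / q.sum(), size=50).astype(float)
        alpha, dev, fitted = fit_amplitudes_batch(counts, kern)
        assert fitted.all()
        np.testing.assert_allclose(alpha.sum(axis=1), 300.0, atol=1e-9)
        assert (dev >= 0).all()

    def test_two_starts_converge_to_same_optimum(self, ref_small, rng):
        # convexity: the optimum is independent of the starting point
        kern = build_kernels(ref_small, [440.0, 1500.0, 3200.0])
        signs = np.array([True, False, False])
        a_true = np.array([-60.0, 260.0, 300.0])
        m = expected_counts(kern, a_true)
        counts = rng.poisson(m).astype(float)[None, :]
        a1, _, _ = fit_amplitudes_batch(
            counts, kern, signs, beta0=np.array([0.2, 0.4, 0.4])
        )
        a2, _, _ = fit_amplitudes_batch(
            counts, kern, signs, beta0=np.array([-0.3, 0.8, 0.5])
        )
        np.testing.assert_allclose(a1, a2, atol=1e-8 * counts.sum())

    def test_matches_generic_constrained_optimizer(self, ref_small, rng):
        # independent route: SLSQP on the same deviance objective
        kern = build_kernels(ref_small, [500.0, 3700.0])
        q = expected_counts(kern, [0.2, 0.8])
        phi = kern.phi
        for _ in range(3):
            counts = rng.multinomial(400, q / q.sum()).astype(float)
            alpha, _, _ = fit_amplitudes_batch(counts[None, :], kern)

            def nll(beta):
                p = beta @ phi
                ok = p > 0
                return -(counts[ok] * np.log(p[ok])).sum()

            res = optimize.minimize(
                nll,
                x0=np.array([0.5, 0.5]),
                method="SLSQP",
                bounds=[(0, 1), (0, 1)],
                constraints={"type": "eq", "fun": lambda b: b.sum() - 1.0},
                options={"ftol": 1e-14, "maxiter": 300},
            )
            np.testing.assert_allclose(
                alpha[0] / counts.sum(), res.x, atol=5e-6
            )

    def test_rise_component_estimated_negative(self, ref_small, rng):
        kern = build_kernels(ref_small, [440.0, 2490.0])
        signs = np.array([True, False])
        a_true = np.array([-44.0, 544.0])  # molecule fractions (-33, 67)
        m = expected_counts(kern, a_true)
        counts = rng.multinomial(
            500, m / m.sum(), size=200
        ).astype(float)
        alpha, _, _ = fit_amplitudes_batch(counts, kern, signs)
        assert alpha[:, 0].mean() < 0

    def test_pixel_below_floor_rejected(self, ref_small):
        kern = build_kernels(ref_small, [1500.0])
        with pytest.raises(FitError):
            fit_pixel_amplitudes(
                np.zeros(ref_small.time_axis.n_channels), kern, min_photons=1
            )


class TestFitLifetimes:
    def test_noiseless_biexponential_identifiable(self, ref_small):
        kern = build_kernels(ref_small, [500.0, 3700.0])
        trace = expected_counts(kern, np.array([1e5, 9e5]))
        model = ModelSpec(
            {"532RFP": [ComponentSpec(tau=700.0), ComponentSpec(tau=3000.0)]}
        )
        fit = fit_lifetimes({"532RFP": trace}, model, ref_small, compute_ci=False)
        taus = sorted(fit.taus.values())
        assert taus[0] == pytest.approx(500.0, rel=1e-6)
        assert taus[1] == pytest.approx(3700.0, rel=1e-6)
        assert fit.converged

    def test_pooled_noisy_recovery_within_one_percent(self, ref_default):
        cfg = preset_scene(
            "rhodamine6g", seed=9, shape=(100, 100), photons_per_pixel=500
        )
        cube, _ = simulate_decay_cube(cfg)
        pooled = cube.channel_counts("532RFP").sum(axis=(0, 1)).astype(float)
        model = ModelSpec(
            {"532RFP": [ComponentSpec(tau=700.0), ComponentSpec(tau=3000.0)]}
        )
        fit = fit_lifetimes({"532RFP": pooled}, model, ref_default, compute_ci=True)
        taus = sorted(fit.taus.values())
        assert taus[0] == pytest.approx(500.0, rel=0.01)
        assert taus[1] == pytest.approx(3700.0, rel=0.01)
        lo, hi = sorted(fit.taus_ci68.values())[0]
        assert lo < hi

    def test_linked_lifetime_shared_with_opposite_amplitude_signs(self, ref_default):
        cfg = preset_scene("fret_construct", seed=4, photons_per_pixel=500)
        cube, _ = simulate_decay_cube(cfg)
        fg = cfg.mask()
        summed = {
            ch: cube.channel_counts(ch)[fg].sum(axis=0).astype(float)
            for ch in ("473GFP", "473RFP")
        }
        model = ModelSpec(
            {
                "473GFP": [
                    ComponentSpec(tau=350.0, link_key="fret"),
                    ComponentSpec(tau=1500.0),
                    ComponentSpec(tau=2900.0),
                ],
                "473RFP": [
                    ComponentSpec(tau=350.0, link_key="fret", sign="free"),
                    ComponentSpec(tau=2200.0),
                ],
            }
        )
        fit = fit_lifetimes(summed, model, ref_default, compute_ci=False)
        assert "fret" in fit.taus  # single shared estimate
        assert fit.taus["fret"] == pytest.approx(440.0, rel=0.15)
        assert fit.channel_amplitudes["473GFP"][0] > 0
        assert fit.channel_amplitudes["473RFP"][0] < 0


class TestPipeline:
    def test_donor_only_maps_recover_molecule_fractions(self, ref_default):
        # with lifetimes at their global values the per-pixel molecule
        # fractions average to the generating (17, 28, 55)% split
        cfg = preset_scene("donor_only", seed=6, shape=(32, 32), photons_per_pixel=500)
        cube, _ = simulate_decay_cube(cfg)
        model = ModelSpec(
            {
                "473GFP": [
                    ComponentSpec(tau=180.0),
                    ComponentSpec(tau=1720.0),
                    ComponentSpec(tau=2710.0),
                ]
            }
        )
        result = run_pipeline(
            cube,
            PipelineConfig(model, ref_default, threshold=30, fix_lifetimes=True),
        )
        assert result.segment_map.n_regions == 1
        lm = result.maps["473GFP"]
        p_mean = np.array(
            [np.nanmean(lm.preexp_fractions[j]) for j in range(3)]
        )
        np.testing.assert_allclose(p_mean, [0.17, 0.28, 0.55], atol=0.03)
        # maps defined exactly on the segmented foreground
        assert np.isfinite(lm.tau_av).sum() == result.segment_map.foreground.sum()
        fg = result.segment_map.foreground
        assert np.isnan(lm.tau_av[~fg]).all()

    def test_donor_only_end_to_end_free_lifetimes(self, ref_default):
        # the 1.72/2.71 ns pair is only weakly identifiable at this photon
        # budget; the fast molecule fraction and the mean lifetime are the
        # stable end-to-end observables
        cfg = preset_scene("donor_only", seed=6, shape=(32, 32), photons_per_pixel=500)
        cube, _ = simulate_decay_cube(cfg)
        model = ModelSpec(
            {
                "473GFP": [
                    ComponentSpec(tau=250.0),
                    ComponentSpec(tau=1400.0),
                    ComponentSpec(tau=3000.0),
                ]
            }
        )
        result = run_pipeline(
            cube, PipelineConfig(model, ref_default, threshold=30)
        )
        lm = result.maps["473GFP"]
        fast = int(np.argmin(lm.taus))
        p_fast = np.nanmean(lm.preexp_fractions[fast])
        assert p_fast == pytest.approx(0.17, abs=0.03)
        tau_mean = np.nanmean(lm.tau_mean)
        assert tau_mean == pytest.approx(2003.0, rel=0.03)

    def test_empty_foreground_yields_empty_result(self, ref_small):
        cfg = preset_scene("rhodamine6g", seed=0, shape=(4, 4), photons_per_pixel=2)
        cube, _ = simulate_decay_cube(cfg)
        model = ModelSpec({"532RFP": [ComponentSpec(tau=2000.0)]})
        result = run_pipeline(
            cube, PipelineConfig(model, ref_small, threshold=1000)
        )
        assert result.segment_map.n_regions == 0
        assert not result.region_fits
        assert np.isnan(result.maps["532RFP"].tau_av).all()
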