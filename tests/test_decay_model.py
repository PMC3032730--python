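import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpflim import (
    ReferenceDecay,
    TimeAxis,
    average_lifetime,
    build_kernels,
    expected_counts,
    mean_lifetime,
    normalized_amplitudes,
    pre_exponential_fractions,
)
from mpflim.decay_model import (
    DomainError,
    Kernels,
    ModelValidityError,
    amplitude_fractions_from_preexp,
)


def oracle_kernel(ref: ReferenceDecay, tau: float, oversample: int = 16):
    """Independent reconvolution oracle on a 16x-oversampled grid.

    The convolution integral C(t) = int_0^t rho(s) exp(-(t-s)/tau) ds obeys
    C' = rho - C/tau; with the binned reference as piecewise-constant
    density this ODE is propagated exactly (exponential integrator) on the
    fine grid, then channel-averaged by the trapezoid rule.
    """
    axis = ref.time_axis
    dt = axis.channel_width
    h = dt / oversample
    rho = np.repeat(ref.histogram / dt, oversample)
    conv_edges = np.zeros(len(rho) + 1)
    decay = np.exp(-h / tau)
    gain = tau * (1.0 - decay)
    for m in range(len(rho)):
        conv_edges[m + 1] = conv_edges[m] * decay + rho[m] * gain
    conv_avg = np.empty(axis.n_channels)
    for i in range(axis.n_channels):
        seg = conv_edges[i * oversample : (i + 1) * oversample + 1]
        conv_avg[i] = np.trapezoid(seg, dx=h) / dt
    phi = ref.histogram / dt + (1.0 / ref.tau_ref - 1.0 / tau) * conv_avg
    phi = np.clip(phi, 0.0, None)
    return phi / phi.sum()


class TestBuildKernels:
    def test_tau_equal_tau_ref_reduces_to_reference(self, ref_small):
        phi = build_kernels(ref_small, [ref_small.tau_ref]).phi[0]
        expect = ref_small.histogram / ref_small.histogram.sum()
        np.testing.assert_allclose(phi, expect, rtol=0, atol=1e-15)

    def test_impulse_reference_gives_exponential_tail(self, axis_small):
        # delta-response limit: geometric decay channel to channel
        hist = np.zeros(axis_small.n_channels)
        hist[0] = 1.0
        ref = ReferenceDecay(hist, tau_ref=1e-3, time_axis=axis_small)
        tau = 2000.0
        phi = build_kernels(ref, [tau]).phi[0]
        ratio = phi[2:40] / phi[1:39]
        np.testing.assert_allclose(
            ratio, np.exp(-axis_small.channel_width / tau), rtol=1e-9
        )
        assert (phi >= 0).all()

    @pytest.mark.parametrize("tau", [500.0, 2490.0, 3700.0])
    def test_matches_oversampled_convolution_oracle(self, ref_small, tau):
        phi = build_kernels(ref_small, [tau]).phi[0]
        expect = oracle_kernel(ref_small, tau)
        mask = expect > 1e-12 * expect.max()
        rel = np.abs(phi[mask] - expect[mask]) / expect[mask]
        assert rel.max() < 1e-4

    @given(
        taus=st.lists(
            st.floats(min_value=90.0, max_value=8000.0), min_size=1, max_size=4
        )
    )
    @settings(max_examples=30, deadline=None)
    def test_rows_sum_to_one(self, taus):
        axis = TimeAxis(128, 48.8)
        # cheap deterministic reference shaped like a response + tail
        t = axis.centers
        hist = np.exp(-0.5 * ((t - 800.0) / 90.0) ** 2) + 1e-6
        ref = ReferenceDecay(hist, 86.0, axis)
        kern = build_kernels(ref, taus)
        np.testing.assert_allclose(kern.phi.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_inputs_rejected(self, ref_small, axis_small):
        with pytest.raises(DomainError):
            build_kernels(ref_small, [-1.0])
        with pytest.raises(DomainError):
            ReferenceDecay(
                np.zeros(axis_small.n_channels), 86.0, axis_small
            )

    def test_hdf5_round_trip(self, ref_small, tmp_path):
        kern = build_kernels(ref_small, [500.0, 3700.0])
        path = tmp_path / "k.h5"
        kern.save_hdf5(path)
        back = Kernels.load_hdf5(path)
        np.testing.assert_array_equal(back.phi, kern.phi)
        np.testing.assert_array_equal(back.taus, kern.taus)
        assert back.time_axis == kern.time_axis


class TestExpectedCounts:
    def test_single_component_scales_kernel(self, ref_small):
        kern = build_kernels(ref_small, [1500.0])
        m = expected_counts(kern, [250.0])
        np.testing.assert_allclose(m, 250.0 * kern.phi[0])
        np.testing.assert_allclose(m.sum(), 250.0, rtol=1e-12)

    def test_equal_lifetimes_merge(self, ref_small):
        kern2 = build_kernels(ref_small, [900.0, 900.0])
        kern1 = build_kernels(ref_small, [900.0])
        np.testing.assert_allclose(
            expected_counts(kern2, [30.0, 70.0]),
            expected_counts(kern1, [100.0]),
            rtol=1e-12,
        )

    @given(
        alpha=st.lists(
            st.floats(min_value=0.0, max_value=1e4), min_size=2, max_size=4
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_conserves_photons(self, ref_small, alpha):
        taus = np.geomspace(200.0, 4000.0, len(alpha))
        kern = build_kernels(ref_small, taus)
        m = expected_counts(kern, np.asarray(alpha))
        np.testing.assert_allclose(
            m.sum(), np.sum(alpha), rtol=1e-9, atol=1e-9
        )

    def test_rising_edge_combination_is_valid(self, ref_small):
        # acceptor channel fed by transfer: molecule fractions (-33, 67)
        # on (0.44, 2.49) ns; converted to area amplitudes the mixture
        # rises and decays but never goes negative
        taus = np.array([440.0, 2490.0])
        a = amplitude_fractions_from_preexp([-0.33, 0.67], taus)
        kern = build_kernels(ref_small, taus)
        m = expected_counts(kern, 500.0 * a / a.sum())
        assert (m >= 0).all()
        np.testing.assert_allclose(m.sum(), 500.0, rtol=1e-9)

    def test_unphysical_combination_rejected(self, ref_small):
        kern = build_kernels(ref_small, [440.0, 2490.0])
        with pytest.raises(ModelValidityError):
            expected_counts(kern, np.array([-330.0, 670.0]))


class TestAmplitudeAlgebra:
    def test_normalized_amplitudes_examples(self):
        np.testing.assert_allclose(
            normalized_amplitudes([100.0, 900.0]), [0.10, 0.90]
        )
        np.testing.assert_allclose(
            normalized_amplitudes([-330.0, 670.0]), [-0.33, 0.67]
        )
        np.testing.assert_allclose(normalized_amplitudes([0.0, 5.0]), [0.0, 1.0])
        with pytest.raises(DomainError):
            normalized_amplitudes([0.0, 0.0])

    def test_single_component_fraction_is_one(self):
        np.testing.assert_allclose(
            pre_exponential_fractions([123.0], [800.0]), [1.0]
        )

    @given(
        p=st.lists(
            st.floats(min_value=-1.0, max_value=1.0).filter(
                lambda v: abs(v) > 1e-3
            ),
            min_size=2,
            max_size=4,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_preexp_amplitude_round_trip(self, p):
        taus = np.geomspace(150.0, 5000.0, len(p))
        p = np.asarray(p) / np.abs(p).sum()
        a = amplitude_fractions_from_preexp(p, taus)
        back = pre_exponential_fractions(a, taus)
        np.testing.assert_allclose(back, p, atol=1e-12)
        assert abs(np.abs(a).sum() - 1.0) < 1e-12

    def test_average_lifetime_examples(self):
        assert average_lifetime([1.0], [3.7]) == pytest.approx(3.7)
        assert average_lifetime([0.10, 0.90], [0.5, 3.7]) == pytest.approx(3.38)
        assert average_lifetime([0.5, 0.5], [1.0, 1.0]) == pytest.approx(1.0)
        assert np.isnan(average_lifetime([0.5, -0.5], [1.0, 2.0]))

    def test_mean_lifetime_on_reference_parameter_sets(self):
        # donor in presence of the acceptor: 1.32 ns
        assert mean_lifetime(
            [0.42, 0.41, 0.17], [0.44, 1.64, 2.71]
        ) == pytest.approx(1.3179, abs=1e-4)
        # donor alone: 2.00 ns from the rounded printed fractions
        assert mean_lifetime(
            [0.17, 0.28, 0.55], [0.18, 1.72, 2.71]
        ) == pytest.approx(2.0027, abs=1e-4)
        assert mean_lifetime([1.0], [2.3]) == pytest.approx(2.3)

    @given(
        a=st.lists(
            st.floats(min_value=1e-3, max_value=1.0), min_size=2, max_size=4
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_mean_never_exceeds_average_for_positive_fractions(self, a):
        taus = np.geomspace(200.0, 4000.0, len(a))
        a = np.asarray(a) / np.sum(a)
        p = pre_exponential_fractions(a, taus)
        assert mean_lifetime(p, taus) <= average_lifetime(a, taus) + 1e-12
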