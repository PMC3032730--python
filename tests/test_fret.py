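import numpy as np
import pytest

from mpflim import (
    ComponentSpec,
    ModelSpec,
    PipelineConfig,
    apparent_efficiency,
    corrected_mean_lifetime,
    donor_acceptor_distance,
    fret_from_fractions,
    fret_report,
    real_efficiency,
    run_pipeline,
)
from mpflim.decay_model import DomainError
from mpflim.fret import efficiency_from_quenched_lifetime
from mpflim.segmentation import intensity_image
from mpflim.simulator import preset_scene, simulate_decay_cube

# donor-alone reference: lifetimes (ns) and molecule fractions, with the
# fast auto-fluorescence term first
DONOR_REF_TAUS = (0.18, 1.72, 2.71)
DONOR_REF_P = (0.17, 0.28, 0.55)
# donor quenched by the acceptor
DONOR_TAUS = (0.44, 1.64, 2.71)
DONOR_P = (0.42, 0.41, 0.17)


class TestEfficiencyArithmetic:
    def test_apparent_efficiency_limits_and_value(self):
        assert apparent_efficiency(2.0, 2.0) == 0.0
        assert apparent_efficiency(1.32, 2.01) == pytest.approx(0.343, abs=5e-4)
        assert apparent_efficiency(1e-9, 2.0) == pytest.approx(1.0)
        with pytest.raises(DomainError):
            apparent_efficiency(3.0, 2.0)

    def test_real_efficiency_from_active_fraction(self):
        assert real_efficiency(0.25, 1.0) == 0.25
        assert real_efficiency(0.343, 0.42) == pytest.approx(0.817, abs=1e-3)
        assert real_efficiency(0.0, 0.5) == 0.0
        with pytest.raises(DomainError):
            real_efficiency(0.6, 0.5)

    def test_distance_definition_and_monotonicity(self):
        assert donor_acceptor_distance(0.5, 5.8) == pytest.approx(5.8)
        e = np.linspace(0.05, 0.95, 19)
        r = [donor_acceptor_distance(x, 5.8) for x in e]
        assert all(a > b for a, b in zip(r, r[1:]))
        with pytest.raises(DomainError):
            donor_acceptor_distance(1.0, 5.8)

    def test_efficiency_distance_round_trip(self):
        for e in (0.1, 0.5, 0.81, 0.97):
            r = donor_acceptor_distance(e, 5.8)
            back = 1.0 / (1.0 + (r / 5.8) ** 6)
            assert back == pytest.approx(e, abs=1e-12)

    def test_corrected_mean_lifetime_strips_autofluorescence(self):
        tau = corrected_mean_lifetime(DONOR_REF_P, DONOR_REF_TAUS, drop=0)
        assert tau == pytest.approx(2.376, abs=2e-3)
        # dropping nothing reproduces the plain mean lifetime
        assert corrected_mean_lifetime(
            DONOR_REF_P, DONOR_REF_TAUS, drop=[]
        ) == pytest.approx(2.0027, abs=1e-3)


class TestFretFromFractions:
    def test_construct_reference_numbers(self):
        fp = fret_from_fractions(
            donor_taus=DONOR_TAUS,
            donor_preexp=DONOR_P,
            donor_ref_taus=DONOR_REF_TAUS,
            donor_ref_preexp=DONOR_REF_P,
            fret_component=0,
            autofluorescence_component=0,
            r0_nm=5.8,
        )
        assert fp.tau_da == pytest.approx(1.318, abs=2e-3)
        assert fp.tau_d == pytest.approx(2.003, abs=2e-3)
        assert fp.tau_d_corrected == pytest.approx(2.376, abs=2e-3)
        assert fp.fret_fraction == pytest.approx(0.42)
        assert fp.e_real == pytest.approx(0.81, abs=0.01)
        assert fp.distance_nm == pytest.approx(4.5, abs=0.1)

    def test_two_efficiency_routes_agree_on_exact_fractions(self):
        fp = fret_from_fractions(
            donor_taus=DONOR_TAUS,
            donor_preexp=DONOR_P,
            donor_ref_taus=DONOR_REF_TAUS,
            donor_ref_preexp=DONOR_REF_P,
        )
        via_fraction = real_efficiency(fp.e_app, fp.fret_fraction)
        assert via_fraction == pytest.approx(fp.e_real, rel=0.01)

    def test_quenched_lifetime_route(self):
        assert efficiency_from_quenched_lifetime(0.44, 2.376) == pytest.approx(
            0.8148, abs=1e-3
        )


@pytest.fixture(scope="module")
def fret_result(ref_default):
    cfg = preset_scene("fret_construct", seed=8, shape=(32, 32), photons_per_pixel=500)
    cube, _ = simulate_decay_cube(cfg)
    model = ModelSpec(
        {
            "473GFP": [
                ComponentSpec(tau=440.0, link_key="fret"),
                ComponentSpec(tau=1640.0),
                ComponentSpec(tau=2710.0),
            ],
            "473RFP": [
                ComponentSpec(tau=440.0, link_key="fret", sign="free"),
                ComponentSpec(tau=2490.0),
            ],
            "532RFP": [
                ComponentSpec(tau=440.0, link_key="fret"),
                ComponentSpec(tau=100.0),
                ComponentSpec(tau=970.0),
                ComponentSpec(tau=2280.0),
            ],
        }
    )
    result = run_pipeline(
        cube,
        PipelineConfig(model, ref_default, threshold=30, fix_lifetimes=True),
    )
    empty = intensity_image(cube, "532GFP")
    return result, model, empty


class TestFretReportOnSimulations:
    def test_all_four_evidence_conditions_on_construct(self, fret_result):
        result, model, empty = fret_result
        report = fret_report(
            result,
            model,
            r0_nm=5.8,
            donor_ref_taus=(180.0, 1720.0, 2710.0),
            donor_ref_preexp=DONOR_REF_P,
            empty_channel_counts=empty,
        )
        assert report.evidence == {"a": True, "b": True, "c": True, "d": True}
        assert report.fret_detected

    def test_derived_quantities_near_truth(self, fret_result):
        result, model, empty = fret_result
        report = fret_report(
            result,
            model,
            r0_nm=5.8,
            donor_ref_taus=(180.0, 1720.0, 2710.0),
            donor_ref_preexp=DONOR_REF_P,
            empty_channel_counts=empty,
        )
        fp = report.params
        assert fp is not None
        assert fp.fret_fraction == pytest.approx(0.42, abs=0.03)
        assert fp.e_real == pytest.approx(0.8148, abs=0.01)
        assert fp.distance_nm == pytest.approx(4.53, abs=0.1)

    def test_donor_only_flags_no_fret(self, ref_default):
        cfg = preset_scene("donor_only", seed=9, shape=(24, 24), photons_per_pixel=400)
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
        report = fret_report(result, model)
        assert not report.evidence["a"]
        assert not report.fret_detected
        assert any("no FRET" in n for n in report.notes)
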