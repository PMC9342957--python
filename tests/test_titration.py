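"""Fluorescence titration normalisation, saturation fits, and probe readouts."""

import numpy as np
import pytest

from pepmem.errors import ConfigError, DataError
from pepmem.synthetic import SyntheticTruth, make_excitation_scan, make_titration_trace
from pepmem.titration import (
    SaturationModel,
    TitrationTrace,
    anepps_ratio,
    hydration_radius,
    normalize_trace,
    saturation_from_trace,
    tmrm_fractional_change,
)


def _trace(intensity, time=None, **kw):
    intensity = np.asarray(intensity, dtype=float)
    if time is None:
        time = np.arange(len(intensity), dtype=float)
    kw.setdefault("baseline_window", (0.0, 4.0))
    return TitrationTrace(time=time, intensity=intensity, **kw)


class TestNormalize:
    def test_constant_trace_becomes_unity(self):
        out = normalize_trace(_trace(np.full(20, 137.0)))
        assert np.allclose(out.intensity, 1.0)

    def test_plateau_arithmetic(self):
        inten = np.concatenate([np.full(5, 200.0), np.full(15, 500.0)])
        out = normalize_trace(_trace(inten))
        assert out.intensity[-1] == pytest.approx(2.5)

    def test_idempotent(self):
        inten = np.concatenate([np.full(5, 200.0), np.full(15, 500.0)])
        once = normalize_trace(_trace(inten))
        twice = normalize_trace(once)
        assert np.allclose(once.intensity, twice.intensity)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DataError):
            normalize_trace(_trace(np.zeros(20)))

    def test_fold_change_recovery_from_generator(self):
        truth = SyntheticTruth(seed=4, trace_noise_sd=0.002)
        trace = normalize_trace(make_titration_trace("surface-probe", truth))
        # oracle: the generator's own saturable response at the final dose
        total = truth.dose_per_addition_nmol * truth.n_additions
        amp = truth.ans_fold_change - 1.0
        expected = 1.0 + amp * total / (truth.half_saturation_nmol + total)
        plateau = trace.window_mean(trace.time[-1] - 10, trace.time[-1])
        assert plateau == pytest.approx(expected, abs=0.02)


class TestSaturation:
    def test_half_saturation_recovered_on_low_noise_fixture(self):
        truth = SyntheticTruth(seed=5, trace_noise_sd=0.002)
        trace = normalize_trace(make_titration_trace("surface-probe", truth))
        curve = saturation_from_trace(trace)
        assert curve.identifiable
        assert curve.half_saturation == pytest.approx(20.0, rel=0.10)

    def test_doubling_doses_doubles_half_saturation(self):
        d = np.array([10.0, 20.0, 40.0, 80.0, 160.0])
        r = 2.0 * d / (25.0 + d)
        fit1 = SaturationModel(d, r).fit()
        fit2 = SaturationModel(2 * d, r).fit()
        assert fit2.half_saturation == pytest.approx(2 * fit1.half_saturation, rel=1e-6)
        assert fit1.half_saturation == pytest.approx(25.0, rel=1e-6)

    def test_flat_response_flagged_unidentifiable(self):
        truth = SyntheticTruth(seed=6, ans_fold_change=1.0, trace_noise_sd=0.0)
        trace = normalize_trace(make_titration_trace("surface-probe", truth))
        assert np.allclose(trace.intensity, 1.0)
        curve = saturation_from_trace(trace)
        assert not curve.identifiable

    def test_plateaus_invariant_to_uniform_rescaling(self):
        truth = SyntheticTruth(seed=7, trace_noise_sd=0.0)
        raw = make_titration_trace("surface-probe", truth)
        scaled = TitrationTrace(
            time=raw.time, intensity=raw.intensity * 7.3,
            events=raw.events, baseline_window=raw.baseline_window,
        )
        c1 = saturation_from_trace(normalize_trace(raw))
        c2 = saturation_from_trace(normalize_trace(scaled))
        assert np.allclose(c1.response, c2.response, atol=1e-12)

    def test_needs_two_additions(self):
        trace = _trace(np.ones(50), events=[(10.0, "peptide", 10.0)])
        with pytest.raises(DataError):
            saturation_from_trace(trace)


class TestProbeReadouts:
    def test_anepps_equal_intensities_give_unity(self):
        wl = np.arange(380.0, 581.0)
        inten = np.full_like(wl, 300.0)
        assert anepps_ratio(wl, inten) == pytest.approx(1.0)

    def test_anepps_ratio_arithmetic(self):
        wl = np.arange(380.0, 581.0)
        inten = np.where(np.abs(wl - 420) <= 2, 300.0, 0.0) + np.where(
            np.abs(wl - 520) <= 2, 400.0, 0.0
        )
        assert anepps_ratio(wl, inten) == pytest.approx(0.75)

    def test_anepps_monotone_decrease_over_titration(self):
        truth = SyntheticTruth(seed=8)
        r_truth = [0.9, 0.8, 0.72, 0.66]
        measured = []
        for k, r in enumerate(r_truth):
            wl, inten = make_excitation_scan(r, truth, index=k, noise_sd=0.002)
            measured.append(anepps_ratio(wl, inten))
        assert all(a > b for a, b in zip(measured, measured[1:]))
        assert np.allclose(measured, r_truth, rtol=0.02)

    def test_anepps_scan_coverage_required(self):
        with pytest.raises(DataError):
            anepps_ratio(np.arange(430.0, 581.0), np.ones(151))

    def test_tmrm_no_quench_gives_zero(self):
        trace = normalize_trace(_trace(np.full(100, 250.0), baseline_window=(0, 10)))
        assert tmrm_fractional_change(trace, (50, 90)) == pytest.approx(0.0)

    def test_tmrm_arithmetic(self):
        inten = np.concatenate([np.full(20, 1.0), np.full(80, 0.6)])
        trace = _trace(inten, baseline_window=(0, 19))
        assert tmrm_fractional_change(trace, (30, 90)) == pytest.approx(-0.4)

    def test_tmrm_generator_truth_recovered(self):
        truth = SyntheticTruth(seed=9, trace_noise_sd=0.002)
        trace = normalize_trace(make_titration_trace("transmembrane", truth))
        out = tmrm_fractional_change(trace, (70.0, 170.0))
        assert out == pytest.approx(-0.35, abs=0.01)


class TestHydrationRadius:
    def test_reference_identity(self):
        assert hydration_radius(1.0, 1.0) == pytest.approx(3.34)

    def test_ratio_of_two(self):
        assert hydration_radius(2.0, 1.0) == pytest.approx(6.68)

    def test_monomer_radius_from_inverted_ratio(self):
        # the printed 5.3 Å analyte radius implies D_ref/D_analyte ≈ 1.587
        ratio = 5.3 / 3.34
        assert hydration_radius(ratio, 1.0) == pytest.approx(5.3, abs=1e-9)

    def test_homogeneity_degrees(self):
        base = hydration_radius(1.3, 0.7, 3.34)
        assert hydration_radius(1.3, 0.7, 2 * 3.34) == pytest.approx(2 * base)
        assert hydration_radius(1.3, 2 * 0.7, 3.34) == pytest.approx(base / 2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigError):
            hydration_radius(0.0, 1.0)


def test_unknown_trace_kind_rejected():
    with pytest.raises(ConfigError):
        make_titration_trace("voltage-clamp", SyntheticTruth(seed=0))
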