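"""NOE ensemble/time-averaging against independent brute-force arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pepmem.errors import ConfigError, DataError
from pepmem.noe import (
    DistanceSeries,
    NOERestraint,
    compliance_report,
    ensemble_avg_distance,
    filter_long_range,
    time_avg_distance,
    violation_fraction,
)


def brute_force_rstar(distances):
    """Loop-based r⁻⁶ ensemble average, independent of the vectorised path."""
    n_chains, n_frames = len(distances), len(distances[0])
    out = []
    for t in range(n_frames):
        acc = 0.0
        for i in range(n_chains):
            acc += math.pow(distances[i][t], -6.0)
        out.append(math.pow(acc / n_chains, -1.0 / 6.0))
    return out


def brute_force_rbar(rstar, tau, dt):
    """Loop-based r⁻³ forward-window average with terminal renormalisation."""
    w = int(round(tau / dt))
    n = len(rstar)
    out = []
    for t in range(n):
        stop = min(t + w + 1, n)
        acc = sum(math.pow(rstar[j], -3.0) for j in range(t, stop))
        out.append(math.pow(acc / (stop - t), -1.0 / 3.0))
    return out


def _restraint(ub=4.0, sep=2):
    return NOERestraint(1, "HA", 1 + sep, "HN", ub)


class TestEnsembleAverage:
    def test_constant_ensemble_is_identity(self):
        d = np.full((20, 7), 4.0)
        assert np.allclose(ensemble_avg_distance(d), 4.0)

    def test_two_populations_match_direct_evaluation(self):
        d = np.concatenate([np.full((10, 1), 3.0), np.full((10, 1), 6.0)])
        expected = (0.5 * (3.0 ** -6 + 6.0 ** -6)) ** (-1 / 6)
        r = ensemble_avg_distance(d)
        assert r[0] == pytest.approx(expected, abs=1e-12)
        assert r[0] == pytest.approx(3.36, abs=0.005)

    def test_single_chain_passthrough(self):
        d = np.array([[3.1, 4.2, 5.3]])
        assert np.allclose(ensemble_avg_distance(d), d[0])

    def test_rejects_nonpositive_distances(self):
        with pytest.raises(DataError):
            ensemble_avg_distance(np.array([[1.0, -2.0]]))

    @given(
        st.lists(
            st.lists(st.floats(1.0, 10.0), min_size=5, max_size=5),
            min_size=2, max_size=6,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_bounded_by_ensemble_min_max(self, rows):
        d = np.asarray(rows)
        r = ensemble_avg_distance(d)
        assert np.all(r >= d.min(axis=0) - 1e-9)
        assert np.all(r <= d.max(axis=0) + 1e-9)

    def test_increasing_one_distance_never_decreases_rstar(self, rng):
        d = rng.uniform(2.0, 8.0, size=(5, 20))
        base = ensemble_avg_distance(d)
        d2 = d.copy()
        d2[2, 7] += 1.5
        bumped = ensemble_avg_distance(d2)
        assert np.all(bumped >= base - 1e-12)


class TestTimeAverage:
    def test_constant_series_is_fixed_point(self):
        x = np.full(50, 4.5)
        assert np.allclose(time_avg_distance(x, 10.0, 1.0), 4.5)

    def test_alternating_window_matches_closed_form(self):
        # equal counts of 3 and 6 in the window -> (0.5(3^-3 + 6^-3))^(-1/3)
        x = np.tile([3.0, 6.0], 10)
        out = time_avg_distance(x, 1.0, 1.0)  # 2-sample windows
        expected = (0.5 * (3.0 ** -3 + 6.0 ** -3)) ** (-1 / 3)
        assert expected == pytest.approx(48 ** (1 / 3), abs=1e-12)
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_tau_equals_zero_window_unsupported_but_dt_window_degenerate(self):
        # tau = dt gives 2-sample windows; a strictly degenerate identity
        # needs a 1-sample window, which the formula reaches only at the
        # terminal frame
        x = np.array([3.0, 4.0, 5.0])
        out = time_avg_distance(x, 1.0, 1.0)
        assert out[-1] == pytest.approx(5.0)

    def test_rejects_non_integer_window(self):
        with pytest.raises(ConfigError):
            time_avg_distance(np.ones(10), 2.5, 1.0)
        with pytest.raises(ConfigError):
            time_avg_distance(np.ones(10), 0.5, 1.0)

    def test_matches_brute_force_on_random_series(self, rng):
        x = rng.uniform(2.0, 8.0, size=200)
        out = time_avg_distance(x, 10.0, 1.0)
        assert np.allclose(out, brute_force_rbar(list(x), 10.0, 1.0), atol=1e-10)

    def test_constant_over_time_reduces_to_ensemble_average(self, rng):
        # Eq-style composition: chains differ, frames constant
        per_chain = rng.uniform(2.0, 8.0, size=12)
        d = np.tile(per_chain[:, None], (1, 60))
        rstar = ensemble_avg_distance(d)
        rbar = time_avg_distance(rstar, 10.0, 1.0)
        assert np.allclose(rbar, rstar[0], atol=1e-12)


class TestViolations:
    def test_no_violations_below_bound(self):
        assert violation_fraction(np.full(20, 3.5), _restraint(4.0)) == 0.0

    def test_tolerance_buffer_rule(self):
        r = _restraint(4.0)
        assert violation_fraction(np.array([4.25]), r, 0.3) == 0.0
        assert violation_fraction(np.array([4.35]), r, 0.3) == 1.0

    def test_infinite_tolerance_kills_all_violations(self):
        assert violation_fraction(np.full(5, 99.0), _restraint(4.0), np.inf) == 0.0

    def test_monotone_in_tolerance(self, rng):
        x = rng.uniform(3.0, 6.0, size=100)
        r = _restraint(4.0)
        fracs = [violation_fraction(x, r, tol) for tol in (0.0, 0.3, 1.0, 2.5)]
        assert fracs == sorted(fracs, reverse=True)

    def test_empty_series_rejected(self):
        with pytest.raises(DataError):
            violation_fraction(np.array([]), _restraint())


class TestFilterAndReport:
    def test_filter_keeps_only_i2_i3(self):
        pairs = [(1, 2), (1, 3), (1, 4), (2, 3)]
        restraints = [NOERestraint(i, "HA", j, "HN", 5.0) for i, j in pairs]
        kept = filter_long_range(restraints)
        assert [(r.residue_i, r.residue_j) for r in kept] == [(1, 3), (1, 4)]

    def test_filter_empty_and_all_sequential(self):
        assert filter_long_range([]) == []
        seq = [NOERestraint(i, "HA", i + 1, "HN", 5.0) for i in range(1, 4)]
        assert filter_long_range(seq) == []

    def test_restraint_class_and_ordering_validation(self):
        assert _restraint(sep=2).restraint_class == "i+2"
        assert _restraint(sep=3).restraint_class == "i+3"
        assert _restraint(sep=1).restraint_class == "sequential"
        with pytest.raises(DataError):
            NOERestraint(3, "HA", 1, "HN", 4.0)
        with pytest.raises(DataError):
            NOERestraint(1, "HA", 3, "HN", -1.0)

    def test_all_satisfied_gives_full_compliance(self):
        series = [
            DistanceSeries(_restraint(4.0), np.full((3, 50), 3.0)),
            DistanceSeries(_restraint(5.0, sep=3), np.full((3, 50), 4.0)),
        ]
        report = compliance_report(series)
        assert (report.table["violation_fraction"] == 0.0).all()
        assert report.share_compliant == 1.0

    def test_mixed_dt_rejected(self):
        series = [
            DistanceSeries(_restraint(4.0), np.full((2, 30), 3.0), dt=1.0),
            DistanceSeries(_restraint(5.0, sep=3), np.full((2, 30), 3.0), dt=2.0),
        ]
        with pytest.raises(DataError):
            compliance_report(series)
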