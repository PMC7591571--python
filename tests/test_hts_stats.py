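import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import jhtriage as j
from jhtriage.hts_stats import (
    DegenerateSeparationError,
    InsufficientControlsError,
)


def summary(mean_p=100.0, mean_n=1100.0, sd_p=0.0, sd_n=0.0, channel="fluc"):
    return j.ControlSummary(channel, mean_p, mean_n, sd_p, sd_n, 16, 16)


class TestSummarizeControls:
    def test_hand_values(self, control_plate_factory, layout96):
        plate = control_plate_factory([90, 110], [1000, 1200])
        s = j.summarize_controls(plate, layout96, "fluc")
        assert s.mean_p == 100 and s.mean_n == 1100
        assert s.sd_p == pytest.approx(14.142135, abs=1e-5)
        assert s.sd_n == pytest.approx(141.42135, abs=1e-4)

    def test_identical_controls_zero_sd(self, control_plate_factory, layout96):
        plate = control_plate_factory([100] * 16, [1100] * 16)
        s = j.summarize_controls(plate, layout96, "fluc")
        assert (s.mean_p, s.sd_p, s.mean_n, s.sd_n) == (100, 0, 1100, 0)

    def test_single_control_errors(self, control_plate_factory, layout96):
        plate = control_plate_factory([100], [1000, 1200])
        with pytest.raises(InsufficientControlsError):
            j.summarize_controls(plate, layout96, "fluc")


class TestInhibitionRate:
    def test_endpoints_exact(self):
        s = summary()
        assert j.inhibition_rate(s.mean_n, s) == 0.0
        assert j.inhibition_rate(s.mean_p, s) == 100.0

    def test_midpoint(self):
        s = summary(mean_p=150.0, mean_n=2150.0)
        assert j.inhibition_rate(1150.0, s) == pytest.approx(50.0)

    def test_activation_is_negative(self):
        s = summary()
        assert j.inhibition_rate(s.mean_n + 500, s) < 0

    def test_degenerate_separation(self):
        with pytest.raises(DegenerateSeparationError):
            j.inhibition_rate(100.0, summary(mean_p=500.0, mean_n=500.0))


class TestZPrime:
    def test_hand_value(self):
        assert j.z_prime(summary(100, 1100, 10, 20)) == pytest.approx(0.91)

    def test_zero_variance_is_one(self):
        assert j.z_prime(summary()) == 1.0

    def test_negative_when_noise_swamps_separation(self):
        assert j.z_prime(summary(100, 1100, 150, 250)) < 0

    def test_strictly_decreasing_in_sds(self):
        base = j.z_prime(summary(100, 1100, 10, 20))
        assert j.z_prime(summary(100, 1100, 15, 20)) < base
        assert j.z_prime(summary(100, 1100, 10, 30)) < base

    def test_inverted_controls_warns_and_uses_abs(self):
        with pytest.warns(UserWarning, match="mean_n < mean_p"):
            z = j.z_prime(summary(mean_p=1100.0, mean_n=100.0, sd_p=10.0, sd_n=20.0))
        assert z == pytest.approx(0.91)


def test_plate_inhibition_matches_brute_force(layout96, rng):
    """plate_inhibition must equal a direct well-by-well application of the
    normalization formula using this plate's own control statistics."""
    from conftest import make_control_plate

    for trial in range(20):
        pos = rng.uniform(50, 200, 8)
        neg = rng.uniform(800, 2000, 8)
        compounds = [(f"C{i}", rng.uniform(0, 2500)) for i in range(30)]
        plate = make_control_plate(pos, neg, compounds, plate_id=f"BF{trial}")
        results = {r.compound_id: r for r in j.plate_inhibition(plate, layout96, "fluc")}
        mean_p, mean_n = np.mean(pos), np.mean(neg)
        for cid, v in compounds:
            expected = 100.0 * (1.0 - (v - mean_p) / (mean_n - mean_p))
            assert results[cid].values[0] == pytest.approx(expected, rel=1e-12)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    a=st.floats(min_value=0.05, max_value=50.0),
    b=st.floats(min_value=-500.0, max_value=500.0),
)
def test_affine_invariance(a, b):
    """InH and Z' are unchanged when every luminescence value on the plate
    is transformed y -> a*y + b (a > 0)."""
    from conftest import make_control_plate

    rng = np.random.default_rng(7)
    pos = rng.uniform(50, 200, 8)
    neg = rng.uniform(800, 2000, 8)
    compounds = [(f"C{i}", rng.uniform(0, 2500)) for i in range(10)]
    layout = j.build_default_layout(96)
    base = make_control_plate(pos, neg, compounds)
    shift = max(0.0, -(a * 0 + b))  # keep RLU non-negative
    trans = make_control_plate(
        a * pos + b + shift, a * neg + b + shift,
        [(cid, a * v + b + shift) for cid, v in compounds],
    )
    inh0 = {r.compound_id: r.mean for r in j.plate_inhibition(base, layout)}
    inh1 = {r.compound_id: r.mean for r in j.plate_inhibition(trans, layout)}
    for cid in inh0:
        assert inh1[cid] == pytest.approx(inh0[cid], rel=1e-9, abs=1e-9)
    z0 = j.z_prime(j.summarize_controls(base, layout, "fluc"))
    z1 = j.z_prime(j.summarize_controls(trans, layout, "fluc"))
    assert z1 == pytest.approx(z0, rel=1e-9)


def test_per_plate_normalization(control_plate_factory, layout96):
    """The same raw RLU scores differently on plates with different controls."""
    p1 = control_plate_factory([100] * 8, [1100] * 8, [("C1", 600)], plate_id="A")
    p2 = control_plate_factory([200] * 8, [2200] * 8, [("C1", 600)], plate_id="B")
    (r1,) = j.plate_inhibition(p1, layout96)
    (r2,) = j.plate_inhibition(p2, layout96)
    assert r1.mean != r2.mean


class TestAggregateReplicates:
    def test_hand_values(self):
        s = j.aggregate_replicates([20, 22, 18, 20], 4)
        assert s.mean == 20 and s.sd == pytest.approx(1.63299, abs=1e-5)
        assert s.n == 4 and not s.shortfall

    def test_single_value_shortfall(self):
        s = j.aggregate_replicates([35.0], 4)
        assert s.mean == 35.0 and s.sd is None and s.shortfall

    def test_identical_values(self):
        assert j.aggregate_replicates([5.0] * 4, 4).sd == 0.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            j.aggregate_replicates([], 4)


class TestViabilityInhibition:
    def test_control_level_is_zero(self):
        assert j.viability_inhibition(1000.0, 1000.0) == 0.0

    def test_half_signal_is_fifty(self):
        assert j.viability_inhibition(500.0, 1000.0) == 50.0

    def test_nonpositive_reference(self):
        with pytest.raises(DegenerateSeparationError):
            j.viability_inhibition(500.0, 0.0)
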