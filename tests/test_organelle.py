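"""Decision rules: MPT calling, swelling, polarization, ETC response."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitoquant.images import ImageBundle
from mitoquant.organelle import (
    TransmittanceSeries,
    call_mpt,
    call_swelling,
    classify_polarization,
    compute_transmittance,
    etc_response,
    mpt_fraction,
    polarized_fraction,
)
from mitoquant.segmentation import IntensityTrace, roi_from_disk


def _trace(values):
    values = np.asarray(values, dtype=float)
    return IntensityTrace(
        timepoints_min=np.arange(len(values)) * 2.0, values=values, roi_id="t"
    )


def brute_force_mpt(values, threshold=0.20, relative_to="initial"):
    """Exhaustive per-interval scan, written independently of the caller."""
    values = list(values)
    f0 = values[0]
    for t in range(len(values) - 1):
        ref = f0 if relative_to == "initial" else values[t]
        if values[t] - values[t + 1] > threshold * ref:
            return True
    return False


class TestCallMpt:
    def test_constant_trace_is_negative(self):
        call = call_mpt(_trace([100.0] * 11))
        assert not call.underwent_mpt
        assert call.event_interval is None

    def test_single_interval_drop_beyond_20_percent_is_positive(self):
        call = call_mpt(_trace([100, 100, 75, 74, 74, 74, 74, 74, 74, 74, 74]))
        assert call.underwent_mpt
        assert call.event_interval == (1, 2)
        assert call.drop_fraction == pytest.approx(0.25)

    def test_slow_linear_decline_is_negative_despite_30_percent_total(self):
        # 3 units per 2-min interval: no single interval exceeds 20 units
        values = np.linspace(100.0, 70.0, 11)
        assert not call_mpt(_trace(values)).underwent_mpt

    def test_nonpositive_initial_value_rejected(self):
        with pytest.raises(ValueError, match="initial"):
            call_mpt(_trace([0.0, 10.0]))

    def test_exactly_threshold_drop_is_not_an_event(self):
        # the rule requires a drop of MORE than 20%
        assert not call_mpt(_trace([100.0, 80.0, 80.0])).underwent_mpt
        assert call_mpt(_trace([100.0, 79.9, 79.9])).underwent_mpt

    def test_current_value_reference_variant(self):
        # 100 -> 90 -> 70: drop 20 of current 90 is 22% > 20%, but only
        # 20% of the initial 100
        trace = _trace([100.0, 90.0, 70.0, 70.0])
        assert not call_mpt(trace, relative_to="initial").underwent_mpt
        assert call_mpt(trace, relative_to="current").underwent_mpt

    @given(
        st.lists(st.floats(min_value=1.0, max_value=1000.0), min_size=2, max_size=15),
        st.floats(min_value=0.1, max_value=100.0),
    )
    def test_scale_invariance(self, values, scale):
        base = call_mpt(_trace(values)).underwent_mpt
        scaled = call_mpt(_trace(np.asarray(values) * scale)).underwent_mpt
        assert base == scaled

    @pytest.mark.parametrize("relative_to", ["initial", "current"])
    def test_agrees_with_brute_force_on_random_traces(self, relative_to):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(2, 12))
            values = rng.uniform(5.0, 100.0, n)
            values[0] = rng.uniform(50.0, 100.0)
            expected = brute_force_mpt(values, relative_to=relative_to)
            got = call_mpt(_trace(values), relative_to=relative_to).underwent_mpt
            assert got == expected


class TestMptFraction:
    def test_percentage_arithmetic(self):
        calls = [call_mpt(_trace([100, 10])) for _ in range(40)]
        calls += [call_mpt(_trace([100, 100])) for _ in range(10)]
        assert mpt_fraction(calls) == pytest.approx(80.0)

    def test_zero_flagged_gives_zero_percent(self):
        calls = [call_mpt(_trace([100, 100]))]
        assert mpt_fraction(calls) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mpt_fraction([])


class TestComputeTransmittance:
    def _stack(self, arr, px=0.1625):
        return ImageBundle(
            frames=arr[None, ...],
            channel="transmitted",
            timepoints_min=[0.0],
            z_positions_um=np.arange(arr.shape[0]) * 0.2,
            pixel_size_um=px,
        )

    def test_uniform_field_reads_one(self):
        stack = self._stack(np.full((5, 64, 64), 800.0))
        roi = roi_from_disk((20, 20), 5, (64, 64))
        blank = roi_from_disk((45, 45), 5, (64, 64))
        assert compute_transmittance(stack, roi, blank) == pytest.approx(1.0)

    def test_darkest_region_over_blank_ratio(self):
        arr = np.full((3, 64, 64), 100.0)
        arr[1, 15:26, 15:26] = 60.0  # in-focus dark particle core
        stack = self._stack(arr)
        roi = roi_from_disk((20, 20), 5, (64, 64))
        blank = roi_from_disk((45, 45), 5, (64, 64))
        assert compute_transmittance(stack, roi, blank) == pytest.approx(0.60)

    def test_global_illumination_scaling_cancels(self):
        arr = np.full((3, 64, 64), 100.0)
        arr[1, 15:26, 15:26] = 60.0
        roi = roi_from_disk((20, 20), 5, (64, 64))
        blank = roi_from_disk((45, 45), 5, (64, 64))
        r1 = compute_transmittance(self._stack(arr), roi, blank)
        r2 = compute_transmittance(self._stack(arr * 3.7), roi, blank)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_nonpositive_blank_rejected(self):
        arr = np.zeros((2, 32, 32))
        stack = self._stack(arr)
        roi = roi_from_disk((10, 10), 3, (32, 32))
        blank = roi_from_disk((25, 25), 3, (32, 32))
        with pytest.raises(ValueError, match="blank"):
            compute_transmittance(stack, roi, blank)


def brute_force_swelling(transmittances, threshold=0.16):
    base = transmittances[0]
    return max(abs(t - base) for t in transmittances[1:]) > threshold


class TestCallSwelling:
    def _series(self, values):
        return TransmittanceSeries(
            roi_id="s",
            timepoints_min=np.arange(len(values)) * 5.0,
            transmittance=np.asarray(values, dtype=float),
        )

    @pytest.mark.parametrize(
        "values,swollen",
        [
            ([0.60, 0.80], True),  # change 0.20 > 0.16
            ([0.60, 0.70], False),  # change 0.10
            ([0.60, 0.60], False),  # null case
            ([0.60, 0.759], False),  # just under the 0.16 threshold
            ([0.60, 0.761], True),  # just over
            ([0.80, 0.60], True),  # sign-free: decreases count too
        ],
    )
    def test_threshold_rule(self, values, swollen):
        assert call_swelling(self._series(values)).swollen is swollen

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            call_swelling(self._series([0.6]))

    def test_agrees_with_direct_arithmetic_on_random_series(self):
        rng = np.random.default_rng(9)
        for _ in range(1000):
            n = int(rng.integers(2, 6))
            values = rng.uniform(0.3, 1.0, n)
            assert call_swelling(self._series(values)).swollen == brute_force_swelling(
                values
            )


class TestClassifyPolarization:
    def test_background_level_signal_is_depolarized(self):
        call = classify_polarization(100.0, 10.0, 10.0, ratio_threshold=2.0)
        assert not call.polarized
        assert call.tmre_over_background == pytest.approx(1.0)

    def test_five_fold_signal_at_two_fold_threshold_is_polarized(self):
        assert classify_polarization(500.0, 10.0, 10.0, ratio_threshold=2.0).polarized

    def test_nonpositive_background_rejected(self):
        with pytest.raises(ValueError):
            classify_polarization(10.0, 0.0, 5.0)

    def test_fraction_requires_calls(self):
        with pytest.raises(ValueError):
            polarized_fraction([])


class TestEtcResponse:
    def test_flat_series_has_zero_increase(self):
        assert etc_response(np.full(10, 50.0)).increase == 0.0

    def test_increase_is_post_minus_pre_mean_skipping_addition_frame(self):
        series = [100.0] * 3 + [999.0] + [150.0] * 6  # frame 3 is the mixing frame
        r = etc_response(series, malate_frame=3)
        assert r.increase == pytest.approx(50.0)

    def test_normalization_to_untreated_control(self):
        series = [100.0] * 3 + [110.0] + [130.0] * 6
        r = etc_response(series, malate_frame=3, control_increase=60.0)
        assert r.normalized_increase == pytest.approx(50.0)

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError, match="control"):
            etc_response(np.arange(10.0), control_increase=0.0)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            etc_response([1.0, 2.0, 3.0], malate_frame=3)
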