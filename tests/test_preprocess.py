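"""QC rules, presence threshold, background subtraction, normalization."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epcmir import (generate_cohort, normalize_internal_controls,
                    preprocess_pipeline, presence_threshold, qc_filter,
                    table2_defaults)
from epcmir.cohort import INTERNAL_CONTROL_NAMES
from epcmir.preprocess import PreprocessError, background_subtract_and_call

from conftest import make_signal_matrix


def _matrix_with_neg(neg_values, target_values=(1000.0,), n_flags=0):
    """One-sample matrix with given negative-control spots and targets."""
    signals, roles, flags = {}, {}, {}
    for i, v in enumerate(neg_values):
        name = f"NC-{i:03d}"
        signals[name] = [v]
        roles[name] = "negative_control"
    for i, v in enumerate(target_values):
        name = f"T-{i:03d}"
        signals[name] = [v]
        roles[name] = "target"
        flags[name] = [i < n_flags]
    for name in INTERNAL_CONTROL_NAMES:
        signals[name] = [5000.0]
        roles[name] = "internal_control"
    return make_signal_matrix(signals, roles, flags)


class TestQC:
    def test_high_cv_fails_with_reason(self):
        # mean 100, sd 20 -> CV 0.20
        raw = _matrix_with_neg([80.0, 100.0, 120.0])
        rep = qc_filter(raw)
        row = rep.table.iloc[0]
        assert not row["passed"]
        assert "CV>0.15" in row["reasons"]

    def test_flag_count_fails_with_reason(self):
        raw = _matrix_with_neg([90.0, 100.0, 110.0], target_values=[1000.0] * 15, n_flags=11)
        row = qc_filter(raw).table.iloc[0]
        assert not row["passed"]
        assert "flagged>10" in row["reasons"]

    def test_thresholds_are_strict_inequalities(self):
        # CV exactly 0.15 and exactly 10 flags both pass
        raw = _matrix_with_neg([85.0, 100.0, 115.0], target_values=[1000.0] * 15, n_flags=10)
        row = qc_filter(raw).table.iloc[0]
        assert row["neg_control_cv"] == pytest.approx(0.15)
        assert row["n_flagged"] == 10
        assert row["passed"]

    def test_zero_mean_negatives_error(self):
        raw = _matrix_with_neg([0.0, 0.0, 0.0])
        with pytest.raises(PreprocessError, match="CV undefined"):
            qc_filter(raw)

    def test_invariant_to_probe_and_sample_order(self, small_cohort):
        _, _, raw = small_cohort
        rep = qc_filter(raw)
        shuffled = type(raw)(
            signals=raw.signals.iloc[::-1, ::-1], roles=raw.roles.iloc[::-1],
            flags=raw.flags.iloc[::-1, ::-1], chip_ids=raw.chip_ids.iloc[::-1])
        rep2 = qc_filter(shuffled)
        pd.testing.assert_frame_equal(rep.table.sort_index(), rep2.table.sort_index())


class TestPresenceThreshold:
    def test_identical_values_give_the_value(self):
        assert presence_threshold([100.0] * 20) == pytest.approx(100.0)

    def test_trimmed_mean_plus_two_sd(self):
        # 1..20: trim one per tail, mean 10.5, sd sqrt(28.5) -> 21.1771
        thr = presence_threshold(np.arange(1.0, 21.0))
        assert thr == pytest.approx(10.5 + 2 * np.sqrt(28.5), abs=1e-9)

    def test_single_outlier_is_trimmed_away(self):
        # 19 spots trim nothing; adding one huge spot makes m=20, so one spot
        # per tail is trimmed and the outlier itself is discarded
        base = np.arange(1.0, 20.0)
        thr0 = presence_threshold(base)
        thr1 = presence_threshold(np.append(base, 1e6))
        assert abs(thr1 - thr0) / thr0 < 0.01
        # without trimming the outlier would dominate the threshold
        naive = np.append(base, 1e6)
        assert naive.mean() + 2 * naive.std(ddof=1) > 100 * thr1

    def test_too_few_spots_error(self):
        with pytest.raises(PreprocessError, match="at least 3"):
            presence_threshold([1.0, 2.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(1.0, 1e4), min_size=5, max_size=40),
           st.floats(-0.5, 1e3), st.floats(0.1, 10.0), st.integers(0, 10))
    def test_shift_scale_and_permutation_equivariance(self, values, shift, scale, perm_seed):
        """Threshold follows affine rescaling of the spots and ignores order."""
        arr = np.asarray(values)
        thr = presence_threshold(arr)
        assert presence_threshold(arr + shift) == pytest.approx(thr + shift, rel=1e-9, abs=1e-9)
        assert presence_threshold(arr * scale) == pytest.approx(thr * scale, rel=1e-9)
        shuffled = np.random.default_rng(perm_seed).permutation(arr)
        assert presence_threshold(shuffled) == pytest.approx(thr, rel=1e-12)


class TestBackgroundSubtraction:
    def _one_sample(self, targets, flags=None):
        signals = {f"T-{i:03d}": [v] for i, v in enumerate(targets)}
        roles = {k: "target" for k in signals}
        for i, v in enumerate([95.0, 100.0, 105.0]):
            signals[f"NC-{i}"] = [v]
            roles[f"NC-{i}"] = "negative_control"
        for name in INTERNAL_CONTROL_NAMES:
            signals[name] = [5000.0]
            roles[name] = "internal_control"
        raw = make_signal_matrix(signals, roles, flags)
        return raw, background_subtract_and_call(raw, qc_filter(raw))

    def test_present_probe_log2_of_subtracted_signal(self):
        # neg mean 100; raw 1000 -> log2(900)
        _, expr = self._one_sample([1000.0, 500.0])
        assert expr.values.loc["T-000"].iloc[0] == pytest.approx(np.log2(900.0))

    def test_below_threshold_gets_floor(self):
        _, expr = self._one_sample([1000.0, 50.0])
        assert not expr.present.loc["T-001"].iloc[0]
        # floor is min over detected log2 values (incl. internal controls) - 0.1
        min_detected = min(expr.values.loc["T-000"].iloc[0],
                           expr.control_values.iloc[:, 0].min())
        assert expr.values.loc["T-001"].iloc[0] == pytest.approx(min_detected - 0.1)

    def test_negative_after_subtraction_gets_floor(self):
        # trimming drops the bright outlier spot, so the presence threshold
        # (10) sits below the untrimmed background mean (59.5): a raw signal
        # of 50 is called present but goes non-positive after subtraction
        signals = {"T-000": [1000.0], "T-001": [50.0]}
        roles = {"T-000": "target", "T-001": "target"}
        for i in range(19):
            signals[f"NC-{i:02d}"] = [10.0]
            roles[f"NC-{i:02d}"] = "negative_control"
        signals["NC-19"] = [1000.0]
        roles["NC-19"] = "negative_control"
        for name in INTERNAL_CONTROL_NAMES:
            signals[name] = [5000.0]
            roles[name] = "internal_control"
        raw = make_signal_matrix(signals, roles)
        rep = qc_filter(raw, cv_threshold=10.0)  # outlier spot inflates CV; QC not under test
        expr = background_subtract_and_call(raw, rep)
        assert expr.thresholds.iloc[0] == pytest.approx(10.0)
        assert expr.neg_means.iloc[0] == pytest.approx(59.5)
        assert expr.present.loc["T-001"].iloc[0]
        min_detected = min(np.log2(1000.0 - 59.5), expr.control_values.iloc[:, 0].min())
        assert expr.values.loc["T-001"].iloc[0] == pytest.approx(min_detected - 0.1)

    def test_flagged_spot_treated_as_undetected(self):
        _, expr = self._one_sample([1000.0, 900.0], flags={"T-001": [True]})
        assert not expr.present.loc["T-001"].iloc[0]
        min_detected = min(np.log2(900.0), expr.control_values.iloc[:, 0].min())
        assert expr.values.loc["T-001"].iloc[0] == pytest.approx(min_detected - 0.1)


class TestNormalization:
    def test_per_sample_control_means_hit_grand_mean(self, preprocessed):
        _, _, expr = preprocessed
        means = expr.control_values.mean(axis=0)
        assert np.allclose(means, means.mean(), atol=1e-9)

    def test_idempotent(self, preprocessed):
        _, _, expr = preprocessed
        again = normalize_internal_controls(expr)
        assert np.allclose(expr.values.to_numpy(), again.values.to_numpy(), atol=1e-9)

    def test_common_mode_shift_is_rejected(self, small_cohort):
        """A +1 log2 whole-array shift of one sample is removed exactly."""
        _, _, raw = small_cohort
        shifted = type(raw)(signals=raw.signals.copy(), roles=raw.roles,
                            flags=raw.flags, chip_ids=raw.chip_ids)
        s0 = shifted.signals.columns[0]
        shifted.signals[s0] = shifted.signals[s0] * 2.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, e1 = preprocess_pipeline(raw, normalization_target=10.0)
            _, e2 = preprocess_pipeline(shifted, normalization_target=10.0)
        common = [s for s in e1.values.columns if s in e2.values.columns]
        assert np.allclose(e1.values[common].to_numpy(),
                           e2.values[common].to_numpy(), atol=1e-9)

    def test_array_offsets_exactly_removed(self):
        """Generator offsets vanish after normalization to a fixed target."""
        spec = table2_defaults().with_(seed=31, n_target_probes=60, flagged_spot_rate=0.0)
        _, raw_off = generate_cohort(spec.with_(array_offset_sd=0.3))
        _, raw_flat = generate_cohort(spec.with_(array_offset_sd=0.0))
        _, e_off = preprocess_pipeline(raw_off, normalization_target=10.0)
        _, e_flat = preprocess_pipeline(raw_flat, normalization_target=10.0)
        assert list(e_off.values.columns) == list(e_flat.values.columns)
        assert np.allclose(e_off.values.to_numpy(), e_flat.values.to_numpy(), atol=1e-6)

    def test_samples_with_absent_controls_are_excluded(self):
        raw = _matrix_with_neg([95.0, 100.0, 105.0])
        expr = background_subtract_and_call(raw, qc_filter(raw))
        expr.control_present.iloc[0, 0] = False
        with pytest.raises(PreprocessError, match="no samples"):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                normalize_internal_controls(expr)
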