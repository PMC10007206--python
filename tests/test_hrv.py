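"""Per-epoch HRV features: windows, band powers, and bookkeeping."""

import numpy as np
import pytest

from jitterhrv.hrv import (
    FREQ_GRID_HZ,
    HF_BAND,
    LF_BAND,
    WindowSpec,
    compute_feature_matrix,
    compute_features,
    lomb_band_power,
    sliding_periodograms,
    window_for_epoch,
)
from jitterhrv.jitter import HBISeries, hbis_from_peaks, perturb_rpeaks
from jitterhrv.synthdata import Hypnogram, RPeakStream, ValidationError


def tachogram(n=400, rr=1.0, f=None, amp=0.05, seed=0):
    rng = np.random.default_rng(seed)
    t = np.cumsum(np.full(n, rr) + rng.normal(0, 0.002, n))
    x = np.full(n, rr) + rng.normal(0, 0.002, n)
    if f is not None:
        x = x + amp * np.sin(2 * np.pi * f * t)
    return t, x


class TestWindowForEpoch:
    def test_default_spec_matches_epoch_grid(self):
        spec = WindowSpec()
        assert spec.step_s == 30.0
        assert spec.overlap == pytest.approx(0.9)

    def test_interior_window(self):
        lo, hi, clipped = window_for_epoch(10, WindowSpec(), record_span=3000.0)
        assert (lo, hi) == (165.0, 465.0)
        assert not clipped

    def test_first_epoch_clipped(self):
        lo, hi, clipped = window_for_epoch(0, WindowSpec(), record_span=3000.0)
        assert (lo, hi) == (0.0, 165.0)
        assert clipped

    def test_width_must_be_multiple_of_step(self):
        with pytest.raises(ValidationError):
            WindowSpec(width_s=299.0)


class TestLombBandPower:
    def test_constant_series_has_no_band_power(self):
        t = np.arange(1.0, 301.0)
        x = np.full(300, 1.0)
        assert lomb_band_power(t, x, LF_BAND) == 0.0
        assert lomb_band_power(t, x, HF_BAND) == 0.0

    def test_hf_modulation_concentrates_in_hf_band(self):
        t, x = tachogram(f=0.25)
        lf = lomb_band_power(t, x, LF_BAND)
        hf = lomb_band_power(t, x, HF_BAND)
        assert hf / lf > 10

    def test_lf_modulation_concentrates_in_lf_band(self):
        t, x = tachogram(f=0.1)
        assert lomb_band_power(t, x, LF_BAND) / lomb_band_power(t, x, HF_BAND) > 10

    def test_band_partition_consistency(self):
        """Two disjoint bands recombine into their union as a grid-weighted
        mean."""
        t, x = tachogram(f=0.12, seed=3)
        union = (0.04, 0.40)
        n_lf = ((FREQ_GRID_HZ >= 0.04) & (FREQ_GRID_HZ < 0.15)).sum()
        n_hf = ((FREQ_GRID_HZ >= 0.15) & (FREQ_GRID_HZ < 0.40)).sum()
        lf = lomb_band_power(t, x, LF_BAND)
        hf = lomb_band_power(t, x, HF_BAND)
        got = lomb_band_power(t, x, union)
        assert got == pytest.approx((lf * n_lf + hf * n_hf) / (n_lf + n_hf), rel=1e-9)


class TestSlidingPeriodograms:
    def test_agrees_with_scipy_reference(self, rng):
        """The prefix-sum sliding path and the per-window scipy path are the
        same estimator."""
        t = np.cumsum(rng.uniform(0.7, 1.3, 2000))
        x = rng.normal(1.0, 0.05, 2000)
        bounds = np.array([[0, 300], [150, 460], [900, 1300], [1500, 2000]])
        power = sliding_periodograms(t, x, bounds)
        for row, (i0, i1) in zip(power, bounds):
            lf_mask = (FREQ_GRID_HZ >= LF_BAND[0]) & (FREQ_GRID_HZ < LF_BAND[1])
            ref = lomb_band_power(t[i0:i1], x[i0:i1], LF_BAND)
            assert row[lf_mask].mean() == pytest.approx(ref, abs=1e-10)

    def test_sinusoid_peak_location(self):
        """Dominant periodogram ordinate sits at the modulation frequency to
        within one grid step."""
        t, x = tachogram(n=600, f=0.25, seed=1)
        power = sliding_periodograms(t, x, np.array([[0, 600]]))[0]
        peak = FREQ_GRID_HZ[np.argmax(power)]
        assert abs(peak - 0.25) <= 0.0025 + 1e-12


class TestComputeFeatures:
    def test_constant_intervals(self):
        stream = RPeakStream(times=np.arange(0.0, 1300.0, 1.0))
        hyp = Hypnogram(labels=np.full(40, "S2"), epoch_s=30.0)
        f = compute_features(hbis_from_peaks(stream), hyp)
        valid = f[f["HR_s"].notna()]
        assert np.allclose(valid["HR_s"], 1.0)
        assert np.allclose(valid["SDNN_s"], 0.0, atol=1e-12)

    def test_one_row_per_epoch_every_level(self, feature_table, cohort):
        _, hyps, _ = cohort
        n_epochs = {h.participant_id: h.n_epochs for h in hyps}
        counts = feature_table.groupby(["participant_id", "level"]).size()
        for (pid, _), n in counts.items():
            assert n == n_epochs[pid]

    def test_level_zero_features_equal_baseline(self, cohort):
        """Zero jitter goes through the same code path and reproduces the
        baseline features bit for bit."""
        _, hyps, streams = cohort
        s, h = streams[0], hyps[0]
        base = compute_features(hbis_from_peaks(s, level=0), h)
        again = compute_features(
            hbis_from_peaks(perturb_rpeaks(s, 0.0, seed=5), level=0), h
        )
        cols = ["HR_s", "SDNN_s", "LF", "HF", "LFHF", "MedFiltLFHF"]
        np.testing.assert_array_equal(base[cols].to_numpy(), again[cols].to_numpy())

    def test_constant_lfhf_survives_median_filter(self):
        stream = RPeakStream(times=np.arange(0.0, 1300.0, 1.0))
        hyp = Hypnogram(labels=np.full(40, "S2"), epoch_s=30.0)
        f = compute_features(hbis_from_peaks(stream), hyp)
        # Constant intervals: both bands zero, LFHF undefined everywhere.
        assert f["LFHF"].isna().all()
        assert f["MedFiltLFHF"].isna().all()

    def test_empty_series_rejected(self):
        hyp = Hypnogram(labels=np.full(4, "S2"))
        with pytest.raises(ValidationError):
            compute_features(
                HBISeries(timestamps=np.array([]), intervals=np.array([])), hyp
            )

    def test_hr_least_perturbed_feature(self, feature_table):
        """Windowed means smooth jitter out: the relative change of HR between
        the top level and baseline is an order of magnitude below HF's."""
        top = feature_table["level"].max()
        base = feature_table[feature_table["level"] == 0].set_index(
            ["participant_id", "epoch_index"]
        )
        jit = feature_table[feature_table["level"] == top].set_index(
            ["participant_id", "epoch_index"]
        )
        rel = {}
        for col in ("HR_s", "HF"):
            d = (jit[col] - base[col]).abs().mean()
            rel[col] = d / base[col].abs().mean()
        assert rel["HR_s"] * 10 < rel["HF"]


def test_feature_matrix_stacks_levels(cohort):
    _, hyps, streams = cohort
    s, h = streams[0], hyps[0]
    by_level = {
        0: hbis_from_peaks(s, level=0),
        3: hbis_from_peaks(perturb_rpeaks(s, 10.0, seed=1, level=3), level=3),
    }
    fm = compute_feature_matrix(by_level, h)
    assert sorted(fm["level"].unique()) == [0, 3]
    assert len(fm) == 2 * h.n_epochs
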