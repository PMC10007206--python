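"""Per-epoch HRV features from unevenly sampled heartbeat-interval series.

Features are computed per 30-s scoring epoch from a five-minute window
centred on the epoch (90% overlap between successive windows):

* ``HR``   — mean heartbeat interval in the window (s);
* ``SDNN`` — standard deviation of the intervals (s);
* ``LF`` / ``HF`` — normalized Lomb-Scargle band power in 0.04-0.15 Hz and
  0.15-0.4 Hz; the Lomb-Scargle periodogram operates directly on the
  unevenly spaced tachogram (interval vs trailing-beat time), avoiding
  resampling;
* ``LFHF`` — ratio LF / HF;
* ``MedFiltLFHF`` — running median (5-epoch kernel) of LFHF.

Windows with too few beats are flagged invalid and excluded from
classification downstream.

Because consecutive windows share 90% of their samples, the per-epoch
periodograms are evaluated with a cumulative-sum formulation of the
floating-mean (generalized) Lomb-Scargle estimator: all window sums are
differences of whole-night prefix sums, so the trigonometric work is done
once per night instead of once per window.  ``lomb_band_power`` exposes the
equivalent single-window computation through :func:`scipy.signal.lombscargle`
and agrees with the sliding path to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import lombscargle

from .jitter import HBISeries
from .synthdata import Hypnogram, ValidationError

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)

#: Fixed periodogram abscissa: 0.005-0.5 Hz in 0.0025 Hz steps.
FREQ_GRID_HZ = np.arange(0.005, 0.5 + 1e-12, 0.0025)

FEATURE_COLUMNS = ("HR_s", "SDNN_s", "LF", "HF", "LFHF", "MedFiltLFHF")

_FREQ_CHUNK = 64


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry for per-epoch feature extraction."""

    width_s: float = 300.0
    step_s: float = 30.0
    min_beats: int = 60
    median_kernel: int = 5

    def __post_init__(self) -> None:
        if self.width_s <= 0 or self.step_s <= 0:
            raise ValidationError("width_s and step_s must be positive")
        if self.width_s % self.step_s != 0:
            raise ValidationError("width_s must be a multiple of step_s")
        if self.min_beats < 2:
            raise ValidationError("min_beats must be >= 2")

    @property
    def overlap(self) -> float:
        return 1.0 - self.step_s / self.width_s


def window_for_epoch(
    epoch_index: int, spec: WindowSpec, record_span: float
) -> tuple[float, float, bool]:
    """Half-open window centred on the epoch midpoint, clipped to the record.

    Returns ``(t_lo, t_hi, clipped)``.  The epoch grid has pitch
    ``spec.step_s``, so consecutive windows overlap by ``spec.overlap``.
    """
    mid = (epoch_index + 0.5) * spec.step_s
    lo = mid - spec.width_s / 2.0
    hi = mid + spec.width_s / 2.0
    clipped = lo < 0.0 or hi > record_span
    return max(lo, 0.0), min(hi, record_span), clipped


def lomb_band_power(
    timestamps: np.ndarray,
    intervals: np.ndarray,
    band: tuple[float, float],
    freq_grid_hz: np.ndarray = FREQ_GRID_HZ,
) -> float:
    """Mean normalized Lomb-Scargle ordinate of a tachogram window in a band.

    The interval series is mean-subtracted and the floating-mean normalized
    periodogram is evaluated on the fixed grid; band power is the mean
    ordinate over grid points in ``[band[0], band[1])``.
    """
    y = np.asarray(intervals, dtype=float)
    y = y - y.mean()
    if np.allclose(y, 0.0):
        return 0.0
    power = lombscargle(
        np.asarray(timestamps, dtype=float),
        y,
        2.0 * np.pi * freq_grid_hz,
        normalize=True,
        floating_mean=True,
    )
    in_band = (freq_grid_hz >= band[0]) & (freq_grid_hz < band[1])
    return float(np.mean(power[in_band]))


def sliding_periodograms(
    timestamps: np.ndarray,
    intervals: np.ndarray,
    bounds: np.ndarray,
    freq_grid_hz: np.ndarray = FREQ_GRID_HZ,
) -> np.ndarray:
    """Floating-mean normalized Lomb-Scargle periodograms of many windows.

    ``bounds`` is an integer array of shape (n_windows, 2); window ``w``
    covers samples ``timestamps[bounds[w, 0]:bounds[w, 1]]``.  Returns an
    (n_windows, n_freqs) power array; windows whose variance or design
    matrix is degenerate come back as NaN rows.

    All per-window sums are prefix-sum differences, so cost is one pass of
    trigonometry over the night regardless of window overlap.
    """
    t = np.asarray(timestamps, dtype=float)
    y = np.asarray(intervals, dtype=float)
    bounds = np.asarray(bounds, dtype=int)
    i0, i1 = bounds[:, 0], bounds[:, 1]
    cnt = (i1 - i0).astype(float)

    def seg(prefix: np.ndarray) -> np.ndarray:
        return prefix[i1] - prefix[i0]

    def prefix(a: np.ndarray) -> np.ndarray:
        out = np.zeros((a.shape[0] + 1,) + a.shape[1:])
        np.cumsum(a, axis=0, out=out[1:])
        return out

    sy = seg(prefix(y))
    syy = seg(prefix(y * y))
    with np.errstate(invalid="ignore", divide="ignore"):
        Y = sy / cnt
        YY = syy / cnt - Y * Y

    n_w = bounds.shape[0]
    power = np.empty((n_w, freq_grid_hz.size))
    for lo in range(0, freq_grid_hz.size, _FREQ_CHUNK):
        w = 2.0 * np.pi * freq_grid_hz[lo : lo + _FREQ_CHUNK]
        ph = np.outer(t, w)
        c = np.cos(ph)
        s = np.sin(ph)
        del ph
        yc = y[:, None] * c
        ys = y[:, None] * s
        with np.errstate(invalid="ignore", divide="ignore"):
            n = cnt[:, None]
            C = seg(prefix(c)) / n
            S = seg(prefix(s)) / n
            CC = seg(prefix(c * c)) / n - C * C
            SS = seg(prefix(s * s)) / n - S * S
            CS = seg(prefix(c * s)) / n - C * S
            YC = seg(prefix(yc)) / n - Y[:, None] * C
            YS = seg(prefix(ys)) / n - Y[:, None] * S
            D = CC * SS - CS * CS
            p = (SS * YC**2 + CC * YS**2 - 2.0 * CS * YC * YS) / (YY[:, None] * D)
        power[:, lo : lo + w.size] = p
    return power


def _window_bounds(
    timestamps: np.ndarray, n_epochs: int, spec: WindowSpec, span: float
) -> np.ndarray:
    """Sample-index bounds of each epoch's window, shape (n_epochs, 2)."""
    edges = np.empty((n_epochs, 2))
    for e in range(n_epochs):
        lo, hi, _ = window_for_epoch(e, spec, span)
        edges[e] = (lo, hi)
    return np.searchsorted(timestamps, edges).astype(int)


def compute_features(
    hbis: HBISeries,
    hyp: Hypnogram,
    spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Per-epoch HRV feature rows aligned to the hypnogram.

    Produces exactly one row per hypnogram epoch.  Rows whose window holds
    fewer than ``spec.min_beats`` intervals carry NaN features and
    ``valid == False``.
    """
    if spec is None:
        spec = WindowSpec(step_s=hyp.epoch_s)
    if hbis.intervals.size == 0:
        raise ValidationError("empty HBI series")

    n_epochs = hyp.n_epochs
    t = hbis.timestamps
    x = hbis.intervals
    bounds = _window_bounds(t, n_epochs, spec, hyp.span_s)
    cnt = bounds[:, 1] - bounds[:, 0]
    valid = cnt >= spec.min_beats

    def prefix(a):
        return np.concatenate([[0.0], np.cumsum(a)])

    sx = prefix(x)[bounds[:, 1]] - prefix(x)[bounds[:, 0]]
    sxx = prefix(x * x)[bounds[:, 1]] - prefix(x * x)[bounds[:, 0]]
    with np.errstate(invalid="ignore", divide="ignore"):
        hr = sx / cnt
        var = np.maximum(sxx - sx * sx / cnt, 0.0) / (cnt - 1)
        sdnn = np.sqrt(var)

    lf = np.full(n_epochs, np.nan)
    hf = np.full(n_epochs, np.nan)
    if valid.any():
        pgram = sliding_periodograms(t, x, bounds[valid])
        lf_mask = (FREQ_GRID_HZ >= LF_BAND[0]) & (FREQ_GRID_HZ < LF_BAND[1])
        hf_mask = (FREQ_GRID_HZ >= HF_BAND[0]) & (FREQ_GRID_HZ < HF_BAND[1])
        lf[valid] = pgram[:, lf_mask].mean(axis=1)
        hf[valid] = pgram[:, hf_mask].mean(axis=1)
        # A constant window has no variance to apportion: zero band power.
        flat = np.zeros(n_epochs, dtype=bool)
        flat[valid] = np.isnan(pgram).any(axis=1)
        lf[flat] = 0.0
        hf[flat] = 0.0

    df = pd.DataFrame(
        {
            "epoch_index": np.arange(n_epochs),
            "HR_s": np.where(valid, hr, np.nan),
            "SDNN_s": np.where(valid, sdnn, np.nan),
            "LF": lf,
            "HF": hf,
        }
    )
    ratio = df["LF"] / df["HF"]
    df["LFHF"] = ratio.where(df["HF"] > 0)
    df["MedFiltLFHF"] = (
        df["LFHF"].rolling(spec.median_kernel, center=True, min_periods=1).median()
    )
    df["valid"] = valid & df["LFHF"].notna()
    df["stage"] = hyp.labels
    df["level"] = hbis.level
    df["participant_id"] = hyp.participant_id
    return df


def compute_feature_matrix(
    hbi_by_level: dict[int, HBISeries],
    hyp: Hypnogram,
    spec: WindowSpec | None = None,
) -> pd.DataFrame:
    """Stack per-level feature tables for one participant."""
    return pd.concat(
        [compute_features(hbi_by_level[lvl], hyp, spec) for lvl in sorted(hbi_by_level)],
        ignore_index=True,
    )
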