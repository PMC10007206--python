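"""Conservative upper bound on total BCG-vs-ECG heartbeat-timing error.

The total error of a detected BCG J peak relative to the ECG R peak
decomposes as e_T = RGI + e_p (R-to-ground-truth-J interval plus the peak
detector's timing error), so by the triangle inequality

    |e_T| <= |RGI| + |e_p|.

The mean R-J offset is irrelevant — HRV features are insensitive to mean
time offsets — so |RGI| is measured per participant as the absolute
deviation of each beat's RGI from that participant's mean RGI.  Summaries
pool over beats (not participant means), and the per-beat sum projects onto
the jitter-ladder error curves by linear interpolation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthdata import ValidationError

QUANTITIES = ("|RGI|", "|ep|", "|RGI|+|ep|")
STATS = ("mean_ms", "median_ms", "min_ms", "max_ms")


def _validate_table(table: pd.DataFrame) -> None:
    required = {"participant_id", "rgi_ms", "ep_ms"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"beat-pair table missing columns: {sorted(missing)}")
    if table.empty:
        raise ValidationError("beat-pair table is empty")


def rgi_jitter(table: pd.DataFrame) -> pd.Series:
    """Per-beat |RGI|: absolute deviation from the participant's mean RGI.

    Centering is per participant, never pooled; a participant with a single
    beat has no deviation scale and is an error.
    """
    _validate_table(table)
    counts = table.groupby("participant_id")["rgi_ms"].transform("size")
    if (counts < 2).any():
        bad = table.loc[counts < 2, "participant_id"].unique()
        raise ValidationError(f"participants with < 2 beats: {list(bad)}")
    centered = table["rgi_ms"] - table.groupby("participant_id")["rgi_ms"].transform("mean")
    return centered.abs().rename("|RGI|")


def total_bound(table: pd.DataFrame) -> pd.DataFrame:
    """Mean/median/min/max (ms) of |RGI|, |ep| and their per-beat sum.

    The sum row is computed beat-wise before summarizing, so its mean equals
    the sum of the component means exactly, while its median/min/max need
    not (medians are not additive).
    """
    _validate_table(table)
    abs_rgi = rgi_jitter(table).to_numpy()
    abs_ep = table["ep_ms"].abs().to_numpy()
    per_beat = {"|RGI|": abs_rgi, "|ep|": abs_ep, "|RGI|+|ep|": abs_rgi + abs_ep}
    rows = {
        q: [float(np.mean(v)), float(np.median(v)), float(np.min(v)), float(np.max(v))]
        for q, v in per_beat.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(STATS))


def project_error(bound_ms: float, curve: pd.DataFrame) -> float:
    """Ensemble mean error (%) at MAE = ``bound_ms``, linearly interpolated.

    ``curve`` is an ensemble table with columns mae_ms and mean_error_pct
    (level 0 included).  A bound outside the curve's MAE range is an error
    reporting the valid range.
    """
    mae = curve["mae_ms"].to_numpy(dtype=float)
    err = curve["mean_error_pct"].to_numpy(dtype=float)
    order = np.argsort(mae)
    mae, err = mae[order], err[order]
    if not mae[0] <= bound_ms <= mae[-1]:
        raise ValidationError(
            f"bound {bound_ms} ms outside curve range [{mae[0]}, {mae[-1]}] ms"
        )
    return float(np.interp(bound_ms, mae, err))
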