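"""Gaussian timing jitter, heartbeat-interval series, and the MAE ladder.

The study's independent variable is the mean absolute error (MAE) between a
jittered heartbeat-interval (HBI) series and its unjittered baseline.  Each
beat time receives an independent zero-mean Gaussian offset of standard
deviation sigma; since an interval error is the difference of two such
offsets it is Normal(0, 2 sigma^2), and the expected MAE follows the
half-normal mean

    E[MAE] = sigma * sqrt(2) * sqrt(2/pi) = 2 sigma / sqrt(pi).

The ladder places 97 linearly spaced sigma levels whose terminal level is
calibrated so the pooled realized MAE lands on the 60 ms target.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .synthdata import RPeakStream, ValidationError, _rng

#: Expected MAE per unit sigma for independent Gaussian beat-time jitter.
MAE_PER_SIGMA = 2.0 / np.sqrt(np.pi)


@dataclass(frozen=True)
class HBISeries:
    """Heartbeat intervals stamped at each interval's trailing beat time."""

    timestamps: np.ndarray
    intervals: np.ndarray
    level: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.timestamps, dtype=float)
        x = np.asarray(self.intervals, dtype=float)
        object.__setattr__(self, "timestamps", t)
        object.__setattr__(self, "intervals", x)
        if t.size != x.size:
            raise ValidationError("timestamps and intervals must have equal length")
        if t.size and not np.all(np.diff(t) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        if np.any(x <= 0):
            raise ValidationError("intervals must be positive")


@dataclass(frozen=True)
class JitterLadder:
    """Severity schedule with realized per-participant and pooled MAEs."""

    sigmas_ms: np.ndarray              # (n_levels,), level 1..n
    mae_ms: np.ndarray                 # (n_participants, n_levels)
    pooled_mae_ms: np.ndarray          # (n_levels,)
    target_mae_ms: float
    seed: int
    participant_ids: tuple[str, ...]

    @property
    def n_levels(self) -> int:
        return int(self.sigmas_ms.size)

    def to_json(self, path) -> None:
        payload = {
            "sigmas_ms": self.sigmas_ms.tolist(),
            "mae_ms": self.mae_ms.tolist(),
            "pooled_mae_ms": self.pooled_mae_ms.tolist(),
            "target_mae_ms": self.target_mae_ms,
            "seed": self.seed,
            "participant_ids": list(self.participant_ids),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "JitterLadder":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            sigmas_ms=np.asarray(d["sigmas_ms"]),
            mae_ms=np.asarray(d["mae_ms"]),
            pooled_mae_ms=np.asarray(d["pooled_mae_ms"]),
            target_mae_ms=d["target_mae_ms"],
            seed=d["seed"],
            participant_ids=tuple(d["participant_ids"]),
        )


def perturb_rpeaks(stream: RPeakStream, sigma_ms: float, seed: int,
                   participant_index: int = 0, level: int = 1) -> RPeakStream:
    """Add independent Normal(0, sigma^2) offsets to every beat time.

    The output is re-sorted: at large sigma adjacent beats may swap order,
    and sorting restores the strict monotonicity the HBI derivation needs
    while preserving the beat count.
    """
    if sigma_ms < 0:
        raise ValidationError("sigma_ms must be >= 0")
    if sigma_ms == 0:
        return stream
    rng = _rng(seed, participant_index, 10, level)
    jittered = stream.times + rng.normal(0.0, sigma_ms / 1000.0, size=stream.n_beats)
    return RPeakStream(times=np.sort(jittered), participant_id=stream.participant_id)


def hbis_from_peaks(stream: RPeakStream, level: int = 0) -> HBISeries:
    """Successive beat-time differences, stamped at the trailing beat."""
    if stream.n_beats < 2:
        raise ValidationError("need at least two beats to form intervals")
    return HBISeries(
        timestamps=stream.times[1:],
        intervals=np.diff(stream.times),
        level=level,
    )


def hbi_mae(a: HBISeries, b: HBISeries) -> float:
    """Mean absolute difference between two aligned HBI series, in ms.

    A length mismatch signals upstream beat loss, which this error model
    excludes, so it is an error rather than a truncation.
    """
    if a.intervals.size != b.intervals.size:
        raise ValidationError(
            f"HBI series lengths differ ({a.intervals.size} vs {b.intervals.size})"
        )
    return float(np.mean(np.abs(a.intervals - b.intervals)) * 1000.0)


def _abs_interval_errors(stream: RPeakStream, sigma_ms: float, seed: int,
                         pidx: int, level: int) -> np.ndarray:
    base = np.diff(stream.times)
    pert = perturb_rpeaks(stream, sigma_ms, seed, pidx, level)
    return np.abs(np.diff(pert.times) - base) * 1000.0


def build_ladder(
    streams: list[RPeakStream],
    n_levels: int = 97,
    target_mae_ms: float = 60.0,
    seed: int = 0,
) -> JitterLadder:
    """Construct the jitter-severity ladder and realize its MAEs.

    Sigmas are linearly spaced, sigma_n = n * sigma_max / n_levels, with
    sigma_max = target * sqrt(pi) / 2 from the closed-form MAE law, then
    rescaled once by the ratio of target to realized pooled MAE at the top
    level.  Jitter draws are independent per participant and per level.
    Pooling concatenates absolute interval errors across participants.
    """
    if not streams:
        raise ValidationError("cohort of streams must be non-empty")
    for s in streams:
        if s.n_beats < 100:
            raise ValidationError(
                f"stream {s.participant_id!r} has {s.n_beats} beats; need >= 100"
            )
    if n_levels < 1:
        raise ValidationError("n_levels must be >= 1")

    sigma_max = target_mae_ms / MAE_PER_SIGMA

    # One-shot calibration against the realized pooled MAE at the top level.
    top_errors = np.concatenate(
        [_abs_interval_errors(s, sigma_max, seed, i, n_levels)
         for i, s in enumerate(streams)]
    )
    realized = float(np.mean(top_errors))
    sigma_max *= target_mae_ms / realized

    sigmas = sigma_max * np.arange(1, n_levels + 1) / n_levels
    mae = np.empty((len(streams), n_levels))
    pooled = np.empty(n_levels)
    for n, sig in enumerate(sigmas, start=1):
        per_level = [
            _abs_interval_errors(s, sig, seed, i, n)
            for i, s in enumerate(streams)
        ]
        mae[:, n - 1] = [float(np.mean(e)) for e in per_level]
        pooled[n - 1] = float(np.mean(np.concatenate(per_level)))

    return JitterLadder(
        sigmas_ms=sigmas,
        mae_ms=mae,
        pooled_mae_ms=pooled,
        target_mae_ms=target_mae_ms,
        seed=seed,
        participant_ids=tuple(s.participant_id for s in streams),
    )
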