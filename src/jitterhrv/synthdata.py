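"""Synthetic sleep cohorts and laboratory beat-pair tables.

This module generates the statistical stand-ins the rest of the pipeline
consumes: per-participant hypnograms (one sleep-stage label per 30-s epoch),
R-peak beat-time streams whose interval dynamics carry stage-dependent
low-frequency (0.04-0.15 Hz) and high-frequency (0.15-0.4 Hz) oscillatory
content, and a table of paired ECG-R / BCG-J beat timings used by the
timing-error bound.

Every distributional assumption is explicit and seeded.  Randomness is split
hierarchically per participant (``numpy.random.SeedSequence`` spawn keys), so
adding participants to a cohort never perturbs existing ones.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MICRO_STAGES = ("W", "S1", "S2", "S3", "R")
#: Raw scoring may additionally contain S4; it is merged into S3 downstream.
RAW_STAGES = ("W", "S1", "S2", "S3", "S4", "R")
MACRO_STAGES = ("W", "N", "R")

_DEFAULT_STAGE_PROPS = {"W": 0.300, "S1": 0.026, "S2": 0.411, "S3": 0.116, "R": 0.147}
_DEFAULT_MEAN_DWELL = {"W": 8.0, "S1": 5.0, "S2": 14.0, "S3": 8.0, "R": 10.0}

# RNG stream kinds for hierarchical seeding (participant, kind).
_KIND_HYPNOGRAM = 0
_KIND_RPEAKS = 1
_KIND_DURATION = 2


class ValidationError(ValueError):
    """A specification or generated object violates its invariants."""


class GenerationError(RuntimeError):
    """Generation parameters produced a physiologically impossible stream."""


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generation parameters.

    Defaults emulate the study cohort: 50 participants, nights of
    8.43 +/- 0.5 h scored in 30-s epochs, and marginal stage occupancy of
    30.0% Wake, 2.6% S1, 41.1% S2, 11.6% S3 and 14.7% REM.
    """

    n_participants: int = 50
    epoch_s: float = 30.0
    duration_mean_h: float = 8.43
    duration_sd_h: float = 0.5
    min_duration_h: float = 6.0
    stage_props: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_STAGE_PROPS)
    )
    mean_dwell_epochs: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MEAN_DWELL)
    )
    #: Probability that an S3 epoch is emitted as the non-standard S4 label,
    #: for exercising the label-cleaning rules.  Off by default.
    s4_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValidationError("n_participants must be >= 1")
        if self.epoch_s <= 0:
            raise ValidationError("epoch_s must be positive")
        if self.duration_mean_h <= 0:
            raise ValidationError("duration_mean_h must be positive")
        if self.duration_sd_h < 0:
            raise ValidationError("duration_sd_h must be non-negative")
        total = sum(self.stage_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(
                f"stage_props must sum to 1 (got {total!r})"
            )
        for stage, p in self.stage_props.items():
            if stage not in MICRO_STAGES:
                raise ValidationError(f"unknown stage in stage_props: {stage!r}")
            if p < 0:
                raise ValidationError(f"stage_props[{stage!r}] must be >= 0")
        for stage, d in self.mean_dwell_epochs.items():
            if d < 1:
                raise ValidationError(
                    f"mean_dwell_epochs[{stage!r}] must be >= 1 (got {d})"
                )
        if not 0.0 <= self.s4_prob <= 1.0:
            raise ValidationError("s4_prob must lie in [0, 1]")


@dataclass(frozen=True)
class StageParams:
    """Interval dynamics for a single sleep stage.

    RR(t) = mean_rr + lf_amp sin(2 pi lf_freq t + phi)
                    + hf_amp sin(2 pi hf_freq t + psi) + N(0, noise_sd).
    """

    mean_rr: float
    lf_amp: float
    hf_amp: float
    lf_freq: float = 0.095
    hf_freq: float = 0.25
    noise_sd: float = 0.01

    def __post_init__(self) -> None:
        if not 0.4 <= self.mean_rr <= 2.0:
            raise ValidationError(f"mean_rr must lie in [0.4, 2.0] s, got {self.mean_rr}")
        if not (self.lf_freq < 0.15 <= self.hf_freq < 0.4):
            raise ValidationError(
                "require lf_freq < 0.15 <= hf_freq < 0.4 "
                f"(got lf={self.lf_freq}, hf={self.hf_freq})"
            )
        if not 0.04 <= self.lf_freq:
            raise ValidationError("lf_freq must lie in the 0.04-0.15 Hz band")
        if self.lf_amp < 0 or self.hf_amp < 0 or self.noise_sd < 0:
            raise ValidationError("amplitudes and noise_sd must be non-negative")
        if self.lf_amp + self.hf_amp + 5 * self.noise_sd >= self.mean_rr:
            raise ValidationError(
                "amplitudes + noise leave no headroom above zero-length intervals"
            )


def default_stage_hrv_params() -> dict[str, StageParams]:
    """Per-stage interval dynamics used by the default cohort.

    The values are package defaults, not claims about any particular cohort.
    They are chosen on two principles.  First, the dominant class signal
    lives in the LF/HF spectral balance: sympathetically driven states (Wake,
    REM) carry strong LF and weak HF modulation, deep sleep the reverse
    (respiratory sinus arrhythmia), with light sleep in between.  Second,
    mean interval gaps between stages are kept small (0.86-0.98 s) and total
    interval variance roughly comparable across stages, so that windowed
    means — which timing jitter barely touches — provide useful but not
    sufficient information on their own.  Wake and REM are deliberately
    similar (their HRV signatures genuinely overlap), which keeps baseline
    classification imperfect.
    """
    return {
        "W": StageParams(mean_rr=0.86, lf_amp=0.050, hf_amp=0.012, noise_sd=0.012),
        "S1": StageParams(mean_rr=0.90, lf_amp=0.038, hf_amp=0.024, noise_sd=0.012),
        "S2": StageParams(mean_rr=0.94, lf_amp=0.026, hf_amp=0.038, noise_sd=0.010),
        "S3": StageParams(mean_rr=0.98, lf_amp=0.012, hf_amp=0.050, noise_sd=0.008),
        "S4": StageParams(mean_rr=1.00, lf_amp=0.012, hf_amp=0.050, noise_sd=0.008),
        "R": StageParams(mean_rr=0.88, lf_amp=0.052, hf_amp=0.020, noise_sd=0.016),
    }


@dataclass(frozen=True)
class Hypnogram:
    """Sleep-stage labels, one per fixed-width scoring epoch."""

    labels: np.ndarray
    epoch_s: float = 30.0
    scheme: str = "micro"
    participant_id: str = ""

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype="U2")
        object.__setattr__(self, "labels", labels)
        if labels.size == 0:
            raise ValidationError("hypnogram must be non-empty")
        alphabet = set(RAW_STAGES) if self.scheme == "micro" else set(MACRO_STAGES)
        bad = set(labels.tolist()) - alphabet
        if bad:
            raise ValidationError(f"labels outside the {self.scheme} alphabet: {bad}")

    @property
    def n_epochs(self) -> int:
        return int(self.labels.size)

    @property
    def span_s(self) -> float:
        return self.n_epochs * self.epoch_s


@dataclass(frozen=True)
class RPeakStream:
    """Strictly increasing heartbeat times (s) for one participant."""

    times: np.ndarray
    participant_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1 or times.size < 2:
            raise ValidationError("an R-peak stream needs at least two beats")
        if not np.all(np.diff(times) > 0):
            raise ValidationError("beat times must be strictly increasing")

    @property
    def n_beats(self) -> int:
        return int(self.times.size)


def generate_hypnogram(spec: CohortSpec, participant_index: int) -> Hypnogram:
    """Simulate one night of sleep scoring as a semi-Markov stage sequence.

    Night length is Normal(duration_mean_h, duration_sd_h) truncated at
    ``min_duration_h``.  Stages are emitted in blocks: the block's stage is
    drawn with probability proportional to ``stage_props[s] /
    mean_dwell_epochs[s]`` and its dwell is geometric with the stage's mean
    dwell, which makes the long-run time fraction in each stage equal to
    ``stage_props`` (renewal-reward).  Deterministic given (spec.seed,
    participant_index).
    """
    rng_dur = _rng(spec.seed, participant_index, _KIND_DURATION)
    rng = _rng(spec.seed, participant_index, _KIND_HYPNOGRAM)

    dur_h = rng_dur.normal(spec.duration_mean_h, spec.duration_sd_h)
    while dur_h < spec.min_duration_h:
        dur_h = rng_dur.normal(spec.duration_mean_h, spec.duration_sd_h)
    n_epochs = int(round(dur_h * 3600.0 / spec.epoch_s))

    stages = [s for s in MICRO_STAGES if spec.stage_props.get(s, 0.0) > 0]
    weights = np.array(
        [spec.stage_props[s] / spec.mean_dwell_epochs.get(s, 4.0) for s in stages]
    )
    weights /= weights.sum()

    labels: list[str] = []
    while len(labels) < n_epochs:
        stage = stages[rng.choice(len(stages), p=weights)]
        mean_dwell = spec.mean_dwell_epochs.get(stage, 4.0)
        dwell = rng.geometric(1.0 / mean_dwell)
        labels.extend([stage] * dwell)
    labels_arr = np.asarray(labels[:n_epochs], dtype="U2")

    if spec.s4_prob > 0:
        s3 = labels_arr == "S3"
        flip = rng.random(n_epochs) < spec.s4_prob
        labels_arr[s3 & flip] = "S4"

    return Hypnogram(
        labels=labels_arr,
        epoch_s=spec.epoch_s,
        scheme="micro",
        participant_id=f"p{participant_index:03d}",
    )


#: Night-level very-low-frequency drift of the mean interval: (amplitude s,
#: frequency Hz) pairs with periods of ~45 and ~18 min.  Both sit far below
#: the 0.04 Hz edge of the LF analysis band, so the drift blurs windowed
#: mean heart rate across stages — as circadian and thermoregulatory
#: rhythms do in real nights — without touching LF or HF band content.
DEFAULT_VLF_DRIFT = ((0.040, 1.0 / 2700.0), (0.030, 1.0 / 1080.0))


def generate_rpeaks(
    hyp: Hypnogram,
    params: dict[str, StageParams] | None = None,
    seed: int = 0,
    participant_index: int = 0,
    vlf_drift: tuple[tuple[float, float], ...] = DEFAULT_VLF_DRIFT,
) -> RPeakStream:
    """Build a beat-time stream spanning ``hyp`` from stage-dependent dynamics.

    Beat times grow iteratively: t_{k+1} = t_k + RR(t_k), where RR mixes the
    stage's mean interval, one LF and one HF sinusoid (phases drawn once per
    night), a stage-independent VLF drift, and white noise.  Raises
    :class:`GenerationError` if any interval falls to 0.2 s or below.
    """
    if hyp.scheme != "micro":
        raise ValidationError("generate_rpeaks requires a micro-coded hypnogram")
    if params is None:
        params = default_stage_hrv_params()
    rng = _rng(seed, participant_index, _KIND_RPEAKS)
    phi, psi = rng.uniform(0.0, 2.0 * np.pi, size=2)
    drift_phases = rng.uniform(0.0, 2.0 * np.pi, size=len(vlf_drift))

    span = hyp.span_s
    n_epochs = hyp.n_epochs
    # Pre-draw noise in chunks; beats number about span / min mean_rr.
    times = [0.0]
    t = 0.0
    labels = hyp.labels
    epoch_s = hyp.epoch_s
    while t < span:
        epoch = min(int(t / epoch_s), n_epochs - 1)
        p = params[labels[epoch]]
        rr = (
            p.mean_rr
            + p.lf_amp * np.sin(2.0 * np.pi * p.lf_freq * t + phi)
            + p.hf_amp * np.sin(2.0 * np.pi * p.hf_freq * t + psi)
            + rng.normal(0.0, p.noise_sd)
        )
        for (amp, freq), chi in zip(vlf_drift, drift_phases):
            rr += amp * np.sin(2.0 * np.pi * freq * t + chi)
        if rr <= 0.2:
            raise GenerationError(
                f"generated RR interval {rr:.3f} s <= 0.2 s; parameters too aggressive"
            )
        t += rr
        times.append(t)
    return RPeakStream(times=np.asarray(times), participant_id=hyp.participant_id)


def generate_cohort(
    spec: CohortSpec,
    params: dict[str, StageParams] | None = None,
) -> tuple[list[Hypnogram], list[RPeakStream]]:
    """Generate hypnogram + R-peak stream for every participant in ``spec``."""
    hyps, streams = [], []
    for i in range(spec.n_participants):
        hyp = generate_hypnogram(spec, i)
        hyps.append(hyp)
        streams.append(generate_rpeaks(hyp, params, seed=spec.seed, participant_index=i))
    return hyps, streams


def generate_beat_pairs(
    n_participants: int = 27,
    beats_per: int = 100,
    rgi_mean_ms: float = 250.0,
    rgi_sd_ms: float = 8.97,
    ep_sd_ms: float = 11.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the laboratory archive of paired ECG-R / BCG-J beat timings.

    Each row carries the R-to-ground-truth-J interval ``rgi_ms`` (Gaussian,
    truncated positive) and the detected-vs-ground-truth J timing error
    ``ep_ms`` (zero-mean Gaussian).  Default table size is 27 participants x
    100 beats = 2700 rows.
    """
    if n_participants < 1 or beats_per < 1:
        raise ValidationError("n_participants and beats_per must be positive")
    rng = _rng(seed, 0, 3)
    rows = []
    for i in range(n_participants):
        rgi = rng.normal(rgi_mean_ms, rgi_sd_ms, size=beats_per)
        while np.any(rgi <= 0):  # truncation; essentially never at defaults
            bad = rgi <= 0
            rgi[bad] = rng.normal(rgi_mean_ms, rgi_sd_ms, size=bad.sum())
        ep = rng.normal(0.0, ep_sd_ms, size=beats_per)
        for j in range(beats_per):
            rows.append((f"p{i:03d}", j, rgi[j], ep[j]))
    return pd.DataFrame(rows, columns=["participant_id", "beat_index", "rgi_ms", "ep_ms"])


# ---------------------------------------------------------------------------
# CSV schemas shared with the rest of the pipeline


def rpeaks_to_csv(streams: list[RPeakStream], path) -> None:
    frames = [
        pd.DataFrame({"participant_id": s.participant_id, "time_s": s.times})
        for s in streams
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def rpeaks_from_csv(path) -> list[RPeakStream]:
    df = pd.read_csv(path)
    return [
        RPeakStream(times=g["time_s"].to_numpy(), participant_id=str(pid))
        for pid, g in df.groupby("participant_id", sort=True)
    ]


def hypnograms_to_csv(hyps: list[Hypnogram], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "participant_id": h.participant_id,
                "epoch_index": np.arange(h.n_epochs),
                "stage": h.labels,
            }
        )
        for h in hyps
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def hypnograms_from_csv(path, epoch_s: float = 30.0, scheme: str = "micro") -> list[Hypnogram]:
    df = pd.read_csv(path)
    out = []
    for pid, g in df.groupby("participant_id", sort=True):
        g = g.sort_values("epoch_index")
        out.append(
            Hypnogram(
                labels=g["stage"].to_numpy(dtype="U2"),
                epoch_s=epoch_s,
                scheme=scheme,
                participant_id=str(pid),
            )
        )
    return out


def cohort_spec_from_dict(d: dict) -> CohortSpec:
    """Build a CohortSpec from a config mapping, naming any offending key."""
    known = {f.name for f in dataclasses.fields(CohortSpec)}
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown CohortSpec keys: {sorted(unknown)}")
    try:
        return CohortSpec(**d)
    except ValidationError:
        raise
    except TypeError as exc:
        raise ValidationError(str(exc)) from exc


def stage_params_from_dict(d: dict) -> dict[str, StageParams]:
    out = dict(default_stage_hrv_params())
    for stage, fields in d.items():
        if stage not in RAW_STAGES:
            raise ValidationError(f"unknown stage in stage_hrv_params: {stage!r}")
        base = dataclasses.asdict(out[stage])
        unknown = set(fields) - set(base)
        if unknown:
            raise ValidationError(
                f"unknown StageParams keys for {stage!r}: {sorted(unknown)}"
            )
        base.update(fields)
        out[stage] = StageParams(**base)
    return out
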