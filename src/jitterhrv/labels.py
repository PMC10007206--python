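"""Hypnogram cleaning and the micro / macro labeling schemes.

Raw sleep scoring occasionally contains the non-standard S4 label and
single-epoch "glitches".  Cleaning merges S4 into S3 and relabels any stage
run shorter than four epochs to the preceding run's stage.  The cleaned
micro hypnogram ({Wake, S1, S2, S3, REM}) can then be collapsed into the
three-class macro coding ({Wake, NREM, REM}).
"""

from __future__ import annotations

import warnings

import numpy as np

from .synthdata import Hypnogram, ValidationError

MICRO_TO_MACRO = {"W": "W", "S1": "N", "S2": "N", "S3": "N", "R": "R"}


def merge_s4(hyp: Hypnogram) -> Hypnogram:
    """Replace every S4 label by S3, leaving everything else unchanged."""
    if hyp.scheme != "micro":
        raise ValidationError("merge_s4 expects a micro-coded hypnogram")
    labels = hyp.labels.copy()
    labels[labels == "S4"] = "S3"
    return Hypnogram(labels=labels, epoch_s=hyp.epoch_s, scheme="micro",
                     participant_id=hyp.participant_id)


def _runs(labels: np.ndarray) -> list[tuple[str, int]]:
    """Run-length encode a label sequence as (stage, length) pairs."""
    out: list[tuple[str, int]] = []
    for lab in labels:
        if out and out[-1][0] == lab:
            out[-1] = (lab, out[-1][1] + 1)
        else:
            out.append((str(lab), 1))
    return out


def merge_short_runs(hyp: Hypnogram, min_epochs: int = 4) -> Hypnogram:
    """Relabel stage runs shorter than ``min_epochs`` to their neighbours.

    Scanning left to right, a short maximal run takes the stage of the
    preceding (already processed) run; a short leading run takes the stage of
    the run after it.  Merging can create new short runs, so the pass repeats
    until a fixed point is reached.  Length is always preserved.  A hypnogram
    shorter than ``min_epochs`` overall is returned unchanged with a warning.
    """
    if min_epochs < 1:
        raise ValidationError("min_epochs must be >= 1")
    if hyp.n_epochs < min_epochs:
        warnings.warn(
            "hypnogram shorter than min_epochs; returned unchanged", stacklevel=2
        )
        return hyp

    # One relabel at a time: find the first (leftmost) short run, absorb it
    # into its predecessor (or successor when it leads), and rescan.  Each
    # relabel removes at least one run, so this terminates in O(#runs) steps.
    runs = _runs(hyp.labels)
    while len(runs) > 1:
        idx = next(
            (i for i, (_, n) in enumerate(runs) if n < min_epochs), None
        )
        if idx is None:
            break
        if idx == 0:
            stage = runs[1][0]
        else:
            stage = runs[idx - 1][0]
        runs[idx] = (stage, runs[idx][1])
        # Coalesce with equal-stage neighbours.
        merged: list[tuple[str, int]] = []
        for s, n in runs:
            if merged and merged[-1][0] == s:
                merged[-1] = (s, merged[-1][1] + n)
            else:
                merged.append((s, n))
        runs = merged

    labels = np.concatenate([np.full(l, s, dtype="U2") for s, l in runs])
    return Hypnogram(labels=labels, epoch_s=hyp.epoch_s, scheme=hyp.scheme,
                     participant_id=hyp.participant_id)


def to_macro(hyp: Hypnogram) -> Hypnogram:
    """Collapse a cleaned micro hypnogram to {Wake, NREM, REM}."""
    if hyp.scheme != "micro":
        raise ValidationError("to_macro expects a micro-coded hypnogram")
    try:
        labels = np.asarray([MICRO_TO_MACRO[str(s)] for s in hyp.labels], dtype="U2")
    except KeyError as exc:
        raise ValidationError(f"unknown micro label {exc.args[0]!r}; merge S4 first") from exc
    return Hypnogram(labels=labels, epoch_s=hyp.epoch_s, scheme="macro",
                     participant_id=hyp.participant_id)


def clean(hyp: Hypnogram, min_epochs: int = 4) -> Hypnogram:
    """Full cleaning pass: S4 merge followed by short-run merging."""
    return merge_short_runs(merge_s4(hyp), min_epochs=min_epochs)
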