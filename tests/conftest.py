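"""Shared fixtures.

The heavy study-scale objects (10-participant default cohort, its 20-level
jitter ladder, and the stacked per-level feature table) are session-scoped:
they are generated once and shared by every test that inspects cohort-level
behaviour.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from jitterhrv.hrv import compute_features
from jitterhrv.jitter import build_ladder, hbis_from_peaks, perturb_rpeaks
from jitterhrv.labels import clean, to_macro
from jitterhrv.synthdata import CohortSpec, generate_cohort

N_PARTICIPANTS = 10
N_LEVELS = 20
SEED = 1


@pytest.fixture(scope="session")
def cohort():
    """Default-parameter synthetic cohort: 10 participants, seed 1."""
    spec = CohortSpec(n_participants=N_PARTICIPANTS, seed=SEED)
    hyps, streams = generate_cohort(spec)
    return spec, hyps, streams


@pytest.fixture(scope="session")
def cleaned_hypnograms(cohort):
    _, hyps, _ = cohort
    micro = [clean(h) for h in hyps]
    macro = [to_macro(h) for h in micro]
    return micro, macro


@pytest.fixture(scope="session")
def ladder(cohort):
    """20-level jitter ladder calibrated to a 60 ms terminal MAE."""
    _, _, streams = cohort
    return build_ladder(streams, n_levels=N_LEVELS, target_mae_ms=60.0, seed=SEED)


@pytest.fixture(scope="session")
def feature_table(cohort, cleaned_hypnograms, ladder):
    """Per-epoch HRV features for every participant at levels 0..20."""
    _, _, streams = cohort
    micro, _ = cleaned_hypnograms
    frames = []
    for i, (stream, hyp) in enumerate(zip(streams, micro)):
        for lvl in range(0, N_LEVELS + 1):
            pert = (
                stream
                if lvl == 0
                else perturb_rpeaks(stream, ladder.sigmas_ms[lvl - 1], SEED, i, lvl)
            )
            frames.append(compute_features(hbis_from_peaks(pert, level=lvl), hyp))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="session")
def mae_by_participant(ladder):
    return {
        pid: {lvl: ladder.mae_ms[i, lvl - 1] for lvl in range(1, N_LEVELS + 1)}
        for i, pid in enumerate(ladder.participant_ids)
    }


@pytest.fixture(scope="session")
def macro_feature_table(feature_table, cleaned_hypnograms):
    """Feature table with macro-coded stage labels."""
    _, macro = cleaned_hypnograms
    labels = {h.participant_id: h.labels for h in macro}
    table = feature_table.copy()
    table["stage"] = [
        labels[pid][int(e)]
        for pid, e in zip(table["participant_id"], table["epoch_index"])
    ]
    return table


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
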