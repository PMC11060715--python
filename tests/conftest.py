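"""Shared fixtures: small synthetic recordings reused across test modules."""

import numpy as np
import pytest

from caim import events, traces
from caim.synthetic import GroundTruth, generate_population

FIVE_ASSEMBLIES = tuple(frozenset(range(i * 10, (i + 1) * 10)) for i in range(5))


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b)


def best_match_jaccard(detected, planted) -> float:
    """Mean over planted assemblies of the best Jaccard with any detected one."""
    return float(
        np.mean(
            [max((jaccard(d, p) for d in detected), default=0.0) for p in planted]
        )
    )


@pytest.fixture(scope="session")
def assembly_recording():
    """100 neurons, 600 s, 5 planted 10-member assemblies (the standard bench)."""
    gt = GroundTruth(
        n_neurons=100, duration_s=600.0, assembly_memberships=FIVE_ASSEMBLIES, seed=42
    )
    return generate_population(gt)


@pytest.fixture(scope="session")
def preprocessed(assembly_recording):
    rec = assembly_recording
    ts = traces.RoiTraceSet(
        rec.roi_fluorescence,
        rec.neuropil_fluorescence,
        rec.ground_truth.frame_rate_hz,
        rec.roi_centroids,
    )
    return traces.preprocess(ts)


@pytest.fixture(scope="session")
def detected(preprocessed):
    noise = events.estimate_noise(preprocessed.dff)
    return events.detect_transients(
        preprocessed.dff, noise, preprocessed.frame_rate_hz
    )
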