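import numpy as np
import pytest

import mtrrp as M


@pytest.fixture(scope="session")
def tiny_cohort():
    """Four-subject, 19-channel synthetic cohort at desk scale (8 s @ 128 Hz)."""
    spec = M.SyntheticEEGSpec(n_per_group=2, sampling_rate=128.0, duration=8.0,
                              seed=42)
    return M.generate_synthetic_eeg(spec)


@pytest.fixture(scope="session")
def tiny_feature_table(tiny_cohort):
    return M.extract_features(tiny_cohort, max_duration=None)


def brute_force_recurrence(vectors: np.ndarray, epsilon: float, norm: str,
                           theiler: int):
    """Independent double-loop oracle for the recurrence matrix and rate."""
    n = len(vectors)
    mat = np.zeros((n, n), dtype=bool)
    ones = 0
    counted = 0
    for i in range(n):
        for j in range(n):
            if abs(i - j) < theiler and theiler > 0:
                continue
            counted += 1
            diff = vectors[i] - vectors[j]
            if norm == "euclidean":
                d = float(np.sqrt(np.sum(diff * diff)))
            else:
                d = float(np.max(np.abs(diff)))
            if d <= epsilon:
                mat[i, j] = True
                ones += 1
    return mat, ones / counted
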