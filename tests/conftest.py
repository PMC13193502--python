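"""Shared fixtures: a brute-force footfall oracle and small canned inputs.

The oracle re-derives epochs by explicit forward scanning over the
confident subsequence, independently of the detector's state machine, so
detector/oracle agreement is a meaningful check rather than a tautology.
"""

from __future__ import annotations

import numpy as np
import pytest


def brute_force_epochs(frames, y, baseline, offset, n_frames):
    """Scan the confident samples directly for slip epochs.

    Returns tuples (start_frame, end_frame, max_drop, closed) with the same
    conventions as the detector: open strictly beyond baseline + offset,
    close at the first sample back at or above baseline (excursion <= 0),
    unclosed epochs end at n_frames.
    """
    events = []
    m = len(frames)
    i = 0
    while i < m:
        exc = y[i] - baseline
        if exc > offset:
            drops = [exc]
            j = i + 1
            while j < m and (y[j] - baseline) > 0:
                drops.append(y[j] - baseline)
                j += 1
            if j < m:
                events.append((int(frames[i]), int(frames[j]), max(drops), True))
                i = j + 1
            else:
                events.append((int(frames[i]), int(n_frames), max(drops), False))
                break
        else:
            i += 1
    return events


@pytest.fixture
def epoch_oracle():
    return brute_force_epochs


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
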