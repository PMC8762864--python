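"""Shared fixtures.

The two heavyweight end-to-end studies (parameter recovery and the
zero-effect null regime) are session-scoped: several test modules probe
different properties of the same fitted pipeline, so it is trained once.
"""

from __future__ import annotations

import numpy as np
import pytest

from m6acall.event_io import EventRead


@pytest.fixture(scope="session")
def recovery_report():
    """Full pipeline on simulated data: rate grid {0.0..0.9}, coverage 200."""
    from m6acall.harness import run_recovery_study

    return run_recovery_study(seed=0)


@pytest.fixture(scope="session")
def null_report():
    """Zero-effect regime: chance-level classifiers, null discovery."""
    from m6acall.harness import run_null_study

    return run_null_study(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_event_read(
    read_id: str = "read1",
    transcript_id: str = "tx1",
    start: int = 0,
    length: int = 20,
    mismatch_at: tuple[int, ...] = (),
    gap_at: tuple[int, ...] = (),
    seed: int = 0,
) -> EventRead:
    """A synthetic EventRead with 4-decimal feature values (exact TSV
    round-tripping) and configurable mismatch/gap positions (absolute
    transcript coordinates)."""
    r = np.random.default_rng(seed)
    feats = np.round(
        np.column_stack(
            [
                r.normal(100, 2, length),
                r.normal(100, 2, length),
                np.abs(r.normal(1.5, 0.2, length)),
                r.lognormal(0, 0.3, length),
                np.clip(r.normal(12, 2, length), 1, 40),
            ]
        ),
        4,
    )
    flags = np.array(["match"] * length, dtype=object)
    for pos in mismatch_at:
        flags[pos - start] = "mismatch"
    for pos in gap_at:
        flags[pos - start] = "gap"
        feats[pos - start] = 0.0
    return EventRead(
        read_id=read_id, transcript_id=transcript_id, start=start,
        features=feats, flags=flags,
    )


@pytest.fixture()
def event_read_factory():
    return make_event_read


def frame_from_flags(flag_matrix, transcript_id="tx1", prefix="r", start=0):
    """Long event frame from an (n_reads, n_pos) array of match flags."""
    n_reads, n_pos = np.asarray(flag_matrix, dtype=object).shape
    rows = []
    for i in range(n_reads):
        read = make_event_read(
            read_id=f"{prefix}{i:04d}", transcript_id=transcript_id,
            start=start, length=n_pos, seed=i,
        )
        read.flags = np.asarray(flag_matrix[i], dtype=object)
        rows.append(read)
    from m6acall.event_io import events_to_frame

    return events_to_frame(rows)


@pytest.fixture()
def flag_frame_factory():
    return frame_from_flags
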