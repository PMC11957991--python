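"""Shared fixtures: small synthetic recordings and the LZ76 parsing oracle."""

from __future__ import annotations

import numpy as np
import pytest

from atriakit.synth import OutcomeSpec, SignalModelParams, generate_sinus_recording


def lz76_oracle(s: str) -> int:
    """Naive exhaustive-parsing LZ76 production count.

    Scans left to right; each phrase is extended while it can be reproduced
    as a substring of the already-produced text (including its own growing
    copy), then closed with the innovating symbol.  O(n^3) string search —
    independent of the pointer-based counting used by the library.
    """
    n = len(s)
    i = 0
    c = 0
    while i < n:
        length = 1
        while i + length <= n and s[i:i + length] in s[:i + length - 1]:
            length += 1
        c += 1
        i += length
    return c


@pytest.fixture(scope="session")
def male_params() -> SignalModelParams:
    return SignalModelParams(seed=0)


@pytest.fixture(scope="session")
def sinus_recording(male_params):
    """10-s conditioned-input sinus recording with ground-truth annotations."""
    return generate_sinus_recording(male_params, 10.0)


@pytest.fixture(scope="session")
def af_outcome() -> OutcomeSpec:
    return OutcomeSpec("af", episode_duration=6.0,
                       af_mean_interval=45.0, af_interval_cv=0.25)


@pytest.fixture(scope="session")
def svt_outcome() -> OutcomeSpec:
    return OutcomeSpec("regular_svt", episode_duration=6.0,
                       svt_cl=70.0, svt_cv=0.01)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
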