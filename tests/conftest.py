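"""Shared fixtures: cached synthetic runs so expensive renders happen once."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from labassay.synthetic import generate_scenario
from labassay.trajectory import extract_trajectory

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


class _RunCache:
    """Memoised generate_scenario + extract_trajectory."""

    def __init__(self) -> None:
        self._cache: dict = {}

    def __call__(self, name: str, seed: int = 0, noiseless: bool = False, **overrides):
        key = (name, seed, noiseless, tuple(sorted(overrides.items())))
        if key not in self._cache:
            ov = dict(overrides)
            if noiseless:
                ov["noise_sd"] = 0.0
            series, truth = generate_scenario(name, overrides=ov or None, seed=seed)
            traj = extract_trajectory(series)
            self._cache[key] = (series, truth, traj)
        return self._cache[key]


@pytest.fixture(scope="session")
def runs() -> _RunCache:
    return _RunCache()


@pytest.fixture(scope="session")
def plate_noiseless(runs):
    """Noiseless reference plate run: 0.1 mM ReC, 1.0 mg/mL enzyme."""
    return runs("plate_soluble_0.1mM_1mg", seed=0, noiseless=True)


@pytest.fixture(scope="session")
def chip_noiseless(runs):
    """Noiseless chip run: 10x10 array, 2 mM stock, 4 mg/mL enzyme."""
    return runs("chip_10x10_2mM", seed=0, noiseless=True)
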