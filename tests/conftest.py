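"""Shared fixtures: small synthetic configurations generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from plvnet import CouplingSpec, SyntheticCohortConfig
from plvnet.synthetic import NoiseSpec

#: compact sensorimotor montage used by reduced-scale tests
SENSORIMOTOR16 = (
    "Fz", "FC3", "FCz", "FC4", "C3", "Cz", "C4", "C5",
    "C1", "C2", "CP3", "CPz", "CP4", "P3", "Pz", "P4",
)


def small_config(seed: int = 7, **overrides) -> SyntheticCohortConfig:
    """A fast cohort: 3 subjects, 8 trials, 16 channels, native 256 Hz."""
    kwargs = dict(
        n_subjects=3, n_trials=8, channels=SENSORIMOTOR16, rate=256.0,
        tasks=("active",), couplings={}, noise=NoiseSpec(snr_db=0.0),
        seed=seed)
    kwargs.update(overrides)
    return SyntheticCohortConfig(**kwargs)


def coupled_pair_config(kappa: float, seed: int = 3, snr_db: float = 0.0,
                        n_trials: int = 42,
                        band: str = "high_beta") -> SyntheticCohortConfig:
    """Two subjects, one coupled pair (C3, C4) during [0, 2] s."""
    return small_config(
        seed=seed, n_subjects=2, n_trials=n_trials,
        couplings={"active": [CouplingSpec(("C3", "C4"), band, (0.0, 2.0), kappa)]},
        noise=NoiseSpec(snr_db=snr_db))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
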