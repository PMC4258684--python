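"""Shared fixtures: small handmade datasets and synthetic study conditions."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from chescatools import (
    ActivityClass,
    GeneratorConfig,
    ShiftDataset,
    StateMeta,
    generate,
)

FIVE_STATES = (
    StateMeta("apo", ActivityClass.APO, is_bound=False),
    StateMeta("Rp", ActivityClass.REVERSE_AGONIST),
    StateMeta("OMe", ActivityClass.PARTIAL_AGONIST),
    StateMeta("cAMP", ActivityClass.AGONIST),
    StateMeta("Sp", ActivityClass.AGONIST),
)


def dataset_from_profiles(
    profiles: dict[int, np.ndarray],
    states=FIVE_STATES,
    base_h: float = 8.0,
    base_n: float = 118.0,
    h_share: float = 0.5,
    sf: float = 0.2,
) -> ShiftDataset:
    """Build a dataset whose per-residue CCS profile follows a given vector.

    Each residue's response is split between the two nuclei so that the
    compounded shift (at the given sf) reproduces the requested profile.
    """
    rows = []
    names = [s.state for s in states]
    for rid, profile in profiles.items():
        profile = np.asarray(profile, dtype=float)
        assert len(profile) == len(names)
        for j, name in enumerate(names):
            rows.append(
                {
                    "residue_id": rid,
                    "state": name,
                    "delta_H": base_h + rid * 0.05 + h_share * profile[j],
                    "delta_N": base_n + rid * 0.1 + (1 - h_share) * profile[j] / sf,
                }
            )
    return ShiftDataset(pd.DataFrame(rows), states)


@pytest.fixture
def five_states():
    return FIVE_STATES


@pytest.fixture
def small_dataset():
    """Two allosteric-like residues plus one flat residue, five states."""
    p = np.array([0.2, 0.1, 0.8, 0.95, 1.0])
    return dataset_from_profiles({1: 0.3 * p, 2: -0.2 * p, 3: 0.0 * p})


@pytest.fixture
def noiseless_allosteric():
    """30 allosteric + 15 unresponsive residues, no noise, no binding."""
    cfg = GeneratorConfig(
        n_binding=0, noise_sigma_h=0.0, noise_sigma_n=0.0, seed=11
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate(cfg)


@pytest.fixture
def noiseless_mixed():
    """Allosteric + binding + unresponsive roles, no measurement noise."""
    cfg = GeneratorConfig(noise_sigma_h=0.0, noise_sigma_n=0.0, seed=5)
    return generate(cfg)


@pytest.fixture
def noisy_default():
    """The canonical noisy study condition (60 residues, sigma 0.002 ppm)."""
    return generate(GeneratorConfig(seed=3))


def random_correlation_matrix(rng: np.random.Generator, n: int):
    """Valid CorrelationMatrix from random Gaussian 5-state profiles."""
    from chescatools import CCSMatrix, correlation_matrix

    data = rng.normal(size=(n, 5))
    m = CCSMatrix(
        values=pd.DataFrame(
            data,
            index=range(1, n + 1),
            columns=[s.state for s in FIVE_STATES],
        ),
        nucleus_mode="combined",
        scaling_factor=0.2,
    )
    return correlation_matrix(m)
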