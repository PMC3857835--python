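"""Shared fixtures: small populations, tiny configs, synthetic response tensors."""

from __future__ import annotations

import numpy as np
import pytest

from gainfieldnet.analysis import ResponseTensor
from gainfieldnet.config import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_config():
    """A deliberately small config for fast end-to-end runs in unit tests."""
    return SimulationConfig.reduced_scale(
        input={"retinal_range": (-12.0, 12.0), "eye_range": (-4.0, 4.0), "sigma_retinal": 3.0, "sigma_eye": 3.0},
        protocol={
            "target_locations": (-4.0, 4.0),
            "fixations_per_period": 2,
            "fixation_duration_ms": 40.0,
            "eye_sample_range": (-3.0, 3.0),
        },
        test={
            "eye_positions": (-2.0, 2.0),
            "head_range": (-8.0, 8.0),
            "head_step": 2.0,
            "settle_ms": 100.0,
        },
        run={"n_output": 20, "epochs": 1, "record_epochs": False},
    )


def gaussian_bump(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-((grid - center) ** 2) / (2.0 * width**2))


def head_centered_tensor(
    n_neurons: int = 5,
    eye_positions=(-6.0, -2.0, 2.0, 6.0),
    head_locations=None,
    width: float = 5.0,
    rng: np.random.Generator | None = None,
) -> ResponseTensor:
    """Synthetic neurons whose head-space response is identical at every eye
    position (perfectly head-centered by construction)."""
    if head_locations is None:
        head_locations = np.arange(-30.0, 31.0, 2.0)
    heads = np.asarray(head_locations, dtype=float)
    rng = rng or np.random.default_rng(0)
    centers = rng.uniform(heads[3], heads[-4], size=n_neurons)
    rates = np.empty((n_neurons, len(eye_positions), len(heads)))
    for j, c in enumerate(centers):
        bump = gaussian_bump(heads, c, width)
        rates[j] = np.tile(bump, (len(eye_positions), 1))
    return ResponseTensor(rates, np.asarray(eye_positions, float), heads)


def retinotopic_tensor(
    n_neurons: int = 5,
    eye_positions=(-6.0, -2.0, 2.0, 6.0),
    head_locations=None,
    width: float = 5.0,
    rng: np.random.Generator | None = None,
) -> ResponseTensor:
    """Synthetic neurons with a bump at a fixed *retinal* location: in head
    coordinates the bump shifts by the eye position (perfectly eye-centered)."""
    if head_locations is None:
        head_locations = np.arange(-30.0, 31.0, 2.0)
    heads = np.asarray(head_locations, dtype=float)
    eyes = np.asarray(eye_positions, dtype=float)
    rng = rng or np.random.default_rng(0)
    centers = rng.uniform(heads[6], heads[-7], size=n_neurons)
    rates = np.empty((n_neurons, len(eyes), len(heads)))
    for j, c in enumerate(centers):
        for i, e in enumerate(eyes):
            # retinal location h - e sits at preferred value c when h = c + e
            rates[j, i] = gaussian_bump(heads, c + e, width)
    return ResponseTensor(rates, eyes, heads)
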