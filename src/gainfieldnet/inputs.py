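"""Input population: retinotopic neurons with eye-position gain fields.

Each coupled input neuron fires as the product of two Gaussians, one over
retinal target location x with preferred location x_i and width sigma_x,
and one over eye position e with preferred position e_i and width sigma_e:

    r'_i(x, e) = exp(-(e - e_i)^2 / (2 sigma_e^2)) * exp(-(x - x_i)^2 / (2 sigma_x^2))

so the neuron responds maximally (rate 1) only when the target sits at its
preferred retinal location while the eyes are at its preferred position
("peaked" gain field).  The population tiles the full cross product of a
1-degree retinal grid and a 1-degree eye-position grid.

The decoupled control population splits the neurons into a visual-only half
(single Gaussian in retinal location, blind to eye position) and an
eye-only half (single Gaussian in eye position, blind to the target).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "InputPopulation",
    "build_coupled_grid",
    "build_decoupled_population",
    "response_coupled",
    "response_decoupled",
    "response",
    "response_series",
]

VISUAL_ROLE = "visual"
EYE_ROLE = "eye"


@dataclass(frozen=True)
class InputPopulation:
    """Preferred locations, tuning widths and mode of the input layer.

    ``preferred_retinal[i]`` and ``preferred_eye[i]`` are the joint
    preference of neuron ``i`` (degrees).  In decoupled mode
    ``decoupled_role[i]`` tags each neuron as visual-only or eye-only and
    the irrelevant preference entry is NaN.
    """

    preferred_retinal: np.ndarray
    preferred_eye: np.ndarray
    sigma_retinal: float
    sigma_eye: float
    mode: str
    decoupled_role: Optional[np.ndarray] = None
    # grid axes kept for factorized evaluation of coupled grids
    retinal_axis: Optional[np.ndarray] = None
    eye_axis: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.sigma_retinal <= 0 or self.sigma_eye <= 0:
            raise ValueError("tuning widths must be strictly positive")
        if self.mode not in ("coupled", "decoupled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "decoupled":
            if self.decoupled_role is None:
                raise ValueError("decoupled population requires per-neuron roles")
            n_vis = int(np.sum(self.decoupled_role == VISUAL_ROLE))
            if abs(2 * n_vis - self.n) > 1:  # halves may differ by 1 on odd grids
                raise ValueError("decoupled roles must split the population in half")

    @property
    def n(self) -> int:
        return len(self.preferred_retinal)


def _axis(lo: float, hi: float, step: float, name: str) -> np.ndarray:
    if hi < lo:
        raise ValueError(f"{name} range must be ordered (lo <= hi)")
    if step <= 0:
        raise ValueError("step must be positive")
    width = hi - lo
    n_steps = width / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"step {step} does not evenly tile the {name} range [{lo}, {hi}]")
    return lo + step * np.arange(int(round(n_steps)) + 1)


def build_coupled_grid(
    retinal_range: tuple[float, float],
    eye_range: tuple[float, float],
    step: float = 1.0,
    sigma_retinal: float = 6.0,
    sigma_eye: float = 6.0,
) -> InputPopulation:
    """Cross-product preference grid, row-major by eye position then retinal.

    Neuron count = (retinal points) x (eye points); neuron ``ie * n_x + ix``
    prefers ``(retinal_axis[ix], eye_axis[ie])``.
    """
    xs = _axis(*retinal_range, step, "retinal")
    es = _axis(*eye_range, step, "eye")
    preferred_retinal = np.tile(xs, len(es))
    preferred_eye = np.repeat(es, len(xs))
    return InputPopulation(
        preferred_retinal=preferred_retinal,
        preferred_eye=preferred_eye,
        sigma_retinal=float(sigma_retinal),
        sigma_eye=float(sigma_eye),
        mode="coupled",
        retinal_axis=xs,
        eye_axis=es,
    )


def build_decoupled_population(
    retinal_range: tuple[float, float],
    eye_range: tuple[float, float],
    step: float = 1.0,
    sigma_retinal: float = 6.0,
    sigma_eye: float = 6.0,
) -> InputPopulation:
    """Decoupled control: the same grid population with coupling removed.

    The population keeps the coupled grid's size and preferences, but half
    of the neurons respond purely to the retinotopic target location (the
    eye-position factor of the response is dropped) and the other half
    purely to the eye position.  Roles alternate along the row-major grid
    so each half covers both grid axes evenly; the irrelevant preference
    entry of each neuron is set to NaN.  (For an odd-sized grid the halves
    differ by one neuron.)
    """
    grid = build_coupled_grid(retinal_range, eye_range, step, sigma_retinal, sigma_eye)
    roles = np.where(np.arange(grid.n) % 2 == 0, VISUAL_ROLE, EYE_ROLE)
    vis = roles == VISUAL_ROLE
    preferred_retinal = np.where(vis, grid.preferred_retinal, np.nan)
    preferred_eye = np.where(vis, np.nan, grid.preferred_eye)
    return InputPopulation(
        preferred_retinal=preferred_retinal,
        preferred_eye=preferred_eye,
        sigma_retinal=float(sigma_retinal),
        sigma_eye=float(sigma_eye),
        mode="decoupled",
        decoupled_role=roles,
    )


def _check_finite(*values: float) -> None:
    if not all(np.isfinite(v) for v in values):
        raise ValueError("retinal location and eye position must be finite")


def response_coupled(pop: InputPopulation, retinal_loc: float, eye_pos: float) -> np.ndarray:
    """Firing rates of a coupled population for one (x, e) pair, in [0, 1]."""
    if pop.mode != "coupled":
        raise ValueError("response_coupled requires a coupled population")
    _check_finite(retinal_loc, eye_pos)
    gx = np.exp(-((retinal_loc - pop.preferred_retinal) ** 2) / (2.0 * pop.sigma_retinal**2))
    ge = np.exp(-((eye_pos - pop.preferred_eye) ** 2) / (2.0 * pop.sigma_eye**2))
    return gx * ge


def response_decoupled(pop: InputPopulation, retinal_loc: float, eye_pos: float) -> np.ndarray:
    """Firing rates of a decoupled population: each half sees one signal only."""
    if pop.mode != "decoupled":
        raise ValueError("response_decoupled requires a decoupled population")
    _check_finite(retinal_loc, eye_pos)
    out = np.empty(pop.n)
    vis = pop.decoupled_role == VISUAL_ROLE
    out[vis] = np.exp(
        -((retinal_loc - pop.preferred_retinal[vis]) ** 2) / (2.0 * pop.sigma_retinal**2)
    )
    out[~vis] = np.exp(-((eye_pos - pop.preferred_eye[~vis]) ** 2) / (2.0 * pop.sigma_eye**2))
    return out


def response(pop: InputPopulation, retinal_loc: float, eye_pos: float) -> np.ndarray:
    """Mode-dispatching single-sample response."""
    if pop.mode == "coupled":
        return response_coupled(pop, retinal_loc, eye_pos)
    return response_decoupled(pop, retinal_loc, eye_pos)


def response_series(
    pop: InputPopulation, retinal_locs: np.ndarray, eye_positions: np.ndarray
) -> np.ndarray:
    """Population rates for a time series of (x, e) samples, shape (T, n).

    For coupled grid populations the Gaussians factorize along the two grid
    axes, so only T x (n_x + n_e) exponentials are evaluated.
    """
    retinal_locs = np.asarray(retinal_locs, dtype=float)
    eye_positions = np.asarray(eye_positions, dtype=float)
    if retinal_locs.shape != eye_positions.shape:
        raise ValueError("retinal and eye series must have matching shapes")
    if not (np.all(np.isfinite(retinal_locs)) and np.all(np.isfinite(eye_positions))):
        raise ValueError("stimulus series must be finite")
    if pop.mode == "coupled" and pop.retinal_axis is not None:
        gx = np.exp(
            -((retinal_locs[:, None] - pop.retinal_axis[None, :]) ** 2)
            / (2.0 * pop.sigma_retinal**2)
        )
        ge = np.exp(
            -((eye_positions[:, None] - pop.eye_axis[None, :]) ** 2) / (2.0 * pop.sigma_eye**2)
        )
        return (ge[:, :, None] * gx[:, None, :]).reshape(len(retinal_locs), pop.n)
    if pop.mode == "decoupled":
        vis = pop.decoupled_role == VISUAL_ROLE
        out = np.empty((len(retinal_locs), pop.n))
        out[:, vis] = np.exp(
            -((retinal_locs[:, None] - pop.preferred_retinal[None, vis]) ** 2)
            / (2.0 * pop.sigma_retinal**2)
        )
        out[:, ~vis] = np.exp(
            -((eye_positions[:, None] - pop.preferred_eye[None, ~vis]) ** 2)
            / (2.0 * pop.sigma_eye**2)
        )
        return out
    return np.stack([response(pop, x, e) for x, e in zip(retinal_locs, eye_positions)])
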