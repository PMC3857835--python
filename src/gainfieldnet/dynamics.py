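"""Output-layer dynamics: activation, competition, firing rate and trace.

Each of the N output neurons carries three dynamical variables, integrated
with Forward Euler at time step dt (by default one tenth of the fastest
time constant):

    activation   tau   dh_j/dt = -h_j + sum_i w_ji r'_i
    firing rate        r_j     = 1 / (1 + exp(-beta (h_j - theta)))
    memory trace tau_q dq_j/dt = -q_j + r_j

Competition between output neurons is the percentile-threshold abstraction
of lateral inhibition: theta is recomputed at every step as the pi-th
percentile of the current activation distribution, so only roughly the top
(100 - pi)% of neurons fire strongly.  With competition disabled, theta is
a fixed constant (0 by default) and all neurons may stay active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "DynamicsParams",
    "NetworkState",
    "activation_step",
    "firing_rates",
    "trace_step",
    "settle_and_read",
]


@dataclass(frozen=True)
class DynamicsParams:
    tau_ms: float = 10.0
    tau_trace_ms: float = 100.0
    slope: float = 10.0
    percentile: float = 95.0
    competition: bool = True
    theta_fixed: float = 0.0
    dt_ms: float | None = None

    def __post_init__(self):
        if self.tau_ms <= 0 or self.tau_trace_ms <= 0:
            raise ValueError("time constants must be positive")
        if self.slope <= 0:
            raise ValueError("sigmoid slope must be positive")
        if not (0.0 <= self.percentile <= 100.0):
            raise ValueError("percentile must lie in [0, 100]")
        if self.dt_ms is not None and self.dt_ms <= 0:
            raise ValueError("dt must be positive")

    @property
    def dt(self) -> float:
        """Integration step (ms): min(tau, tau_q)/10 unless overridden."""
        if self.dt_ms is not None:
            return self.dt_ms
        return min(self.tau_ms, self.tau_trace_ms) / 10.0


@dataclass
class NetworkState:
    """Synaptic weights (sparse row layout), activations, rates and traces.

    Connectivity is fixed at initialization: output neuron j is connected
    to inputs ``conn_idx[j]`` with weights ``w[j]``; all other synapses are
    structurally absent (exactly zero in the dense view).  Each weight row
    is kept at unit Euclidean norm by the plasticity rules.
    """

    conn_idx: np.ndarray  # (n_out, K) int — afferent input indices per neuron
    w: np.ndarray  # (n_out, K) float — weights of connected synapses
    n_in: int
    h: np.ndarray = field(default=None)  # type: ignore[assignment]
    r: np.ndarray = field(default=None)  # type: ignore[assignment]
    q: np.ndarray = field(default=None)  # type: ignore[assignment]
    clock: float = 0.0

    def __post_init__(self):
        n_out = self.conn_idx.shape[0]
        if self.w.shape != self.conn_idx.shape:
            raise ValueError("w and conn_idx must have matching shapes")
        for name in ("h", "r", "q"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n_out))

    @property
    def n_out(self) -> int:
        return self.conn_idx.shape[0]

    @property
    def fan_in(self) -> int:
        return self.conn_idx.shape[1]

    @property
    def connectivity_mask(self) -> np.ndarray:
        mask = np.zeros((self.n_out, self.n_in), dtype=bool)
        np.put_along_axis(mask, self.conn_idx, True, axis=1)
        return mask

    @property
    def weights(self) -> np.ndarray:
        """Dense (n_out, n_in) weight matrix; masked entries are exactly 0."""
        dense = np.zeros((self.n_out, self.n_in))
        np.put_along_axis(dense, self.conn_idx, self.w, axis=1)
        return dense

    def drive(self, input_rates: np.ndarray) -> np.ndarray:
        """Synaptic drive sum_i w_ji r'_i per output neuron."""
        return np.einsum("jk,jk->j", self.w, input_rates[self.conn_idx])

    def reset(self) -> None:
        self.h[:] = 0.0
        self.r[:] = 0.0
        self.q[:] = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(
            conn_idx=self.conn_idx.copy(),
            w=self.w.copy(),
            n_in=self.n_in,
            h=self.h.copy(),
            r=self.r.copy(),
            q=self.q.copy(),
            clock=self.clock,
        )


def activation_step(
    state: NetworkState, input_rates: np.ndarray, params: DynamicsParams
) -> np.ndarray:
    """One Euler step of the activation equation; updates and returns h."""
    if len(input_rates) != state.n_in:
        raise ValueError("input_rates length does not match the input population")
    if not np.all(np.isfinite(input_rates)):
        raise ValueError("non-finite input rates")
    dt = params.dt
    state.h += (dt / params.tau_ms) * (state.drive(input_rates) - state.h)
    state.clock += dt
    return state.h


def firing_rates(activations: np.ndarray, params: DynamicsParams) -> np.ndarray:
    """Sigmoid rates with a dynamic percentile threshold (competition).

    theta is the pi-th percentile of the instantaneous activation
    distribution (linear interpolation between order statistics) when
    competition is enabled, else the fixed configured threshold.
    """
    activations = np.asarray(activations)
    if activations.size == 0:
        raise ValueError("empty output layer")
    if params.competition:
        theta = np.percentile(activations, params.percentile)
    else:
        theta = params.theta_fixed
    return expit(params.slope * (activations - theta))


def trace_step(state: NetworkState, params: DynamicsParams) -> np.ndarray:
    """One Euler step of the trace equation; updates and returns q."""
    state.q += (params.dt / params.tau_trace_ms) * (state.r - state.q)
    return state.q


def settle_and_read(
    state: NetworkState,
    input_rates: np.ndarray,
    params: DynamicsParams,
    duration_ms: float,
) -> np.ndarray:
    """Integrate a constant input from rest and return the final rates.

    State (h, r, q) is reset to zero before and after, so repeated calls
    are order-independent.  Learning is never applied here.  Because the
    output layer has no recurrent synapses, the rates do not feed back into
    the activations, so r (and q) need only be evaluated at readout.
    """
    dt = params.dt
    if duration_ms < dt:
        raise ValueError("settle duration shorter than one integration step")
    if len(input_rates) != state.n_in:
        raise ValueError("input_rates length does not match the input population")
    state.reset()
    drive = state.drive(input_rates)
    a = dt / params.tau_ms
    h = np.zeros_like(drive)
    for _ in range(int(np.floor(duration_ms / dt + 1e-9))):
        h += a * (drive - h)
    rates = firing_rates(h, params)
    state.reset()
    return rates
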