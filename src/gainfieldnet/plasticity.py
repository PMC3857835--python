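"""Connectivity initialization and synaptic learning rules.

Every output neuron receives the same number of afferents, round(f * n_in),
from its own randomly drawn subset of the input population.  Weights start
i.i.d. uniform on the init interval and each weight row is renormalized to
unit Euclidean norm, as is standard in competitive networks.

Two local learning rules are implemented, both Euler-discretized with the
simulation step dt and followed by row renormalization (which prevents
unbounded weight growth and makes learning competitive):

    trace rule    dw_ji/dt = rho * q_j * r'_i
    hebbian rule  dw_ji/dt = rho * r_j * r'_i

The trace rule's postsynaptic factor is the memory trace q_j, which binds
input patterns that occur close together in time onto the same output
neuron; the Hebbian rule uses the instantaneous rate r_j, whose temporal
smearing by the activation time constant provides an implicit trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import NetworkState

__all__ = ["PlasticityParams", "init_network", "learning_step", "renormalize_rows"]

RULES = ("trace", "hebbian")


@dataclass(frozen=True)
class PlasticityParams:
    rule: str = "trace"
    learning_rate: float = 0.05  # rho, 1/s
    connectivity_fraction: float = 0.10  # f, fraction of inputs each neuron sees
    init_weight_interval: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self):
        if self.rule not in RULES:
            raise ValueError(f"unknown learning rule {self.rule!r}; expected one of {RULES}")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be non-negative")
        if not (0.0 < self.connectivity_fraction <= 1.0):
            raise ValueError("connectivity_fraction must be in (0, 1]")
        lo, hi = self.init_weight_interval
        if not (0.0 <= lo < hi):
            raise ValueError("init interval must satisfy 0 <= low < high")


def init_network(
    n_out: int, n_in: int, params: PlasticityParams, rng: np.random.Generator
) -> NetworkState:
    """Random partial connectivity with unit-norm uniform random weight rows."""
    k = int(round(params.connectivity_fraction * n_in))
    if k < 1:
        raise ValueError(
            f"connectivity_fraction {params.connectivity_fraction} of {n_in} inputs "
            "rounds to zero afferents per neuron"
        )
    conn_idx = np.empty((n_out, k), dtype=np.intp)
    for j in range(n_out):
        conn_idx[j] = np.sort(rng.choice(n_in, size=k, replace=False))
    lo, hi = params.init_weight_interval
    w = rng.uniform(lo, hi, size=(n_out, k))
    state = NetworkState(conn_idx=conn_idx, w=w, n_in=n_in)
    renormalize_rows(state)
    return state


def renormalize_rows(state: NetworkState) -> np.ndarray:
    """Divide each weight row by its Euclidean norm over connected synapses."""
    norms = np.sqrt(np.einsum("jk,jk->j", state.w, state.w))
    bad = np.flatnonzero(norms == 0.0)
    if bad.size:
        raise ValueError(f"zero-norm weight row for output neuron(s) {bad.tolist()}")
    state.w /= norms[:, None]
    return state.w


def learning_step(
    state: NetworkState,
    input_rates: np.ndarray,
    params: PlasticityParams,
    dt_ms: float,
) -> np.ndarray:
    """One Euler step of the active rule on connected synapses, then renormalize.

    The postsynaptic factor is the trace q_j (trace rule) or the rate r_j
    (hebbian rule); the presynaptic factor is the input rate r'_i.  rho is
    per second, dt in ms.
    """
    if params.rule == "trace":
        post = state.q
    elif params.rule == "hebbian":
        post = state.r
    else:  # pragma: no cover - guarded by PlasticityParams
        raise ValueError(f"unknown learning rule {params.rule!r}")
    pre = input_rates[state.conn_idx]  # (n_out, K)
    state.w += (dt_ms / 1000.0) * params.learning_rate * post[:, None] * pre
    return renormalize_rows(state)
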