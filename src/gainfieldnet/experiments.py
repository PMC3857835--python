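"""Full runs (init -> train -> test -> analyze) and the control experiments.

``run_training`` integrates the coupled activation/rate/trace equations
through the saccade-and-fixation protocol while applying the synaptic
learning rule at every Euler step.  Network state evolves continuously
within an epoch (the trace carrying activity across saccades and target
periods is the learning mechanism) and is reset at epoch boundaries and
during testing.

``run_experiment`` reproduces the study designs: the baseline
self-organization run (trained vs untrained), decoupled inputs, competition
turned off, time-constant sweeps for the Hebbian and trace rules, and the
fixation-sequence-length sweep.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    NeuronMetrics,
    PopulationSummary,
    ResponseTensor,
    analyze_population,
    metrics_to_frame,
)
from .config import SimulationConfig
from .dynamics import (
    DynamicsParams,
    NetworkState,
    activation_step,
    firing_rates,
    settle_and_read,
    trace_step,
)
from .inputs import (
    InputPopulation,
    build_coupled_grid,
    build_decoupled_population,
    response,
    response_series,
)
from .plasticity import PlasticityParams, init_network, learning_step
from .protocol import TestGrid, TrainingSchedule, make_test_conditions, make_training_period, resample_to_step

__all__ = [
    "ExperimentSpec",
    "RunRecord",
    "build_population",
    "run_training",
    "run_testing",
    "run_experiment",
    "write_outputs",
    "EXPERIMENT_NAMES",
]

EXPERIMENT_NAMES = (
    "baseline",
    "decoupled",
    "no_competition",
    "tau_sweep_hebbian",
    "tauq_sweep_trace",
    "fixation_sweep",
)

_SERIES_CHUNK = 1024  # stimulus steps per input-rate evaluation block


@dataclass
class ExperimentSpec:
    name: str
    config: SimulationConfig
    sweep_values: tuple[float, ...] = ()
    seeds: tuple[int, ...] = (0,)

    def __post_init__(self):
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(f"unknown experiment {self.name!r}; expected one of {EXPERIMENT_NAMES}")
        # fixation_sweep may leave sweep_values empty (meaning 1 .. configured N_f)
        if "sweep" in self.name and self.sweep_values and len(self.sweep_values) < 3:
            raise ValueError("sweep experiments need at least 3 sweep values")
        if self.name in ("tau_sweep_hebbian", "tauq_sweep_trace") and not self.sweep_values:
            raise ValueError("time-constant sweeps need explicit sweep values")


@dataclass
class RunRecord:
    label: str
    config: SimulationConfig
    seed: int
    state: NetworkState
    tensor: ResponseTensor
    metrics: list[NeuronMetrics]
    summary: PopulationSummary
    epoch_summaries: list[PopulationSummary] = field(default_factory=list)
    wall_time_s: float = 0.0


# ---------------------------------------------------------------------------
# assembly from config


def build_population(config: SimulationConfig) -> InputPopulation:
    ic = config.input
    if ic.mode == "coupled":
        return build_coupled_grid(
            ic.retinal_range, ic.eye_range, ic.step, ic.sigma_retinal, ic.sigma_eye
        )
    return build_decoupled_population(
        ic.retinal_range, ic.eye_range, ic.step, ic.sigma_retinal, ic.sigma_eye
    )


def _dynamics_params(config: SimulationConfig) -> DynamicsParams:
    d = config.dynamics
    return DynamicsParams(
        tau_ms=d.tau_ms,
        tau_trace_ms=d.tau_trace_ms,
        slope=d.slope,
        percentile=d.percentile,
        competition=d.competition,
        theta_fixed=d.theta_fixed,
        dt_ms=d.dt_ms,
    )


def _plasticity_params(config: SimulationConfig) -> PlasticityParams:
    p = config.plasticity
    return PlasticityParams(
        rule=p.rule,
        learning_rate=p.learning_rate,
        connectivity_fraction=p.connectivity_fraction,
        init_weight_interval=p.init_weight_interval,
    )


def _schedule(config: SimulationConfig) -> TrainingSchedule:
    p = config.protocol
    return TrainingSchedule(
        target_locations=p.target_locations,
        fixations_per_period=p.fixations_per_period,
        fixation_duration_ms=p.fixation_duration_ms,
        saccade_speed_deg_per_s=p.saccade_speed_deg_per_s,
        eye_sample_range=p.eye_sample_range,
        stimulus_rate_khz=p.stimulus_rate_khz,
        retinal_range=config.input.retinal_range,
    )


def _test_grid(config: SimulationConfig) -> TestGrid:
    t = config.test
    return TestGrid.from_range(t.eye_positions, t.head_range, t.head_step, t.settle_ms)


# ---------------------------------------------------------------------------
# training / testing


def _train_period(
    state: NetworkState,
    pop: InputPopulation,
    traj,
    dyn: DynamicsParams,
    plas: PlasticityParams,
) -> None:
    """Integrate one training period with learning, in stimulus chunks."""
    dt = dyn.dt
    n = len(traj.times)
    learn = plas.learning_rate > 0.0
    for start in range(0, n, _SERIES_CHUNK):
        stop = min(start + _SERIES_CHUNK, n)
        series = response_series(
            pop, traj.retinal_loc[start:stop], traj.eye_pos[start:stop]
        )
        for t in range(stop - start):
            r_in = series[t]
            activation_step(state, r_in, dyn)
            state.r = firing_rates(state.h, dyn)
            trace_step(state, dyn)
            if learn:
                learning_step(state, r_in, plas, dt)
        if not np.all(np.isfinite(state.h)):
            raise FloatingPointError("network activations became non-finite during training")


def run_training(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    state: Optional[NetworkState] = None,
    epoch_callback=None,
) -> tuple[NetworkState, list[PopulationSummary]]:
    """Train a network through ``config.run.epochs`` epochs.

    Per epoch, the target locations are visited in listed (or shuffled)
    order; h, r, q are reset at epoch boundaries only.  When
    ``config.run.record_epochs`` is set, the network is tested and analyzed
    after every epoch and the per-epoch summaries are returned.
    """
    if rng is None:
        rng = np.random.default_rng(config.run.seed)
    init_rng, proto_rng = rng.spawn(2)
    pop = build_population(config)
    dyn = _dynamics_params(config)
    plas = _plasticity_params(config)
    schedule = _schedule(config)
    if state is None:
        state = init_network(config.run.n_output, pop.n, plas, init_rng)
    summaries: list[PopulationSummary] = []
    for epoch in range(config.run.epochs):
        state.reset()
        targets = list(schedule.target_locations)
        if config.protocol.shuffle_targets:
            proto_rng.shuffle(targets)
        for head_loc in targets:
            traj = make_training_period(schedule, head_loc, proto_rng)
            traj = resample_to_step(traj, dyn.dt)
            _train_period(state, pop, traj, dyn, plas)
        if config.run.record_epochs:
            tensor = run_testing(state, _test_grid(config), dyn, pop)
            _, summary = analyze_population(
                tensor, config.protocol.target_locations, config.run.rf_threshold_fraction
            )
            summaries.append(summary)
            if epoch_callback is not None:
                epoch_callback(epoch, summary)
    return state, summaries


def run_testing(
    state: NetworkState,
    grid: TestGrid,
    params: DynamicsParams,
    pop: InputPopulation,
) -> ResponseTensor:
    """Settle-and-read every (eye, head) condition with resets; learning off."""
    conditions = make_test_conditions(grid)
    n_e, n_h = len(grid.eye_positions), len(grid.head_locations)
    rates = np.empty((state.n_out, n_e, n_h))
    for idx, (eye, head, traj) in enumerate(conditions):
        r_in = response(pop, head - eye, eye)
        rates[:, idx // n_h, idx % n_h] = settle_and_read(state, r_in, params, grid.settle_ms)
    return ResponseTensor(
        rates=rates,
        eye_positions=np.asarray(grid.eye_positions),
        head_locations=np.asarray(grid.head_locations),
    )


def run_full(config: SimulationConfig, label: str, seed: Optional[int] = None) -> RunRecord:
    """Init -> train -> test -> analyze, bundled into a RunRecord."""
    if seed is not None:
        config = config.replace(run={"seed": seed})
    started = time.perf_counter()
    rng = np.random.default_rng(config.run.seed)
    state, epoch_summaries = run_training(config, rng)
    pop = build_population(config)
    dyn = _dynamics_params(config)
    tensor = run_testing(state, _test_grid(config), dyn, pop)
    metrics, summary = analyze_population(
        tensor, config.protocol.target_locations, config.run.rf_threshold_fraction
    )
    return RunRecord(
        label=label,
        config=config,
        seed=config.run.seed,
        state=state,
        tensor=tensor,
        metrics=metrics,
        summary=summary,
        epoch_summaries=epoch_summaries,
        wall_time_s=time.perf_counter() - started,
    )


# ---------------------------------------------------------------------------
# the named experiments


def run_experiment(spec: ExperimentSpec) -> list[RunRecord]:
    """Dispatch one of the named study designs; one record per (variant, seed)."""
    records: list[RunRecord] = []
    base = spec.config
    for seed in spec.seeds:
        if spec.name == "baseline":
            records.append(run_full(base.replace(run={"epochs": 0}), "baseline_untrained", seed))
            records.append(run_full(base, "baseline_trained", seed))
        elif spec.name == "decoupled":
            cfg = base.replace(input={"mode": "decoupled"})
            records.append(run_full(cfg, "decoupled", seed))
        elif spec.name == "no_competition":
            cfg = base.replace(dynamics={"competition": False, "theta_fixed": 0.0})
            records.append(run_full(cfg, "no_competition", seed))
        elif spec.name == "tau_sweep_hebbian":
            for tau in spec.sweep_values:
                cfg = base.replace(
                    dynamics={"tau_ms": float(tau)}, plasticity={"rule": "hebbian"}
                )
                records.append(run_full(cfg, f"hebbian_tau_{tau:g}ms", seed))
        elif spec.name == "tauq_sweep_trace":
            for tau_q in spec.sweep_values:
                cfg = base.replace(dynamics={"tau_trace_ms": float(tau_q)})
                records.append(run_full(cfg, f"trace_tauq_{tau_q:g}ms", seed))
        elif spec.name == "fixation_sweep":
            n_max = int(max(spec.sweep_values)) if spec.sweep_values else base.protocol.fixations_per_period
            values = (
                [int(v) for v in spec.sweep_values]
                if spec.sweep_values
                else list(range(1, n_max + 1))
            )
            for n_f in values:
                cfg = base.replace(protocol={"fixations_per_period": int(n_f)})
                records.append(run_full(cfg, f"fixations_{n_f}", seed))
    return records


# ---------------------------------------------------------------------------
# outputs


def _summary_frame(record: RunRecord) -> pd.DataFrame:
    frames = []
    stages = list(enumerate(record.epoch_summaries, start=1)) + [("final", record.summary)]
    for stage, summary in stages:
        frame = summary.to_frame()
        frame.insert(0, "epoch", stage)
        frame["head_centered_rate"] = summary.head_centered_rate
        frame["coverage"] = np.nan if summary.coverage is None else summary.coverage
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def write_outputs(record: RunRecord, out_dir: str | Path) -> dict[str, Path]:
    """Write config, per-neuron metrics, per-epoch summaries, state and a log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["config"] = out / "config.yaml"
    record.config.save(paths["config"])

    paths["metrics"] = out / "metrics.csv"
    with open(paths["metrics"], "w") as fh:
        fh.write(
            "# per-neuron reference-frame metrics; "
            f"head_step_deg={record.tensor.head_step:g}, "
            f"rf_threshold_fraction={record.config.run.rf_threshold_fraction:g}, "
            "sd=population; excluded neurons carry empty metric fields\n"
        )
        metrics_to_frame(record.metrics).to_csv(fh, index=False)

    paths["summaries"] = out / "summaries.csv"
    _summary_frame(record).to_csv(paths["summaries"], index=False)

    paths["state"] = out / "state.npz"
    np.savez(
        paths["state"],
        conn_idx=record.state.conn_idx,
        w=record.state.w,
        n_in=record.state.n_in,
        h=record.state.h,
        r=record.state.r,
        q=record.state.q,
        clock=record.state.clock,
    )

    paths["responses"] = out / "responses.npz"
    np.savez(
        paths["responses"],
        rates=record.tensor.rates,
        eye_positions=record.tensor.eye_positions,
        head_locations=record.tensor.head_locations,
    )

    paths["log"] = out / "run.json"
    paths["log"].write_text(
        json.dumps(
            {
                "label": record.label,
                "seed": record.seed,
                "config_sha256": hashlib.sha256(
                    json.dumps(record.config.to_dict(), sort_keys=True).encode()
                ).hexdigest(),
                "gainfieldnet_version": __version__,
                "numpy_version": np.__version__,
                "wall_time_s": record.wall_time_s,
                "n_neurons": record.summary.n_neurons,
                "head_centered_rate": record.summary.head_centered_rate,
            },
            indent=2,
        )
    )
    return paths


def load_state(path: str | Path) -> NetworkState:
    data = np.load(path)
    return NetworkState(
        conn_idx=data["conn_idx"],
        w=data["w"],
        n_in=int(data["n_in"]),
        h=data["h"],
        r=data["r"],
        q=data["q"],
        clock=float(data["clock"]),
    )


def load_tensor(path: str | Path) -> ResponseTensor:
    data = np.load(path)
    return ResponseTensor(
        rates=data["rates"],
        eye_positions=data["eye_positions"],
        head_locations=data["head_locations"],
    )
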