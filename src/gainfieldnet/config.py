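"""Run configuration for the self-organizing gain-field network.

A :class:`SimulationConfig` bundles every tunable quantity of a simulation:
the input-population geometry, the saccade-and-fixation training protocol,
the testing grid, the output-layer dynamics, and the plasticity rule.
Configs round-trip through YAML so that every run can be reproduced from
its serialized record.

Two profiles are provided: :func:`SimulationConfig.full_scale` is the full-size
model (12261 input neurons, 900 output neurons), and
:func:`SimulationConfig.reduced_scale` is a ~1/50-state-size profile that
preserves every structural feature (1-degree grids, even target spacing,
visibility of all targets at all eye positions, commensurate test grids)
while being cheap enough for routine testing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "InputConfig",
    "ProtocolConfig",
    "TestConfig",
    "DynamicsConfig",
    "PlasticityConfig",
    "RunConfig",
    "SimulationConfig",
]


@dataclass
class InputConfig:
    """Geometry and tuning of the input population.

    ``retinal_range`` / ``eye_range`` are the spans of retinal location and
    eye position (degrees) covered by the preference grid; ``step`` is the
    grid spacing.  ``sigma_retinal`` / ``sigma_eye`` are the Gaussian tuning
    widths (sigma_x, sigma_e).  ``mode`` selects coupled gain-field neurons
    or the decoupled control (half visual-only, half eye-only).
    """

    retinal_range: tuple[float, float] = (-100.0, 100.0)
    eye_range: tuple[float, float] = (-30.0, 30.0)
    step: float = 1.0
    sigma_retinal: float = 6.0
    sigma_eye: float = 6.0
    mode: str = "coupled"  # "coupled" | "decoupled"


@dataclass
class ProtocolConfig:
    """Training protocol: targets fixed in head space while the eyes saccade."""

    target_locations: tuple[float, ...] = (-56.0, -40.0, -24.0, -8.0, 8.0, 24.0, 40.0, 56.0)
    fixations_per_period: int = 15
    fixation_duration_ms: float = 300.0
    saccade_speed_deg_per_s: float = 400.0
    eye_sample_range: tuple[float, float] = (-27.0, 27.0)
    stimulus_rate_khz: float = 1.0
    shuffle_targets: bool = False


@dataclass
class TestConfig:
    """Static testing grid: all (eye position, head location) combinations."""

    eye_positions: tuple[float, ...] = (-18.0, -6.0, 6.0, 18.0)
    head_range: tuple[float, float] = (-60.0, 60.0)
    head_step: float = 2.0
    settle_ms: float = 300.0


@dataclass
class DynamicsConfig:
    """Output-layer dynamics: activation/trace time constants and competition.

    ``dt_ms=None`` resolves to one tenth of the fastest time constant.
    ``percentile`` (pi) sets the dynamic firing threshold; with
    ``competition=False`` the threshold is pinned at ``theta_fixed``.
    """

    tau_ms: float = 10.0
    tau_trace_ms: float = 100.0
    slope: float = 10.0
    percentile: float = 95.0
    competition: bool = True
    theta_fixed: float = 0.0
    dt_ms: Optional[float] = None


@dataclass
class PlasticityConfig:
    rule: str = "trace"  # "trace" | "hebbian"
    learning_rate: float = 0.05  # rho, 1/s
    connectivity_fraction: float = 0.10
    init_weight_interval: tuple[float, float] = (0.0, 1.0)


@dataclass
class RunConfig:
    n_output: int = 900
    epochs: int = 20
    record_epochs: bool = False
    rf_threshold_fraction: float = 0.5  # phi for receptive-field size
    seed: int = 0


@dataclass
class SimulationConfig:
    input: InputConfig = field(default_factory=InputConfig)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    test: TestConfig = field(default_factory=TestConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    plasticity: PlasticityConfig = field(default_factory=PlasticityConfig)
    run: RunConfig = field(default_factory=RunConfig)

    @classmethod
    def full_scale(cls, **overrides) -> "SimulationConfig":
        """Full-size model: 201 x 61 = 12261 inputs, 900 outputs."""
        cfg = cls()
        return cfg.replace(**overrides)

    @classmethod
    def reduced_scale(cls, **overrides) -> "SimulationConfig":
        """Small profile preserving all structural features of the protocol."""
        cfg = cls(
            input=InputConfig(
                retinal_range=(-40.0, 40.0),
                eye_range=(-10.0, 10.0),
                step=1.0,
                sigma_retinal=4.0,
                sigma_eye=4.0,
            ),
            protocol=ProtocolConfig(
                target_locations=(-21.0, -7.0, 7.0, 21.0),
                fixations_per_period=8,
                fixation_duration_ms=300.0,
                saccade_speed_deg_per_s=400.0,
                eye_sample_range=(-9.0, 9.0),
            ),
            test=TestConfig(
                eye_positions=(-6.0, -2.0, 2.0, 6.0),
                head_range=(-30.0, 30.0),
                head_step=2.0,
                settle_ms=300.0,
            ),
            run=RunConfig(n_output=150, epochs=10, record_epochs=True),
        )
        return cfg.replace(**overrides)

    # -- convenience -------------------------------------------------------

    def replace(self, **section_overrides) -> "SimulationConfig":
        """Return a copy with whole sections or section fields replaced.

        Accepts either section instances (``dynamics=DynamicsConfig(...)``)
        or dicts of field overrides (``dynamics={"tau_ms": 100.0}``).
        """
        parts = {}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if f.name in section_overrides:
                override = section_overrides.pop(f.name)
                if isinstance(override, dict):
                    value = dataclasses.replace(value, **override)
                else:
                    value = override
            else:
                value = dataclasses.replace(value)
            parts[f.name] = value
        if section_overrides:
            raise TypeError(f"unknown config sections: {sorted(section_overrides)}")
        return SimulationConfig(**parts)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        sections = {}
        for f in dataclasses.fields(cls):
            section_cls = f.default_factory  # type: ignore[misc]
            raw = dict(data.get(f.name, {}))
            kwargs = {}
            for sf in dataclasses.fields(section_cls()):
                if sf.name in raw:
                    value = raw.pop(sf.name)
                    if isinstance(value, list):
                        value = tuple(value)
                    kwargs[sf.name] = value
            if raw:
                raise ValueError(f"unknown keys in section '{f.name}': {sorted(raw)}")
            sections[f.name] = section_cls(**kwargs)
        return cls(**sections)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
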