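"""Reference-frame and receptive-field analysis of testing responses.

All statistics consume a :class:`ResponseTensor`: firing rates indexed by
(neuron, eye position, head-centered location), with eye positions sorted
ascending and head locations on a uniform grid of spacing dh.

Per neuron:

* **head-centeredness** (lambda_h): mean Pearson correlation, over all
  unordered pairs of eye positions, of the full head-centered response
  vectors.  A value of 1 means the response profile over head space is
  identical at every eye position.
* **eye-centeredness** (lambda_e): the same statistic after re-aligning the
  response vectors to the common window of *retinal* locations tested at
  every eye position.  A purely retinotopic neuron scores 1 here.
* **RFI** (reference-frame index): lambda_h - lambda_e.  Positive values
  classify the neuron as head-centered, negative as eye-centered, zero as
  undetermined.
* **RF location**: per-eye-position centre of mass of the response over
  head space, averaged over eye positions with a response.
* **RF size**: total length of head space where the piecewise-linear
  interpolated response exceeds a fraction phi of the neuron's global
  maximum rate, averaged over eye positions that reach the threshold.

Population level: mean/SD summaries over analyzable neurons (and over the
head-centered subset), the head-centered rate, and **coverage** — the
normalized entropy of the assignment of head-centered neurons to their
nearest training locations (1 = perfectly even; undefined, i.e. "no
coverage", if any training location is unrepresented).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ResponseTensor",
    "NeuronMetrics",
    "PopulationSummary",
    "head_centeredness",
    "eye_alignment_indices",
    "eye_centeredness",
    "rfi",
    "rf_location",
    "rf_size",
    "coverage",
    "analyze_neuron",
    "analyze_population",
    "summarize_population",
    "metrics_to_frame",
]

METRIC_NAMES = ("head_centeredness", "eye_centeredness", "rfi", "rf_location", "rf_size")

#: rates are on a [0, 1] scale; a (sub)vector whose maximum stays below this
#: floor carries no response for the purposes of the exclusion rules (the
#: logistic rate function never reaches exactly zero)
RESPONSE_FLOOR = 0.01


@dataclass(frozen=True)
class ResponseTensor:
    """Testing rates, shape (n_neurons, n_eye_positions, n_head_locations)."""

    rates: np.ndarray
    eye_positions: np.ndarray
    head_locations: np.ndarray

    def __post_init__(self):
        rates = np.asarray(self.rates, dtype=float)
        eyes = np.asarray(self.eye_positions, dtype=float)
        heads = np.asarray(self.head_locations, dtype=float)
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "eye_positions", eyes)
        object.__setattr__(self, "head_locations", heads)
        if rates.ndim != 3 or rates.shape[1] != len(eyes) or rates.shape[2] != len(heads):
            raise ValueError("rates must have shape (neurons, eye positions, head locations)")
        if np.any(rates < -1e-12) or np.any(rates > 1 + 1e-12):
            raise ValueError("rates must lie in [0, 1]")
        if np.any(np.diff(eyes) < 0):
            raise ValueError("eye positions must be sorted ascending")
        if len(heads) >= 2:
            dh = np.diff(heads)
            if dh[0] <= 0 or not np.allclose(dh, dh[0], rtol=0, atol=1e-9):
                raise ValueError("head locations must be uniformly spaced ascending")

    @property
    def n_neurons(self) -> int:
        return self.rates.shape[0]

    @property
    def n_eyes(self) -> int:
        return self.rates.shape[1]

    @property
    def n_heads(self) -> int:
        return self.rates.shape[2]

    @property
    def head_step(self) -> float:
        return float(self.head_locations[1] - self.head_locations[0])


@dataclass
class NeuronMetrics:
    neuron: int
    head_centeredness: Optional[float] = None
    eye_centeredness: Optional[float] = None
    rfi: Optional[float] = None
    rf_location: Optional[float] = None
    rf_size: Optional[float] = None
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class PopulationSummary:
    """Mean/SD of each metric over all analyzable neurons and the RFI>0 subset.

    ``stats[metric]`` is a dict with keys mean_all, sd_all, mean_hc, sd_hc
    (population SD, i.e. divide by n).  ``coverage`` is None when some
    training location has no assigned head-centered neuron ("no coverage").
    """

    n_neurons: int
    n_analyzable: int
    n_excluded: int
    n_head_centered: int
    head_centered_rate: float
    coverage: Optional[float]
    stats: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for metric, s in self.stats.items():
            rows.append({"metric": metric, **s})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# per-neuron metrics


def _pairwise_mean_correlation(
    vectors: list[np.ndarray], modulation_floor: float = RESPONSE_FLOOR
) -> Optional[float]:
    """Mean Pearson r over unordered pairs; effectively constant vectors dropped.

    A vector whose dynamic range stays below ``modulation_floor`` (rates are
    on a [0, 1] scale) carries no resolvable tuning — e.g. the residual
    ripple of a saturated sigmoid — and correlating it would return noise,
    so any pair containing one is dropped, as are exactly-constant pairs.
    """
    corrs = []
    for a, b in combinations(vectors, 2):
        if np.ptp(a) < modulation_floor or np.ptp(b) < modulation_floor:
            continue
        corrs.append(float(np.corrcoef(a, b)[0, 1]))
    if not corrs:
        return None
    return float(np.mean(corrs))


def head_centeredness(tensor: ResponseTensor, neuron: int) -> Optional[float]:
    """lambda_h: stability of full head-centered response vectors across eyes."""
    if tensor.n_eyes < 2:
        return None
    vectors = [tensor.rates[neuron, i] for i in range(tensor.n_eyes)]
    return _pairwise_mean_correlation(vectors)


def eye_alignment_indices(
    eye_positions: np.ndarray, head_locations: np.ndarray
) -> tuple[np.ndarray, int]:
    """Start index b_i and common length L of the retinally aligned subvectors.

    At eye position e the tested head locations h_1..h_T correspond to
    retinal locations h_k - e; the intersection of these retinal ranges
    over all eye positions is covered by the subvector [b_i, b_i + L) with
    b_i = (e_i - e_min)/dh and L = T - (e_max - e_min)/dh.  Eye spacings
    that are not integer multiples of dh are rejected (the index arithmetic
    would silently misalign).
    """
    eyes = np.asarray(eye_positions, dtype=float)
    heads = np.asarray(head_locations, dtype=float)
    t = len(heads)
    if t < 2:
        raise ValueError("need at least two head locations")
    dh = heads[1] - heads[0]
    span = eyes.max() - eyes.min()
    if span >= heads[-1] - heads[0]:
        raise ValueError("eye-position span leaves no common retinal window")
    offsets = (eyes - eyes.min()) / dh
    if np.any(np.abs(offsets - np.round(offsets)) > 1e-9):
        raise ValueError("eye-position spacing is not commensurate with the head grid")
    b = np.round(offsets).astype(int)
    length = t - int(round(span / dh))
    return b, length


def eye_centeredness(
    tensor: ResponseTensor, neuron: int, response_floor: float = RESPONSE_FLOOR
) -> Optional[float]:
    """lambda_e: stability of the retinally aligned response subvectors.

    Subvectors with no response (maximum below ``response_floor``) are
    excluded pairwise; returns None when fewer than two responsive
    subvectors with variance remain.
    """
    if tensor.n_eyes < 2:
        return None
    b, length = eye_alignment_indices(tensor.eye_positions, tensor.head_locations)
    subvectors = [
        tensor.rates[neuron, i, b[i] : b[i] + length] for i in range(tensor.n_eyes)
    ]
    responsive = [v for v in subvectors if v.max() >= response_floor]
    if len(responsive) < 2:
        return None
    return _pairwise_mean_correlation(responsive)


def has_aligned_response(
    tensor: ResponseTensor, neuron: int, response_floor: float = RESPONSE_FLOOR
) -> bool:
    """True when some aligned subvector carries a response anywhere."""
    b, length = eye_alignment_indices(tensor.eye_positions, tensor.head_locations)
    return any(
        tensor.rates[neuron, i, b[i] : b[i] + length].max() >= response_floor
        for i in range(tensor.n_eyes)
    )


def rfi(lambda_h: Optional[float], lambda_e: Optional[float]) -> Optional[float]:
    """Reference-frame index lambda_h - lambda_e; None if either is undefined."""
    if lambda_h is None or lambda_e is None:
        return None
    return lambda_h - lambda_e


def rf_location(
    tensor: ResponseTensor, neuron: int, response_floor: float = 0.0
) -> Optional[float]:
    """Centre of mass over head space per eye position, averaged over
    eye positions with positive total response (eye positions whose
    response stays below ``response_floor`` everywhere are silent)."""
    r = tensor.rates[neuron]  # (E, T)
    totals = r.sum(axis=1)
    responsive = (totals > 0.0) & (r.max(axis=1) >= response_floor)
    if not responsive.any():
        return None
    coms = (r[responsive] @ tensor.head_locations) / totals[responsive]
    return float(np.mean(coms))


def _above_threshold_length(values: np.ndarray, grid: np.ndarray, psi: float) -> float:
    """Total length where the piecewise-linear interpolant of ``values`` on
    ``grid`` is >= psi, clipped to the grid extent."""
    y0, y1 = values[:-1], values[1:]
    seg = np.diff(grid)
    a0, a1 = y0 >= psi, y1 >= psi
    length = np.where(a0 & a1, seg, 0.0).astype(float)
    partial = a0 ^ a1
    if partial.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (psi - y0[partial]) / (y1[partial] - y0[partial])
        frac = np.where(a1[partial], 1.0 - t, t)
        length[partial] = seg[partial] * frac
    return float(length.sum())


def rf_size(
    tensor: ResponseTensor, neuron: int, threshold_fraction: float = 0.5
) -> Optional[float]:
    """Receptive-field size (deg): above-threshold extent of the interpolated
    response over head space, averaged over eye positions reaching threshold.

    The threshold is psi = phi * (max rate over all eye positions and head
    locations).  Eye positions whose maximum stays below psi are excluded
    from the average; a fully silent neuron has undefined size.
    """
    if not (0.0 < threshold_fraction < 1.0):
        raise ValueError("threshold_fraction must lie in (0, 1)")
    r = tensor.rates[neuron]
    peak = r.max()
    if peak <= 0.0:
        return None
    psi = threshold_fraction * peak
    sizes = [
        _above_threshold_length(r[i], tensor.head_locations, psi)
        for i in range(tensor.n_eyes)
        if r[i].max() >= psi
    ]
    if not sizes:  # pragma: no cover - the argmax eye position always qualifies
        return None
    return float(np.mean(sizes))


# ---------------------------------------------------------------------------
# population level


def coverage(
    metrics: Sequence[NeuronMetrics], training_locations: Sequence[float]
) -> Optional[float]:
    """Normalized entropy of head-centered neurons over training locations.

    Each neuron with RFI > 0 and a defined RF location is assigned to its
    nearest training location (ties go to the more negative location).
    Returns None ("no coverage") when any location has no assigned neuron
    or there are no head-centered neurons at all.
    """
    locations = np.sort(np.asarray(training_locations, dtype=float))
    if len(locations) < 2:
        raise ValueError("need at least two training locations")
    assigned = [
        m.rf_location
        for m in metrics
        if m.rfi is not None and m.rfi > 0 and m.rf_location is not None
    ]
    if not assigned:
        return None
    counts = np.zeros(len(locations), dtype=int)
    for loc in assigned:
        counts[int(np.argmin(np.abs(locations - loc)))] += 1
    if np.any(counts == 0):
        return None
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum() / np.log(len(locations)))


def analyze_neuron(
    tensor: ResponseTensor,
    neuron: int,
    threshold_fraction: float = 0.5,
    response_floor: float = RESPONSE_FLOOR,
) -> NeuronMetrics:
    """All per-neuron metrics with the exclusion rules applied.

    A neuron with no response inside the aligned retinal window at any eye
    position is excluded from further analysis; RFI is defined only when
    both reference-frame metrics are.
    """
    m = NeuronMetrics(neuron=neuron)
    if not has_aligned_response(tensor, neuron, response_floor):
        m.excluded = True
        m.exclusion_reason = "no response in the aligned retinal window at any eye position"
        return m
    m.head_centeredness = head_centeredness(tensor, neuron)
    m.eye_centeredness = eye_centeredness(tensor, neuron, response_floor)
    m.rfi = rfi(m.head_centeredness, m.eye_centeredness)
    if m.rfi is None:
        m.excluded = True
        m.exclusion_reason = "reference-frame metrics undefined (zero-variance responses)"
        return m
    m.rf_location = rf_location(tensor, neuron, response_floor)
    m.rf_size = rf_size(tensor, neuron, threshold_fraction)
    return m


def analyze_population(
    tensor: ResponseTensor,
    training_locations: Sequence[float],
    threshold_fraction: float = 0.5,
    response_floor: float = RESPONSE_FLOOR,
) -> tuple[list[NeuronMetrics], "PopulationSummary"]:
    metrics = [
        analyze_neuron(tensor, j, threshold_fraction, response_floor)
        for j in range(tensor.n_neurons)
    ]
    return metrics, summarize_population(metrics, training_locations)


def _mean_sd(values: list[float]) -> tuple[float, float]:
    if not values:
        return float("nan"), float("nan")
    arr = np.asarray(values)
    return float(arr.mean()), float(arr.std())  # population SD (ddof=0)


def summarize_population(
    metrics: Sequence[NeuronMetrics], training_locations: Sequence[float]
) -> PopulationSummary:
    """Mean/SD per metric over analyzable neurons and the RFI > 0 subset."""
    if not metrics:
        raise ValueError("metrics list is empty")
    analyzable = [m for m in metrics if not m.excluded]
    head_centered = [m for m in analyzable if m.rfi is not None and m.rfi > 0]
    stats = {}
    for name in METRIC_NAMES:
        all_vals = [getattr(m, name) for m in analyzable if getattr(m, name) is not None]
        hc_vals = [getattr(m, name) for m in head_centered if getattr(m, name) is not None]
        mean_all, sd_all = _mean_sd(all_vals)
        mean_hc, sd_hc = _mean_sd(hc_vals)
        stats[name] = {
            "mean_all": mean_all,
            "sd_all": sd_all,
            "mean_hc": mean_hc,
            "sd_hc": sd_hc,
        }
    return PopulationSummary(
        n_neurons=len(metrics),
        n_analyzable=len(analyzable),
        n_excluded=len(metrics) - len(analyzable),
        n_head_centered=len(head_centered),
        head_centered_rate=len(head_centered) / len(metrics),
        coverage=coverage(metrics, training_locations),
        stats=stats,
    )


# ---------------------------------------------------------------------------
# serialization helpers


def metrics_to_frame(metrics: Sequence[NeuronMetrics]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "neuron": [m.neuron for m in metrics],
            **{name: [getattr(m, name) for m in metrics] for name in METRIC_NAMES},
            "excluded": [m.excluded for m in metrics],
            "exclusion_reason": [m.exclusion_reason for m in metrics],
        }
    )


def tensor_to_frame(tensor: ResponseTensor) -> pd.DataFrame:
    """Long-format (neuron, eye_deg, head_deg, rate) table."""
    n, e, t = tensor.rates.shape
    idx = np.indices((n, e, t))
    return pd.DataFrame(
        {
            "neuron": idx[0].ravel(),
            "eye_deg": tensor.eye_positions[idx[1].ravel()],
            "head_deg": tensor.head_locations[idx[2].ravel()],
            "rate": tensor.rates.ravel(),
        }
    )


def tensor_from_frame(frame: pd.DataFrame) -> ResponseTensor:
    neurons = np.sort(frame["neuron"].unique())
    eyes = np.sort(frame["eye_deg"].unique())
    heads = np.sort(frame["head_deg"].unique())
    pivot = frame.set_index(["neuron", "eye_deg", "head_deg"])["rate"]
    rates = pivot.reindex(
        pd.MultiIndex.from_product([neurons, eyes, heads])
    ).to_numpy().reshape(len(neurons), len(eyes), len(heads))
    if np.any(np.isnan(rates)):
        raise ValueError("long-format table does not cover the full (neuron, eye, head) grid")
    return ResponseTensor(rates=rates, eye_positions=eyes, head_locations=heads)
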