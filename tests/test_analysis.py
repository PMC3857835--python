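"""Reference-frame metrics, receptive-field statistics, coverage, summaries."""

from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gainfieldnet.analysis import (
    NeuronMetrics,
    ResponseTensor,
    analyze_neuron,
    coverage,
    eye_alignment_indices,
    eye_centeredness,
    head_centeredness,
    metrics_to_frame,
    rf_location,
    rf_size,
    rfi,
    summarize_population,
    tensor_from_frame,
    tensor_to_frame,
)
from conftest import gaussian_bump, head_centered_tensor, retinotopic_tensor


def make_tensor(rates, eyes, heads):
    return ResponseTensor(np.asarray(rates, float), np.asarray(eyes, float), np.asarray(heads, float))


# -- head-centeredness -------------------------------------------------------


def test_identical_bumps_give_perfect_head_centeredness():
    tensor = head_centered_tensor(n_neurons=3)
    for j in range(3):
        assert head_centeredness(tensor, j) == pytest.approx(1.0, abs=1e-12)


def test_anticorrelated_vectors_give_minus_one():
    heads = np.arange(-4.0, 5.0, 2.0)
    up = np.linspace(0, 1, len(heads))
    rates = np.stack([up, 1 - up])[None, :, :]
    tensor = make_tensor(rates, [-2.0, 2.0], heads)
    assert head_centeredness(tensor, 0) == pytest.approx(-1.0, abs=1e-12)


def test_head_centeredness_matches_bruteforce_pair_loop(rng):
    rates = rng.uniform(0, 1, size=(4, 5, 21))
    tensor = make_tensor(rates, [-4, -2, 0, 2, 4], np.arange(-20, 21, 2))
    for j in range(4):
        oracle = np.mean(
            [np.corrcoef(rates[j, a], rates[j, b])[0, 1] for a, b in combinations(range(5), 2)]
        )
        assert head_centeredness(tensor, j) == pytest.approx(oracle, abs=1e-12)


def test_single_eye_position_undefined():
    tensor = make_tensor(np.ones((1, 1, 5)) * 0.5, [0.0], np.arange(-4.0, 5.0, 2.0))
    assert head_centeredness(tensor, 0) is None


# -- alignment indices -------------------------------------------------------


def test_alignment_worked_example():
    b, length = eye_alignment_indices([-6.0, 6.0], np.arange(-60.0, 61.0, 2.0))
    assert length == 55
    assert b.tolist() == [0, 6]


def test_alignment_zero_shift_for_equal_eyes():
    heads = np.arange(-10.0, 11.0, 2.0)
    b, length = eye_alignment_indices([3.0, 3.0, 3.0], heads)
    assert length == len(heads)
    assert b.tolist() == [0, 0, 0]


def test_alignment_equals_bruteforce_grid_intersection(rng):
    """The subvector windows select exactly the intersection of the per-eye
    retinal grids, for random commensurate configurations."""
    for _ in range(100):
        dh = float(rng.choice([1.0, 2.0, 4.0]))
        t = int(rng.integers(10, 40))
        heads = dh * np.arange(t) - dh * t / 2
        eyes = np.sort(rng.choice(np.arange(-3, 4) * dh, size=rng.integers(2, 5), replace=True))
        if eyes.max() - eyes.min() >= heads[-1] - heads[0]:
            continue
        b, length = eye_alignment_indices(eyes, heads)
        grids = [set(np.round(heads - e, 9)) for e in eyes]
        intersection = sorted(set.intersection(*grids))
        for i, e in enumerate(eyes):
            window = np.round(heads[b[i] : b[i] + length] - e, 9)
            assert window.tolist() == intersection


def test_alignment_rejects_incommensurate_eyes():
    with pytest.raises(ValueError, match="commensurate"):
        eye_alignment_indices([-5.0, 6.0], np.arange(-60.0, 61.0, 2.0))


def test_alignment_rejects_empty_intersection():
    with pytest.raises(ValueError, match="window"):
        eye_alignment_indices([-20.0, 20.0], np.arange(-10.0, 11.0, 2.0))


# -- eye-centeredness --------------------------------------------------------


def test_retinotopic_neuron_has_perfect_eye_centeredness():
    tensor = retinotopic_tensor(n_neurons=3)
    for j in range(3):
        assert eye_centeredness(tensor, j) == pytest.approx(1.0, abs=1e-9)


def test_head_centered_bump_scores_higher_on_head_metric():
    tensor = head_centered_tensor(n_neurons=3, width=4.0)
    for j in range(3):
        lh = head_centeredness(tensor, j)
        le = eye_centeredness(tensor, j)
        assert lh == pytest.approx(1.0, abs=1e-12)
        assert le < lh


def test_all_silent_subvectors_excluded():
    heads = np.arange(-10.0, 11.0, 2.0)
    rates = np.zeros((1, 2, len(heads)))
    rates[0, :, 0] = 0.9  # response only at the leftmost head location,
    tensor = make_tensor(rates, [-4.0, 4.0], heads)  # outside both windows?
    b, length = eye_alignment_indices(tensor.eye_positions, tensor.head_locations)
    # window at eye -4 starts at 0 so it does include h_1; construct silence
    rates2 = np.zeros((1, 2, len(heads)))
    rates2[0, 1, 0] = 0.9  # eye +4 window starts at index 4: index 0 not seen
    rates2[0, 0, len(heads) - 1] = 0.9  # eye -4 window ends before the last index
    tensor2 = make_tensor(rates2, [-4.0, 4.0], heads)
    assert eye_centeredness(tensor2, 0) is None
    m = analyze_neuron(tensor2, 0)
    assert m.excluded and "aligned retinal window" in m.exclusion_reason


# -- RFI ---------------------------------------------------------------------


@pytest.mark.parametrize(
    "lh, le, expected",
    [(0.8, 0.2, 0.6), (0.4, 0.4, 0.0), (0.1, 0.9, -0.8)],
)
def test_rfi_difference_form(lh, le, expected):
    assert rfi(lh, le) == pytest.approx(expected, abs=1e-12)


def test_rfi_undefined_propagates():
    assert rfi(None, 0.5) is None
    assert rfi(0.5, None) is None


@settings(max_examples=100, deadline=None)
@given(
    width=st.floats(2.0, 8.0),
    center=st.floats(-15.0, 15.0),
    seed=st.integers(0, 2**16),
)
def test_rfi_sign_separates_constructed_families(width, center, seed):
    """Perfectly head-centered neurons get positive RFI, perfectly
    retinotopic neurons negative RFI, across random bump geometries."""
    rng = np.random.default_rng(seed)
    hc = head_centered_tensor(n_neurons=1, width=width, rng=rng)
    m = analyze_neuron(hc, 0)
    assert m.rfi is not None and m.rfi > 0
    rt = retinotopic_tensor(n_neurons=1, width=width, rng=rng)
    m = analyze_neuron(rt, 0)
    assert m.rfi is not None and m.rfi < 0


# -- RF location -------------------------------------------------------------


def test_rf_location_of_symmetric_bump():
    heads = np.arange(-30.0, 31.0, 2.0)
    bump = gaussian_bump(heads, 8.0, 5.0)
    tensor = make_tensor(np.tile(bump, (1, 4, 1)), [-6, -2, 2, 6], heads)
    # tiny asymmetric edge truncation of the Gaussian tails shifts the
    # centre of mass by well under the grid step
    assert rf_location(tensor, 0) == pytest.approx(8.0, abs=0.01)


def test_rf_location_weighted_mean_arithmetic():
    tensor = make_tensor(np.array([[[0.0, 0.25, 0.75]]]), [0.0], [-2.0, 0.0, 2.0])
    # centre of mass: (0.25 * 0 + 0.75 * 2) / 1.0 = 1.5
    assert rf_location(tensor, 0) == pytest.approx(1.5, abs=1e-12)


def test_rf_location_skips_silent_eye_positions():
    heads = np.array([-2.0, 0.0, 2.0])
    rates = np.zeros((1, 4, 3))
    rates[0, :3, :] = np.array([0.0, 1.0, 0.0])  # bump at 0 for three eyes
    tensor = make_tensor(rates, [-3.0, -1.0, 1.0, 3.0], heads)
    assert rf_location(tensor, 0) == pytest.approx(0.0, abs=1e-12)
    assert rf_location(tensor, 0, response_floor=0.5) == pytest.approx(0.0)


def test_rf_location_undefined_for_silent_neuron():
    tensor = make_tensor(np.zeros((1, 2, 3)), [-1.0, 1.0], [-2.0, 0.0, 2.0])
    assert rf_location(tensor, 0) is None


# -- RF size -----------------------------------------------------------------


def test_rf_size_triangular_bump():
    tensor = make_tensor(np.array([[[0.0, 1.0, 0.0]]]), [0.0], [-2.0, 0.0, 2.0])
    assert rf_size(tensor, 0, 0.5) == pytest.approx(2.0, abs=1e-12)


def test_rf_size_block_gains_half_step_tails():
    heads = np.arange(-10.0, 11.0, 2.0)
    rates = np.zeros((1, 1, len(heads)))
    rates[0, 0, 3:7] = 1.0  # block of width 3 steps = 6 degrees
    tensor = make_tensor(rates, [0.0], heads)
    width = heads[6] - heads[3]
    assert rf_size(tensor, 0, 0.5) == pytest.approx(width + 2.0, abs=1e-12)


def test_rf_size_uniform_response_covers_whole_interval():
    heads = np.arange(-10.0, 11.0, 2.0)
    tensor = make_tensor(np.full((1, 2, len(heads)), 0.7), [-2.0, 2.0], heads)
    assert rf_size(tensor, 0, 0.5) == pytest.approx(heads[-1] - heads[0], abs=1e-12)


def test_rf_size_matches_dense_crossing_oracle(rng):
    heads = np.arange(-20.0, 21.0, 2.0)
    rates = rng.uniform(0, 1, size=(1, 3, len(heads)))
    tensor = make_tensor(rates, [-2.0, 0.0, 2.0], heads)
    phi = 0.4
    psi = phi * rates.max()
    dense = np.linspace(heads[0], heads[-1], 200001)
    sizes = []
    for i in range(3):
        y = np.interp(dense, heads, rates[0, i])
        if rates[0, i].max() >= psi:
            sizes.append(np.mean(y >= psi) * (heads[-1] - heads[0]))
    assert rf_size(tensor, 0, phi) == pytest.approx(np.mean(sizes), abs=2e-3)


def test_rf_size_monotone_nonincreasing_in_threshold(rng):
    heads = np.arange(-20.0, 21.0, 2.0)
    rates = rng.uniform(0, 1, size=(5, 4, len(heads)))
    tensor = make_tensor(rates, [-4.0, -2.0, 2.0, 4.0], heads)
    for j in range(5):
        sizes = [rf_size(tensor, j, phi) for phi in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a >= b - 1e-12 for a, b in zip(sizes, sizes[1:]))


def test_rf_size_excludes_eye_positions_below_threshold():
    heads = np.array([-2.0, 0.0, 2.0])
    rates = np.zeros((1, 2, 3))
    rates[0, 0] = [0.0, 1.0, 0.0]
    rates[0, 1] = [0.0, 0.2, 0.0]  # below psi = 0.5: excluded from average
    tensor = make_tensor(rates, [-1.0, 1.0], heads)
    assert rf_size(tensor, 0, 0.5) == pytest.approx(2.0, abs=1e-12)


# -- coverage ----------------------------------------------------------------


def hc_metric(location, rfi_value=0.5):
    return NeuronMetrics(0, 0.8, 0.3, rfi_value, location, 10.0)


def test_uniform_assignment_gives_full_coverage():
    locations = (-56, -40, -24, -8, 8, 24, 40, 56)
    metrics = [hc_metric(loc + 0.5) for loc in locations] * 3
    assert coverage(metrics, locations) == pytest.approx(1.0, abs=1e-12)


def test_empty_location_means_no_coverage():
    locations = (-56, -40, -24, -8, 8, 24, 40, 56)
    metrics = [hc_metric(loc) for loc in locations[1:]]
    assert coverage(metrics, locations) is None


def test_no_head_centered_neurons_means_no_coverage():
    metrics = [NeuronMetrics(0, 0.2, 0.5, -0.3, 1.0, 5.0)]
    assert coverage(metrics, (-8, 8)) is None


def test_coverage_entropy_example():
    """Counts (3, 1) over two locations: H/ln(2) = 0.8113."""
    metrics = [hc_metric(-8.0)] * 3 + [hc_metric(8.0)]
    assert coverage(metrics, (-8.0, 8.0)) == pytest.approx(0.81127812, abs=1e-6)


def test_coverage_tie_goes_to_more_negative_location():
    # the neuron at 0 is equidistant; a deterministic tie-break sends it to
    # the more negative location, leaving +8 unrepresented
    assert coverage([hc_metric(0.0), hc_metric(8.0)], (-8.0, 8.0)) == pytest.approx(1.0)
    assert coverage([hc_metric(0.0)], (-8.0, 8.0)) is None


def test_coverage_bounded_by_one(rng):
    locations = (-24.0, -8.0, 8.0, 24.0)
    metrics = [hc_metric(float(rng.uniform(-30, 30))) for _ in range(40)]
    value = coverage(metrics, locations)
    if value is not None:
        assert value <= 1.0 + 1e-12


# -- population summary ------------------------------------------------------


def test_identical_neurons_have_zero_sd():
    metrics = [hc_metric(5.0) for _ in range(6)]
    summary = summarize_population(metrics, (-8.0, 8.0))
    for name in ("head_centeredness", "rfi", "rf_size"):
        assert summary.stats[name]["sd_all"] == pytest.approx(0.0, abs=1e-14)


def test_summary_matches_spreadsheet_oracle():
    metrics = [
        NeuronMetrics(0, 0.9, 0.1, 0.8, -8.0, 20.0),
        NeuronMetrics(1, 0.7, 0.3, 0.4, 8.0, 30.0),
        NeuronMetrics(2, 0.1, 0.6, -0.5, 0.0, 50.0),
        NeuronMetrics(3, None, None, None, None, None, excluded=True, exclusion_reason="x"),
    ]
    summary = summarize_population(metrics, (-8.0, 8.0))
    assert summary.n_neurons == 4
    assert summary.n_analyzable == 3
    assert summary.n_head_centered == 2
    vals = [0.8, 0.4, -0.5]
    assert summary.stats["rfi"]["mean_all"] == pytest.approx(np.mean(vals))
    assert summary.stats["rfi"]["sd_all"] == pytest.approx(np.std(vals))
    assert summary.stats["rf_size"]["mean_hc"] == pytest.approx(25.0)
    assert summary.head_centered_rate == pytest.approx(2 / 4)


def test_head_centered_rate_counting():
    metrics = [hc_metric(0.0, rfi_value=0.5)] * 2 + [hc_metric(0.0, rfi_value=-0.5)] * 6
    summary = summarize_population(metrics, (-8.0, 8.0))
    assert summary.head_centered_rate == pytest.approx(0.25)


def test_pearson_metrics_invariant_under_affine_rescaling(rng):
    rates = rng.uniform(0.2, 0.8, size=(1, 4, 21))
    heads = np.arange(-20.0, 21.0, 2.0)
    eyes = [-4.0, -2.0, 2.0, 4.0]
    t1 = make_tensor(rates, eyes, heads)
    t2 = make_tensor(0.9 * rates + 0.05, eyes, heads)
    assert head_centeredness(t2, 0) == pytest.approx(head_centeredness(t1, 0), abs=1e-10)
    assert eye_centeredness(t2, 0) == pytest.approx(eye_centeredness(t1, 0), abs=1e-10)


# -- round trips -------------------------------------------------------------


def test_tensor_long_format_round_trip(rng):
    rates = rng.uniform(0, 1, size=(3, 2, 5))
    tensor = make_tensor(rates, [-2.0, 2.0], np.arange(-4.0, 5.0, 2.0))
    back = tensor_from_frame(tensor_to_frame(tensor))
    np.testing.assert_allclose(back.rates, tensor.rates, atol=1e-12)


def test_metrics_frame_has_exclusion_columns():
    frame = metrics_to_frame([hc_metric(1.0), NeuronMetrics(1, excluded=True, exclusion_reason="silent")])
    assert set(["neuron", "rfi", "excluded", "exclusion_reason"]).issubset(frame.columns)
    assert frame["excluded"].tolist() == [False, True]
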