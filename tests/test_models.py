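"""Trajectory-level behaviour of the ED and WI generative models."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from affectdyn.models import (
    EDParams,
    WIParams,
    ed_trajectory,
    trajectory,
    wi_trajectory_closed,
    wi_trajectory_recursive,
)


@pytest.mark.parametrize(
    "params, stimuli, expected",
    [
        # gamma = 1: every stimulus weighted evenly (cumulative sum)
        (EDParams(w0=0, ws=1, gamma=1), [0.2, 0.3, 0.5], [0.2, 0.5, 1.0]),
        # gamma = 0: only the most recent stimulus counts
        (EDParams(w0=0.1, ws=2, gamma=0), [1, -1], [2.1, -1.9]),
        # hand sum: 0.5*1 + 1*2
        (EDParams(w0=0, ws=1, gamma=0.5), [1, 2], [1.0, 2.5]),
    ],
)
def test_ed_trajectory_hand_examples(params, stimuli, expected):
    np.testing.assert_allclose(ed_trajectory(params, stimuli), expected, atol=1e-12)


@pytest.mark.parametrize(
    "params, stimuli, expected",
    [
        (WIParams(x0=0, beta=0.5), [1, 1], [0.5, 0.75]),
        # beta = 0 freezes the state at x0
        (WIParams(x0=0.3, beta=0.0), [1, -1, 2], [0.3, 0.3, 0.3]),
        # beta = 1 tracks the latest stimulus exactly
        (WIParams(x0=5, beta=1.0), [0.4, -0.2], [0.4, -0.2]),
    ],
)
def test_wi_trajectory_hand_examples(params, stimuli, expected):
    np.testing.assert_allclose(
        wi_trajectory_recursive(params, stimuli), expected, atol=1e-12
    )


@pytest.mark.parametrize(
    "params, stimuli, expected",
    [
        # beta = 1 forgets the initial state after one stimulus
        (WIParams(x0=5, beta=1.0), [0.3], [0.3]),
        # zero stimuli: pure geometric decay of x0
        (WIParams(x0=1, beta=0.5), [0, 0], [0.5, 0.25]),
    ],
)
def test_wi_closed_form_hand_examples(params, stimuli, expected):
    np.testing.assert_allclose(wi_trajectory_closed(params, stimuli), expected, atol=1e-12)


@settings(max_examples=200, derandomize=True)
@given(
    beta=st.floats(0, 1),
    x0=st.floats(-2, 2),
    data=st.lists(st.floats(-3, 3), min_size=1, max_size=40),
)
def test_wi_closed_equals_recursive(beta, x0, data):
    params = WIParams(x0=x0, beta=beta)
    closed = wi_trajectory_closed(params, data)
    recursive = wi_trajectory_recursive(params, data)
    np.testing.assert_allclose(closed, recursive, atol=1e-10)


@settings(max_examples=200, derandomize=True)
@given(
    beta=st.floats(0, 1),
    x0=st.floats(-1, 1),
    data=st.lists(st.floats(-1, 1), min_size=1, max_size=40),
)
def test_wi_trajectory_bounded_by_inputs(beta, x0, data):
    """Every WI value is a convex combination of x0 and past stimuli."""
    values = wi_trajectory_recursive(WIParams(x0=x0, beta=beta), data)
    lo = min([x0] + data)
    hi = max([x0] + data)
    assert np.all(values >= lo - 1e-12) and np.all(values <= hi + 1e-12)


def test_ed_gamma_one_is_cumulative_sum():
    rng = np.random.default_rng(3)
    s = rng.normal(size=50)
    params = EDParams(w0=0.4, ws=0.7, gamma=1.0)
    np.testing.assert_allclose(
        ed_trajectory(params, s), 0.4 + 0.7 * np.cumsum(s), atol=1e-10
    )


def test_relevance_split_uses_own_stimulus_relevance():
    """Weight and decay of stimulus j follow stimulus j's relevance; the
    exponent counts all stimuli."""
    params = EDParams(w0=0, ws_rel=2.0, ws_irr=0.5, gamma_rel=0.5, gamma_irr=0.9)
    s = np.array([1.0, 1.0, 1.0])
    rel = np.array([True, False, True])
    expected = [
        2.0,
        2.0 * 0.5 + 0.5,
        2.0 * 0.25 + 0.5 * 0.9 + 2.0,
    ]
    np.testing.assert_allclose(ed_trajectory(params, s, rel), expected, atol=1e-12)

    wi = WIParams(x0=0.0, beta_rel=1.0, beta_irr=0.0)
    out = wi_trajectory_recursive(wi, [0.5, -0.7, 0.9], [True, False, True])
    np.testing.assert_allclose(out, [0.5, 0.5, 0.9], atol=1e-12)


def test_block_permutation_permutes_segments():
    """Trajectories restart at block boundaries, so block order is exchangeable."""
    rng = np.random.default_rng(9)
    blocks = [rng.normal(size=8) for _ in range(3)]
    params = WIParams(x0=0.2, beta=0.4)
    segments = [wi_trajectory_recursive(params, b) for b in blocks]
    for order in ([2, 0, 1], [1, 2, 0]):
        permuted = [wi_trajectory_recursive(params, blocks[i]) for i in order]
        for i, seg in zip(order, permuted):
            np.testing.assert_allclose(seg, segments[i])


@pytest.mark.parametrize(
    "factory",
    [
        lambda: EDParams(w0=0, ws=1, gamma=1.5),
        lambda: WIParams(x0=0, beta=-0.1),
        lambda: WIParams(x0=0, beta=0.5, beta_rel=0.5, beta_irr=0.5),
        lambda: EDParams(w0=0),
        lambda: WIParams(x0=0),
        lambda: EDParams(w0=0, ws=1, gamma=0.5, ws_rel=1.0),
    ],
)
def test_invalid_params_rejected(factory):
    with pytest.raises(ValueError):
        factory()


def test_relevance_flag_contract():
    split = WIParams(x0=0, beta_rel=0.5, beta_irr=0.2)
    with pytest.raises(ValueError):
        wi_trajectory_recursive(split, [1, 2])  # flags required
    with pytest.raises(ValueError):
        wi_trajectory_recursive(WIParams(x0=0, beta=0.5), [1, 2], [True, False])
    with pytest.raises(ValueError):
        wi_trajectory_recursive(split, [1, 2], [True])  # length mismatch
    with pytest.raises(ValueError):
        wi_trajectory_closed(split, [1, 2])  # closed form is unsplit-only


def test_trajectory_dispatch():
    s = [0.1, -0.2]
    np.testing.assert_allclose(
        trajectory("wi", WIParams(x0=0, beta=0.3), s),
        wi_trajectory_recursive(WIParams(x0=0, beta=0.3), s),
    )
    with pytest.raises(TypeError):
        trajectory("ED", WIParams(x0=0, beta=0.3), s)
    with pytest.raises(ValueError):
        trajectory("nope", WIParams(x0=0, beta=0.3), s)
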