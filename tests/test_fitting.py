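"""Maximum-likelihood fitting: likelihood arithmetic and recovery."""

import numpy as np
import pytest
from scipy import stats

from affectdyn.fitting import (
    FitResult,
    aic,
    aic_value,
    fit_participant,
    n_free_params,
    negative_log_likelihood,
)
from affectdyn.models import WIParams
from affectdyn.simulate import participant_blocks, simulate_ratings


def _single_block(stimuli, rating_positions):
    return [(1, np.asarray(stimuli, float), None, np.asarray(rating_positions))]


def test_nll_zero_residuals_is_normalizing_constant():
    params = WIParams(x0=0.0, beta=1.0)
    blocks = _single_block([0.5, -0.5], [0, 1])
    observed = [0.5, -0.5]  # exactly on the trajectory
    nll = negative_log_likelihood("WI", params, 1.0, observed, blocks)
    assert nll == pytest.approx(np.log(2 * np.pi), abs=1e-12)


def test_nll_unit_residuals():
    params = WIParams(x0=0.0, beta=1.0)
    blocks = _single_block([0.0, 0.0], [0, 1])
    nll = negative_log_likelihood("WI", params, 1.0, [1.0, -1.0], blocks)
    assert nll == pytest.approx(np.log(2 * np.pi) + 1.0, abs=1e-12)


def test_nll_matches_per_point_density_product():
    rng = np.random.default_rng(4)
    stimuli = rng.normal(size=12)
    params = WIParams(x0=0.3, beta=0.6)
    pos = np.array([3, 7, 11])
    blocks = _single_block(stimuli, pos)
    observed = rng.normal(size=3)
    sigma = 0.7
    # independent oracle: explicit normal density at the recursion's values
    v = params.x0
    traj = []
    for s in stimuli:
        v = v + 0.6 * (s - v)
        traj.append(v)
    oracle = -np.sum(stats.norm.logpdf(observed, np.asarray(traj)[pos], sigma))
    nll = negative_log_likelihood("WI", params, sigma, observed, blocks)
    assert nll == pytest.approx(oracle, rel=1e-12)


def test_nll_rejects_bad_inputs():
    params = WIParams(x0=0.0, beta=0.5)
    blocks = _single_block([1.0, 2.0], [1])
    with pytest.raises(ValueError):
        negative_log_likelihood("WI", params, 0.0, [1.0], blocks)
    with pytest.raises(ValueError):
        negative_log_likelihood("WI", params, 1.0, [1.0, 2.0], blocks)


def test_aic_identity_and_counts():
    fit = FitResult(
        model_name="WI",
        dimension="valence",
        participant_id="p",
        params=WIParams(x0=0, beta=0.5),
        sigma=1.0,
        loglik=-10.0,
        n_params=3,
        n_obs=19,
        aic=aic_value(3, -10.0),
        converged=True,
        n_restarts_used=1,
    )
    assert aic(fit) == pytest.approx(26.0)
    assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik, abs=1e-9)
    assert n_free_params("WI", split=False) == 3
    assert n_free_params("ED", split=False) == 4
    assert n_free_params("WI", split=True) == 4
    assert n_free_params("ED", split=True) == 6


@pytest.fixture(scope="module")
def low_noise_fit(schedule, catalog):
    true = WIParams(x0=0.0, beta_rel=0.6, beta_irr=0.6)
    params = {
        p: {"valence": true, "arousal": true}
        for p in schedule["participant_id"].unique()
    }
    ratings = simulate_ratings(
        schedule, catalog, "WI", params, noise_sd=0.05, seed=21, design="task"
    )
    fit = fit_participant(
        "WI", schedule, catalog, ratings, "p000", "valence",
        design="task", n_restarts=6, seed=2,
    )
    return true, ratings, fit


def test_low_noise_beta_recovery(low_noise_fit):
    true, _, fit = low_noise_fit
    assert fit.params.beta_rel == pytest.approx(true.beta_rel, abs=0.05)
    assert fit.params.beta_irr == pytest.approx(true.beta_irr, abs=0.05)
    assert fit.n_obs == 76
    assert fit.converged


def test_mle_dominates_truth_in_sample(low_noise_fit, schedule, catalog):
    true, ratings, fit = low_noise_fit
    blocks = participant_blocks(schedule, catalog, "p000", "valence", "task")
    obs = (
        ratings[(ratings["participant_id"] == "p000")]
        .sort_values(["block_index", "rating_index"])["valence"]
        .to_numpy()
    )
    loglik_truth = -negative_log_likelihood("WI", true, 0.05, obs, blocks)
    assert fit.loglik >= loglik_truth - 1e-6


def test_more_restarts_never_hurt(schedule, catalog, wi_task_ratings):
    fits = [
        fit_participant(
            "ED", schedule, catalog, wi_task_ratings, "p001", "valence",
            design="task", n_restarts=n, seed=5,
        )
        for n in (2, 6)
    ]
    # same seed: the first two start points are shared, so the max over the
    # larger restart set cannot be worse
    assert fits[1].loglik >= fits[0].loglik - 1e-9


def test_fit_is_reproducible(schedule, catalog, wi_task_ratings):
    a = fit_participant(
        "WI", schedule, catalog, wi_task_ratings, "p002", "valence",
        design="task", n_restarts=4, seed=9,
    )
    b = fit_participant(
        "WI", schedule, catalog, wi_task_ratings, "p002", "valence",
        design="task", n_restarts=4, seed=9,
    )
    assert a.params == b.params and a.loglik == b.loglik and a.sigma == b.sigma


def test_control_design_uses_unsplit_params(schedule, catalog, participant_ids):
    params = {
        p: {"valence": WIParams(x0=0, beta=0.5), "arousal": WIParams(x0=0, beta=0.3)}
        for p in participant_ids
    }
    ratings = simulate_ratings(
        schedule, catalog, "WI", params, noise_sd=0.3, seed=3, design="control"
    )
    fit = fit_participant(
        "WI", schedule, catalog, ratings, "p000", "valence",
        design="control", n_restarts=4, seed=0,
    )
    assert not fit.params.split
    assert fit.n_params == 3
    assert fit.n_obs == 19
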