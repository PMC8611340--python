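"""Lagged regression, Wald comparisons, Holm correction and power analysis."""

import numpy as np
import pandas as pd
import pytest

from affectdyn.lagged import (
    RegressionResult,
    _paired_t_power,
    build_lag_design,
    fit_hierarchical_lm,
    holm_bonferroni,
    paired_ttest_sample_size,
    wald_compare,
)
from affectdyn.models import WIParams
from affectdyn.simulate import simulate_ratings


@pytest.fixture(scope="module")
def task_design(schedule, catalog, wi_task_ratings):
    return build_lag_design(
        schedule, wi_task_ratings, catalog, "valence",
        include_relevance=True, design="task",
    )


def test_design_shapes(schedule, catalog, wi_task_ratings, task_design, participant_ids):
    per_pid = task_design.groupby("participant_id").size()
    assert (per_pid == 76).all()  # 304 task trials / 4
    lag_cols = [c for c in task_design.columns if c.startswith("S_lag") and "x" not in c]
    inter_cols = [c for c in task_design.columns if c.endswith("_x_rel")]
    assert len(lag_cols) == 4 and len(inter_cols) == 4


def test_control_design_shape(schedule, catalog, participant_ids):
    params = {
        p: {"valence": WIParams(x0=0, beta=0.4), "arousal": WIParams(x0=0, beta=0.3)}
        for p in participant_ids
    }
    ratings = simulate_ratings(
        schedule, catalog, "WI", params, noise_sd=0.4, seed=2, design="control"
    )
    tab = build_lag_design(schedule, ratings, catalog, "valence", design="control")
    assert (tab.groupby("participant_id").size() == 19).all()
    assert not any(c.endswith("_x_rel") for c in tab.columns)


def test_lags_are_the_window_stimuli(schedule, catalog, wi_task_ratings, task_design):
    """S_lag1..S_lag4 must be the norms of the four images since the previous
    rating, most recent first."""
    norms = catalog.set_index("stimulus_id")["valence_std"]
    pid = "p000"
    sub = schedule[
        (schedule["participant_id"] == pid)
        & (schedule["block_type"] == "task")
    ].sort_values(["block_index", "trial_index"])
    first_block = sub[sub["block_index"] == sub["block_index"].iloc[0]]
    window = first_block.iloc[0:4]  # trials 1-4 precede the first rating
    row = task_design[task_design["participant_id"] == pid].iloc[0]
    for lag in range(1, 5):
        sid = window.iloc[4 - lag]["stimulus_id"]
        assert row[f"S_lag{lag}"] == pytest.approx(norms[sid])


def test_recency_and_relevance_interactions_recovered(task_design):
    """Generative check: ratings simulated with beta_rel > beta_irr must show
    larger recent-lag coefficients and positive recent interactions."""
    res = fit_hierarchical_lm(task_design, method="two_stage")
    assert res.coef["S_lag1"] > res.coef["S_lag4"]
    assert res.coef["S_lag1"] > 0
    assert res.coef["S_lag1_x_rel"] > 0
    assert res.coef["S_lag2_x_rel"] > 0
    z, p = wald_compare(res, "S_lag1", "S_lag4")
    assert z > 0


def test_mixed_and_two_stage_agree(schedule, catalog, participant_ids):
    rng = np.random.default_rng(8)
    params = {
        p: {
            "valence": WIParams(x0=0, beta=float(rng.uniform(0.2, 0.6))),
            "arousal": WIParams(x0=0, beta=0.3),
        }
        for p in participant_ids
    }
    ratings = simulate_ratings(
        schedule, catalog, "WI", params, noise_sd=0.4, seed=3, design="control"
    )
    tab = build_lag_design(schedule, ratings, catalog, "valence", design="control")
    mixed = fit_hierarchical_lm(tab, method="mixed")
    two = fit_hierarchical_lm(tab, method="two_stage")
    assert mixed.method == "mixed"
    assert np.max(np.abs(mixed.coef - two.coef)) < 0.06


def test_null_simulation_type_one_calibration(schedule, catalog, participant_ids):
    """Pure-noise ratings: fixed effects should rarely exceed 2 se."""
    rng = np.random.default_rng(12)
    hits = []
    for rep in range(30):
        base = build_lag_design(
            schedule,
            _noise_ratings(schedule, rng),
            catalog,
            "valence",
            design="task",
        )
        res = fit_hierarchical_lm(base, method="two_stage")
        hits.extend((res.pvals > 0.05).tolist())
    # nominal non-rejection rate is 0.95; allow Monte Carlo slack for the
    # within-replicate correlation of the five tests
    assert np.mean(hits) >= 0.85


def _noise_ratings(schedule, rng):
    task = schedule[schedule["block_type"] == "task"]
    rows = []
    for (pid, block), bdf in task.groupby(["participant_id", "block_index"]):
        pos = bdf[bdf["is_rating_trial"]].sort_values("trial_index")
        for k, (_, trial) in enumerate(pos.iterrows()):
            rows.append(
                {
                    "participant_id": pid,
                    "block_index": block,
                    "block_type": "task",
                    "rating_index": k + 1,
                    "trial_index": trial["trial_index"],
                    "valence": rng.normal(),
                    "arousal": rng.normal(),
                }
            )
    return pd.DataFrame(rows)


def _toy_result():
    names = ["a", "b"]
    cov = pd.DataFrame(np.diag([0.01, 0.01]), index=names, columns=names)
    return RegressionResult(
        coef=pd.Series([0.3, 0.1], index=names),
        se=pd.Series(np.sqrt(np.diag(cov)), index=names),
        cov=cov,
        pvals=pd.Series([0.01, 0.2], index=names),
        n_obs=100,
        n_participants=10,
        model_spec="toy",
        method="two_stage",
    )


def test_wald_hand_example():
    res = _toy_result()
    z, p = wald_compare(res, "a", "b")
    assert z == pytest.approx(np.sqrt(2), abs=1e-6)
    assert p == pytest.approx(0.157, abs=0.001)
    z2, p2 = wald_compare(res, "b", "a")
    assert z2 == pytest.approx(-z)
    assert p2 == pytest.approx(p)


def test_wald_equal_coefficients():
    res = _toy_result()
    res.coef["b"] = res.coef["a"]
    z, p = wald_compare(res, "a", "b")
    assert z == 0.0 and p == 1.0


def test_wald_shift_invariance():
    res = _toy_result()
    z1, _ = wald_compare(res, "a", "b")
    res.coef += 5.0
    z2, _ = wald_compare(res, "a", "b")
    assert z1 == pytest.approx(z2)


def test_holm_hand_example():
    reject, adjusted = holm_bonferroni({"x": 0.01, "y": 0.03, "z": 0.04}, alpha=0.05)
    assert adjusted == pytest.approx({"x": 0.03, "y": 0.06, "z": 0.06})
    assert reject == {"x": True, "y": False, "z": False}


def test_holm_no_rejections_at_one():
    reject, adjusted = holm_bonferroni([1.0, 1.0, 1.0])
    assert not reject.any()
    assert (adjusted == 1.0).all()


def test_holm_rejects_superset_of_bonferroni():
    rng = np.random.default_rng(5)
    for _ in range(50):
        p = rng.uniform(0, 0.2, size=6)
        holm_reject, _ = holm_bonferroni(p, alpha=0.05)
        bonf_reject = p <= 0.05 / p.size
        assert np.all(holm_reject[bonf_reject])


def test_power_analysis_reference_value():
    assert paired_ttest_sample_size(0.5, power=0.95, alpha=0.05) == 54


def test_power_monotone_in_effect_size():
    assert paired_ttest_sample_size(1.0) < paired_ttest_sample_size(0.5)


def test_returned_n_is_minimal():
    n = paired_ttest_sample_size(0.4, power=0.9)
    assert _paired_t_power(n, 0.4, 0.05, True) >= 0.9
    assert _paired_t_power(n - 1, 0.4, 0.05, True) < 0.9
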