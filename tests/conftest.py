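import numpy as np
import pytest

from affectdyn import WIParams, build_schedule, generate_catalog, simulate_ratings


@pytest.fixture(scope="session")
def catalog():
    return generate_catalog(seed=1)


@pytest.fixture(scope="session")
def schedule(catalog):
    return build_schedule(6, catalog, seed=7)


@pytest.fixture(scope="session")
def participant_ids(schedule):
    return list(schedule["participant_id"].unique())


@pytest.fixture(scope="session")
def wi_task_params(participant_ids):
    """Relevance-split WI parameters with a clear rel > irr valence gap."""
    rng = np.random.default_rng(11)
    return {
        pid: {
            "valence": WIParams(
                x0=float(rng.uniform(-0.3, 0.3)),
                beta_rel=float(rng.uniform(0.45, 0.65)),
                beta_irr=float(rng.uniform(0.15, 0.35)),
            ),
            "arousal": WIParams(
                x0=float(rng.uniform(-0.3, 0.3)),
                beta_rel=float(rng.uniform(0.2, 0.4)),
                beta_irr=float(rng.uniform(0.15, 0.35)),
            ),
        }
        for pid in participant_ids
    }


@pytest.fixture(scope="session")
def wi_task_ratings(schedule, catalog, wi_task_params):
    return simulate_ratings(
        schedule, catalog, "WI", wi_task_params, noise_sd=0.5, seed=5, design="task"
    )
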