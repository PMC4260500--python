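import numpy as np
import pytest

from wmlbci import Study2Config
from wmlbci.forward import simulate_session
from wmlbci.preprocess import extract_interval_pairs, regress_out_eog
from wmlbci.schedules import build_nback_block


@pytest.fixture(scope="session")
def desk_config() -> Study2Config:
    return Study2Config.desk()


@pytest.fixture(scope="session")
def nback_recording(desk_config):
    """A three-level n-back mini-session rendered with the default signature
    (no artifacts, for clean spectral checks)."""
    from wmlbci.events import SessionSchedule

    frags = [build_nback_block(level, 24, 100 + level) for level in (1, 2, 3)]
    sched = SessionSchedule.concatenate("fix", frags, gap_s=4.0)
    rec, ratings = simulate_session(
        sched, desk_config.forward_model, desk_config.profile,
        desk_config.rating_model, seed=17, artifacts=False,
    )
    return rec, ratings


@pytest.fixture(scope="session")
def nback_features(nback_recording, desk_config):
    from wmlbci.features import build_crosstask_features

    rec, _ = nback_recording
    pairs = extract_interval_pairs(rec, "nback")
    return build_crosstask_features(rec, pairs, ar_order=desk_config.ar_order)


def make_clusters(n_per_class=12, n_features=6, sep=6.0, seed=0):
    """Two well-separated Gaussian clouds with string labels."""
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per_class, n_features))
    b = rng.standard_normal((n_per_class, n_features))
    b[:, 0] += sep
    X = np.vstack([a, b])
    y = np.array(["low"] * n_per_class + ["high"] * n_per_class)
    return X, y
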