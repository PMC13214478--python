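import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import srtkit as sk

settings.register_profile(
    "fixed",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def synthetic_corpus() -> pd.DataFrame:
    return sk.generate_synthetic_corpus(n_per_template=120, seed=11)


@pytest.fixture(scope="session")
def filtered_corpus(synthetic_corpus):
    """(retained-and-trimmed corpus, normalization reference mean)."""
    retained, _ = sk.apply_filters(synthetic_corpus)
    return sk.trim_by_offset(retained)


@pytest.fixture(scope="session")
def list_set(filtered_corpus):
    final, _ = filtered_corpus
    return sk.optimize_lists(final, 44, n_iter=5, seed=11)


@pytest.fixture(scope="session")
def steep_list() -> tuple[pd.DataFrame, float]:
    """A normalized 20-sentence list, every sentence with slope 18.5 %/dB."""
    rng = np.random.default_rng(0)
    midpoints = rng.normal(-4.8, 1.6, 20)
    reference = float(midpoints.mean())
    df = pd.DataFrame(
        {
            "sentence_id": np.arange(1, 21),
            "midpoint_db": midpoints,
            "slope_pct_per_db": 18.5,
            "offset_db": midpoints - reference,
        }
    )
    return df, reference


@pytest.fixture(scope="session")
def small_study(filtered_corpus, list_set):
    """A full simulated 20-participant study with per-track trial logs."""
    final, _ = filtered_corpus
    listeners = sk.make_listeners(20, seed=5, srt_shift_sd_db=0.5)
    plans = sk.make_session_plan(20, 44, seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return sk.simulate_study(
            final, list_set, listeners, plans, seed=5,
            fit_slopes=True, keep_logs=True,
        )


def scripted_track(responses, sentences=None, **kwargs) -> sk.Track:
    """Drive a track with a fixed correct/incorrect script (3 or 0 keywords)."""
    if sentences is None:
        sentences = [(i, 0.0) for i in range(1, 21)]
    track = sk.start_track(sentences, **kwargs)
    it = iter(responses)
    while track.running:
        track.score(3 if next(it) else 0)
    return track
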