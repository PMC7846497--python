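import datetime as dt

import numpy as np
import pytest

from lvattention.lv_dynamics import solve_shares
from lvattention.share_model import ShareSystem
from lvattention.trends_io import AttentionSeries
from lvattention.utility_fit import FourierUtility


def make_series(values_by_topic, area="testland", start=dt.date(2019, 5, 5)):
    """Build aligned AttentionSeries from a dict {topic: values}."""
    n = len(next(iter(values_by_topic.values())))
    dates = tuple(start + dt.timedelta(weeks=k) for k in range(n))
    return [
        AttentionSeries(topic=topic, area=area, times=dates, values=np.asarray(v))
        for topic, v in values_by_topic.items()
    ]


def random_fourier_system(rng, n_topics=4, order=2, n_weeks=52, scale=0.4):
    """Random Fourier utilities plus their closed-form share trajectories."""
    times = np.arange(n_weeks, dtype=float)
    tau = float(times[-1] - times[0])
    topics = tuple(f"topic_{i + 1}" for i in range(n_topics))
    utilities = tuple(
        FourierUtility(
            a0=rng.normal(-1.0, 0.5),
            a=rng.normal(0.0, scale, order),
            b=rng.normal(0.0, scale, order),
            tau=tau,
        )
        for _ in topics
    )
    shares = solve_shares(utilities, times, topics)
    return utilities, shares


def random_share_system(rng, n_times=30, n_topics=4):
    """Random strictly valid shares (rows drawn from a Dirichlet)."""
    p = rng.dirichlet(np.ones(n_topics + 1), size=n_times)
    return ShareSystem(
        times=np.arange(n_times, dtype=float),
        topics=tuple(f"t{i}" for i in range(n_topics)),
        S=p[:, :n_topics],
        S0=p[:, n_topics],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
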