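import numpy as np
import pandas as pd
import pytest

import sumaerr as s


@pytest.fixture
def tiny_table():
    """Four predictions x four replicates with hand-checkable moments."""
    return s.EnsembleTable(
        prediction_ids=np.array(["a", "b", "c", "d"], dtype=object),
        values=np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [1.0, 2.0, 3.0, 4.0],
                [8.0, 6.0, 4.0, 2.0],
                [5.0, 5.0, 5.0, 5.0],
            ]
        ),
    )


@pytest.fixture(scope="session")
def paper_regime():
    """One draw at the estimated real-data regime: multiplicative error only."""
    spec = s.SimulationSpec(
        n_pred=600,
        n_ens=120,
        sigma_sm2=0.0003,
        sigma_m2=0.0075,
        sigma_sa2=0.0,
        sigma_a2=0.0,
        z_dist="uniform",
        z_params=(10.0, 100.0),
        seed=7,
    )
    return s.simulate(spec)


@pytest.fixture(scope="session")
def study():
    """The default synthetic study fixture, scaled down for the test suite.

    3000 predictions x 120 replicates keeps the per-period strata around
    1000 predictions while the replicate count (which controls moment
    estimation error) stays at the real study's value.
    """
    return s.simulate_study(n_pred=3000, seed=11)


def spatial_labels(n, seed, hotspot=None, p_high=0.2):
    """Bernoulli high/low labels over a uniform spatial layout.

    ``hotspot=(cx, cy, radius, odds_mult)`` multiplies the odds of a high
    label inside the disc, rescaling the outside so the overall high
    fraction stays near ``p_high``.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 2e5, n)
    y = rng.uniform(0, 1.5e5, n)
    odds = np.full(n, p_high / (1 - p_high))
    inside = np.zeros(n, dtype=bool)
    if hotspot is not None:
        cx, cy, r, mult = hotspot
        inside = (x - cx) ** 2 + (y - cy) ** 2 <= r**2
        odds[inside] *= mult
    p = odds / (1 + odds)
    lab = np.where(rng.uniform(size=n) < p, "high", "low")
    labels = s.SmmeLabelSet(
        frame=pd.DataFrame({"mean_cov": np.zeros(n), "label": lab}), threshold=0.0, percentile=80.0
    )
    meta = pd.DataFrame({"x": x, "y": y})
    return labels, meta, inside
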