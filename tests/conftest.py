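import numpy as np
import pandas as pd
import pytest

from ruttrack.trajectory import Track


def make_track(xy, start="2015-11-01", freq_h=1.0, animal_id="A1", sex="male",
               study_area="SN"):
    """Track from an (n, 2) coordinate array on a regular time grid."""
    xy = np.asarray(xy, dtype=float)
    times = pd.Timestamp(start) + pd.to_timedelta(np.arange(len(xy)) * freq_h, unit="h")
    return Track(
        animal_id=animal_id,
        sex=sex,
        study_area=study_area,
        fixes=pd.DataFrame({"timestamp": times, "x": xy[:, 0], "y": xy[:, 1]}),
    )


def brownian_track(n, sigma2_per_s, delta, seed, dt_s=3600.0, **kw):
    """Observed Brownian path: true diffusion sigma2_per_s (m^2/s per
    coordinate), GPS error SD delta."""
    rng = np.random.default_rng(seed)
    true = np.cumsum(rng.normal(0, np.sqrt(sigma2_per_s * dt_s), (n, 2)), axis=0)
    obs = true + rng.normal(0, delta, (n, 2))
    return make_track(obs, freq_h=dt_s / 3600.0, **kw)


@pytest.fixture(scope="session")
def distinct_run():
    """One cohesive-distinct scenario pushed through detection (session-cached)."""
    from ruttrack.interaction import attach_di, detect_events
    from ruttrack.synthetic import Scenario, simulate_pair
    from ruttrack.trajectory import align_dyad

    scen = Scenario(seed=11, mode="cohesive-distinct")
    male, female, truth = simulate_pair(scen)
    dyad = align_dyad(male, female)
    events = attach_di(detect_events(dyad))
    return {"scenario": scen, "male": male, "female": female, "truth": truth,
            "dyad": dyad, "events": events}
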