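import numpy as np
import pandas as pd
import pytest

import fpsae
from fpsae.synthetic import OUTCOMES


@pytest.fixture(scope="session")
def path_graph():
    """Three areas in a row: a - b - c."""
    return fpsae.AdjacencyGraph.from_edges([("a", "b"), ("b", "c")])


@pytest.fixture(scope="session")
def small_world():
    """A 6-area world with truth surfaces, a frame, and three surveys."""
    g = fpsae.synthetic_graph(6, seed=1)
    years = range(2010, 2016)
    surfaces = {
        o: fpsae.generate_true_surface(g, years, seed=10 + i, outcome=o)
        for i, o in enumerate(OUTCOMES)
    }
    frame = fpsae.build_sampling_frame(g, seed=3)
    recs = []
    for i, (sid, inst, yr) in enumerate(
        [("dhs1", "DHS", 2011), ("mics1", "MICS", 2013), ("pma1", "PMA", 2014)]
    ):
        spec = fpsae.SurveySpec(sid, inst, yr, g.areas, clusters_per_stratum=6)
        recs.append(fpsae.simulate_survey(surfaces, frame, spec, seed=40 + i))
    records = pd.concat(recs, ignore_index=True)
    return {"graph": g, "years": tuple(years), "surfaces": surfaces,
            "frame": frame, "records": records}


@pytest.fixture(scope="session")
def small_estimates(small_world):
    est = fpsae.DirectEstimator().fit_transform(small_world["records"])
    return est[est["outcome"] == "modern"].reset_index(drop=True)


def make_two_stratum_toy():
    """A fixed 40-record table: 2 strata x 2 clusters x 10 women, unequal weights.

    Deterministic by construction so brute-force oracles can be run against
    the exact same numbers.
    """
    rows = []
    rng = np.random.default_rng(12345)
    for h, stratum in enumerate(["S1", "S2"]):
        for c, cluster in enumerate([f"{stratum}C1", f"{stratum}C2"]):
            for i in range(10):
                rows.append({
                    "survey_id": "toy", "instrument_type": "DHS", "area": "A",
                    "year": 2015, "stratum": stratum, "cluster": cluster,
                    "weight": float(1 + h + 0.5 * c + 0.1 * i),
                    "age_group": "25+", "parity": "parous",
                    "uses_modern": int(rng.uniform() < 0.3 + 0.1 * h),
                    "uses_traditional": 0, "unmet_need": 0,
                })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def two_stratum_toy():
    return make_two_stratum_toy()
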