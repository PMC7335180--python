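import numpy as np
import pandas as pd
import pytest

from vcforge.bayesnet import DiscreteBN
from vcforge.schema import CohortTable, FeatureSpec, GroupSpec, VisitSchedule


@pytest.fixture
def schedule():
    return VisitSchedule(("bl", "m06", "m12"), (0.0, 6.0, 12.0))


@pytest.fixture
def small_gspec(schedule):
    """Two longitudinal groups x two visits plus one static group."""
    feats = []
    for g, cls in (("cog", "cognition"), ("csf", "biomarker")):
        for f in (f"{g}1", f"{g}2"):
            for v in ("bl", "m06"):
                feats.append(FeatureSpec(f, "continuous", g, v))
    feats.append(FeatureSpec("age", "continuous", "demo", "static"))
    return GroupSpec(feats, schedule, {"cog": "cognition", "csf": "biomarker",
                                       "demo": "demographics"})


@pytest.fixture
def small_cohort(small_gspec):
    rng = np.random.default_rng(0)
    cols = small_gspec.columns
    df = pd.DataFrame(rng.normal(size=(12, len(cols))), columns=cols,
                      index=[f"p{i}" for i in range(12)])
    return CohortTable(df)


def chain_bn(probs=((0.3, 0.7), ((0.8, 0.2), (0.1, 0.9)), ((0.9, 0.1), (0.3, 0.7)))):
    """Binary chain A -> B -> C with explicit CPTs."""
    a, b, c = (np.asarray(p, float) for p in probs)
    return DiscreteBN(["A", "B", "C"], {"A": 2, "B": 2, "C": 2},
                      {"A": (), "B": ("A",), "C": ("B",)},
                      {"A": a, "B": b, "C": c})


def enumerate_joint(bn: DiscreteBN) -> dict[tuple[int, ...], float]:
    """Brute-force joint distribution from the CPTs (oracle)."""
    import itertools

    joint = {}
    for cfg in itertools.product(*[range(bn.levels[v]) for v in bn.nodes]):
        assign = dict(zip(bn.nodes, cfg))
        p = 1.0
        for v in bn.nodes:
            idx = tuple(assign[u] for u in bn.parents[v]) + (assign[v],)
            p *= float(bn.cpts[v][idx])
        joint[cfg] = p
    return joint
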