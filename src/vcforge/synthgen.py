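"""Seeded generator of ground-truth longitudinal cohorts.

Emulates the statistical structure the modelling pipeline assumes: a known
DAG over discrete per-(group, visit) latent module scores with
forward-in-time edges only, per-group continuous raw-feature emissions
(loading * level + Gaussian noise), and monotone missing-not-at-random
drop-out whose hazard depends on the visit's latent level (patients who
worsen are more likely to leave, and once a group's block is dropped it
stays dropped at all later visits).  Every downstream module — imputation,
autoencoding, discretization, structure learning, simulation, evaluation —
is testable against this known truth without any external data.

Latent scores are generated directly as discrete levels so the fitted BN's
estimand is well defined; the continuous emissions exist solely to exercise
the raw-data half of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy.special import expit

from .bayesnet import DiscreteBN
from .schema import (STATIC, CohortTable, FeatureSpec, GroupSpec, VisitSchedule,
                     node_name)
from .simulate import ancestral_sample


@dataclass
class GroundTruth:
    """True latent BN + emission + drop-out model of a synthetic cohort."""

    bn: DiscreteBN
    loadings: dict[str, np.ndarray]       # node -> per-feature loading vector
    noise_sd: float
    n_groups: int
    n_features_per_group: int
    n_visits: int
    levels: int
    dropout_gain: float = 1.5             # slope of the drop-out hazard logit

    def group(self, g: int) -> str:
        return f"g{g + 1}"

    def visit(self, t: int) -> str:
        return f"v{t + 1}"

    @property
    def visit_labels(self) -> list[str]:
        return [self.visit(t) for t in range(self.n_visits)]

    def feature_columns(self, node: str) -> list[str]:
        group, visit = node.split("@")
        return [f"{group}f{j + 1}@{visit}"
                for j in range(self.n_features_per_group)]

    def group_spec(self) -> GroupSpec:
        schedule = VisitSchedule(tuple(self.visit_labels),
                                 tuple(6.0 * t for t in range(self.n_visits)))
        features, classes = [], {}
        for g in range(self.n_groups):
            grp = self.group(g)
            classes[grp] = "biomarker"
            for j in range(self.n_features_per_group):
                for v in self.visit_labels:
                    features.append(FeatureSpec(f"{grp}f{j + 1}", "continuous",
                                                grp, v))
        return GroupSpec(features, schedule, classes)

    def to_dict(self) -> dict:
        return {
            "bn": self.bn.to_dict(),
            "loadings": {k: v.tolist() for k, v in self.loadings.items()},
            "noise_sd": self.noise_sd,
            "n_groups": self.n_groups,
            "n_features_per_group": self.n_features_per_group,
            "n_visits": self.n_visits,
            "levels": self.levels,
            "dropout_gain": self.dropout_gain,
        }

    def save(self, path: str | Path):
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, raw: dict) -> "GroundTruth":
        return cls(DiscreteBN.from_dict(raw["bn"]),
                   {k: np.asarray(v, float) for k, v in raw["loadings"].items()},
                   raw["noise_sd"], raw["n_groups"], raw["n_features_per_group"],
                   raw["n_visits"], raw["levels"], raw.get("dropout_gain", 1.5))

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _random_cpt_rows(shape: tuple[int, ...], L: int, rng: np.random.Generator,
                     dependence: float | None, parent_dims: int) -> np.ndarray:
    """CPT with entries bounded away from 0 and 1 (in [0.05, 0.95]).

    With ``dependence`` set, each row puts that much extra mass on a level
    determined by the parent configuration (sum of parent levels mod L),
    giving strong, recoverable parent-child coupling; otherwise rows are a
    Dirichlet/uniform mixture.
    """
    q = int(np.prod(shape[:-1])) if parent_dims else 1
    lam = min(0.8, 1.0 - 0.05 * L, dependence if dependence is not None else 0.8)
    rows = np.empty((q, L))
    configs = np.indices(shape[:-1]).reshape(parent_dims, -1).T if parent_dims \
        else np.zeros((1, 0), int)
    for r in range(q):
        if dependence is not None and parent_dims:
            peak = int(configs[r].sum() % L)
            base = np.zeros(L)
            base[peak] = 1.0
        else:
            base = rng.dirichlet(np.ones(L))
        rows[r] = lam * base + (1.0 - lam) / L
    return rows.reshape(shape)


def make_ground_truth(n_groups: int = 4, n_features_per_group: int = 6,
                      n_visits: int = 3, levels: int = 3, seed: int = 0,
                      edge_prob: float = 0.3, noise_sd: float = 0.5,
                      dependence: float | None = None,
                      within_visit: bool = True,
                      max_parents: int = 3) -> GroundTruth:
    """Random forward-in-time latent DAG with bounded-away-from-deterministic
    CPTs and random emission loadings.

    Temporal backbone edges g@t -> g@(t+1) are always present; additional
    cross-group edges are added forward in time (and, if ``within_visit``,
    between groups at the same visit, ordered by group index) with
    probability ``edge_prob``, capped at ``max_parents`` parents per node.
    """
    if min(n_groups, n_features_per_group, n_visits, levels) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    nodes = [node_name(f"g{g + 1}", f"v{t + 1}")
             for t in range(n_visits) for g in range(n_groups)]
    order = {n: i for i, n in enumerate(nodes)}
    parents: dict[str, list[str]] = {n: [] for n in nodes}
    for g in range(n_groups):
        for t in range(n_visits - 1):
            parents[node_name(f"g{g + 1}", f"v{t + 2}")].append(
                node_name(f"g{g + 1}", f"v{t + 1}"))
    for v in nodes:
        for u in nodes:
            if u == v or u in parents[v]:
                continue
            tu = int(u.split("@v")[1])
            tv = int(v.split("@v")[1])
            if tu > tv:
                continue
            if tu == tv and (not within_visit or order[u] >= order[v]):
                continue
            if len(parents[v]) >= max_parents:
                break
            if rng.random() < edge_prob:
                parents[v].append(u)

    level_map = {n: levels for n in nodes}
    cpts = {}
    for v in nodes:
        ps = tuple(sorted(parents[v], key=order.get))
        parents[v] = ps
        shape = tuple(levels for _ in ps) + (levels,)
        cpts[v] = _random_cpt_rows(shape, levels, rng, dependence, len(ps))
    bn = DiscreteBN(nodes, level_map, {v: tuple(p) for v, p in parents.items()},
                    cpts, alpha=1.0)

    loadings = {}
    for v in nodes:
        mag = rng.uniform(0.5, 1.5, size=n_features_per_group)
        sign = rng.choice([-1.0, 1.0], size=n_features_per_group)
        loadings[v] = mag * sign
    return GroundTruth(bn, loadings, noise_sd, n_groups, n_features_per_group,
                       n_visits, levels)


def sample_cohort(gt: GroundTruth, n: int, dropout_strength: float = 0.0,
                  seed: int = 0, return_latents: bool = False):
    """Sample a raw cohort: latent levels -> feature emissions -> MNAR drop-out.

    Drop-out is monotone per (patient, group): at each follow-up visit a
    still-observed block drops with hazard
    ``dropout_strength * sigmoid(gain * (level - (L-1)/2))`` — worse latent
    scores mean higher drop-out probability, and a dropped block stays
    missing at all later visits.  The baseline visit is always observed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= dropout_strength <= 1.0):
        raise ValueError("dropout_strength must be in [0, 1]")
    rng = np.random.default_rng(seed)
    latents = ancestral_sample(gt.bn, n, seed=int(rng.integers(2**31 - 1)))

    center = (gt.levels - 1) / 2.0
    cols: dict[str, np.ndarray] = {}
    for node in gt.bn.nodes:
        lv = latents[node].to_numpy(float)
        for j, col in enumerate(gt.feature_columns(node)):
            cols[col] = gt.loadings[node][j] * (lv - center) \
                + rng.normal(0.0, gt.noise_sd, size=n)
    data = pd.DataFrame(cols, index=[f"P{i + 1:04d}" for i in range(n)])

    if dropout_strength > 0:
        for g in range(gt.n_groups):
            dropped = np.zeros(n, bool)
            for t in range(1, gt.n_visits):
                node = node_name(gt.group(g), gt.visit(t))
                hazard = dropout_strength * expit(
                    gt.dropout_gain * (latents[node].to_numpy(float) - center))
                dropped |= rng.random(n) < hazard
                block = gt.feature_columns(node)
                data.loc[dropped, block] = np.nan
    cohort = CohortTable(data)
    latents.index = data.index
    return (cohort, latents) if return_latents else cohort
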