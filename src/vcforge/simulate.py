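"""Virtual-patient simulation, conservative filtering, and interventions.

Virtual patients are drawn from the fitted discrete BN by ancestral
sampling (parents before children, children conditioned on drawn parent
values).  Because model misfit or unobserved confounding can make some
draws unrealistic, a *conservative filter* scores every virtual patient
with a class-weighted random forest trained real-vs-virtual: the weight
(default 100) penalises misclassifying a real patient 100x more than a
virtual one, the forest's predicted probability of class "real" is the
patient's confidence score, and patients below the acceptance threshold
(default 0.5) are rejected.  Sampling and filtering loop until the desired
cohort size is reached.

Counterfactual interventions do(X_k = x) are simulated in the mutilated
network (all edges into X_k deleted) by logic sampling; for pure
do-interventions the intervened node is a root, so forward sampling needs
no rejection.  Per-patient target values (e.g. cognition scores shifted
towards a healthy median and re-encoded) are supported.  Conditioning
p(. | X = x) — a different operation — is available via
:func:`logic_sample`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .bayesnet import BayesNetError, DiscreteBN


class SimulationError(ValueError):
    pass


@dataclass
class VirtualCohort:
    """Virtual patients with per-patient confidence scores and accept flags."""

    table: pd.DataFrame
    confidence: np.ndarray
    accepted: np.ndarray
    threshold: float
    acceptance_log: list[float] = field(default_factory=list)

    @property
    def accepted_table(self) -> pd.DataFrame:
        return self.table[self.accepted].reset_index(drop=True)

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean()) if len(self.accepted) else 0.0


@dataclass
class InterventionSpec:
    """do()-intervention: per target node, a fixed level or a per-patient
    level vector (all vectors must share one length)."""

    targets: dict[str, int | np.ndarray]
    n: int | None = None
    seed: int = 0

    def n_rows(self) -> int | None:
        lengths = {len(v) for v in self.targets.values()
                   if isinstance(v, (np.ndarray, list, pd.Series))}
        if len(lengths) > 1:
            raise SimulationError("per-patient target vectors differ in length")
        if lengths:
            return lengths.pop()
        return self.n


def ancestral_sample(bn: DiscreteBN, n: int, seed: int = 0,
                     fixed: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Draw n joint samples in topological order.

    ``fixed`` optionally pins whole columns (used for per-patient
    interventions on root nodes of a mutilated network).
    """
    if n < 0:
        raise SimulationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    fixed = fixed or {}
    out: dict[str, np.ndarray] = {}
    for v in bn.topological_order():
        if v in fixed:
            vals = np.asarray(fixed[v], dtype=np.int64)
            if vals.ndim == 0:
                vals = np.full(n, int(vals))
            if len(vals) != n:
                raise SimulationError(f"fixed values for {v!r} have wrong length")
            if vals.min(initial=0) < 0 or (len(vals) and vals.max() >= bn.levels[v]):
                raise SimulationError(f"invalid level for node {v!r}")
            out[v] = vals
            continue
        cpt = bn.cpts[v]
        if bn.parents[v]:
            idx = tuple(out[p] for p in bn.parents[v])
            rows = cpt[idx]                      # (n, L)
        else:
            rows = np.broadcast_to(cpt, (n, len(cpt)))
        u = rng.random(n)[:, None]
        out[v] = (u > np.cumsum(rows, axis=1)).sum(axis=1).astype(np.int64)
    return pd.DataFrame({v: out[v] for v in bn.nodes})


def conservative_filter(real: pd.DataFrame, virtual: pd.DataFrame,
                        weight: float = 100.0, threshold: float = 0.5,
                        seed: int = 0, n_trees: int = 500) -> VirtualCohort:
    """Score virtual patients against the real distribution.

    Trains a random forest on real (sample weight = ``weight``) vs virtual
    (weight 1) and accepts virtual patients whose predicted probability of
    being real is >= ``threshold``.
    """
    if list(real.columns) != list(virtual.columns):
        raise SimulationError("real and virtual tables have different columns")
    if weight <= 0:
        raise SimulationError("weight must be > 0")
    X = pd.concat([real, virtual], ignore_index=True).to_numpy(float)
    y = np.r_[np.ones(len(real)), np.zeros(len(virtual))]
    # class weights act on the split criterion and leaf values (classic
    # weighted-RF semantics); confidence is the out-of-bag probability, so a
    # virtual patient is never scored by trees that memorised it
    tree = DecisionTreeClassifier(max_features="sqrt",
                                  class_weight={1.0: float(weight), 0.0: 1.0})
    rf = BaggingClassifier(tree, n_estimators=n_trees, random_state=seed,
                           n_jobs=1, oob_score=True)
    with np.errstate(invalid="ignore"):
        rf.fit(X, y)
    real_col = list(rf.classes_).index(1.0)
    proba_real = rf.oob_decision_function_[len(real):, real_col]
    if np.isnan(proba_real).any():  # rows that were in-bag in every tree
        fallback = rf.predict_proba(virtual.to_numpy(float))[:, real_col]
        proba_real = np.where(np.isnan(proba_real), fallback, proba_real)
    accepted = proba_real >= threshold
    return VirtualCohort(virtual.reset_index(drop=True), proba_real, accepted,
                         threshold)


def generate_vc(bn: DiscreteBN, real: pd.DataFrame, n_target: int,
                batch: int | None = None, max_rounds: int = 50,
                weight: float = 100.0, threshold: float = 0.5, seed: int = 0,
                n_trees: int = 500) -> VirtualCohort:
    """Iteratively sample -> filter -> append until n_target accepted."""
    if n_target < 1:
        raise SimulationError("n_target must be >= 1")
    batch = batch or n_target
    rng = np.random.default_rng(seed)
    tables, confs, log = [], [], []
    n_acc = 0
    for _ in range(max_rounds):
        draw = ancestral_sample(bn, batch, seed=int(rng.integers(2**31 - 1)))
        if threshold <= 0:
            vc = VirtualCohort(draw, np.ones(len(draw)), np.ones(len(draw), bool),
                               threshold)
        else:
            vc = conservative_filter(real, draw, weight=weight, threshold=threshold,
                                     seed=int(rng.integers(2**31 - 1)),
                                     n_trees=n_trees)
        log.append(vc.acceptance_rate)
        tables.append(vc.table[vc.accepted])
        confs.append(vc.confidence[vc.accepted])
        n_acc += int(vc.accepted.sum())
        if n_acc >= n_target:
            break
    if n_acc == 0:
        raise SimulationError(
            f"no virtual patient accepted after {max_rounds} rounds "
            f"(mean acceptance rate {np.mean(log):.3f})")
    table = pd.concat(tables, ignore_index=True).head(n_target)
    conf = np.concatenate(confs)[:len(table)]
    return VirtualCohort(table, conf, np.ones(len(table), bool), threshold,
                         acceptance_log=log)


def mutilate(bn: DiscreteBN, spec: InterventionSpec) -> DiscreteBN:
    """Delete all incoming edges of intervened nodes (Pearl's do-operator).

    Fixed-level targets get a point-mass CPT; per-patient targets become
    parentless with their CPT left as the (irrelevant) marginal placeholder,
    to be overridden at sampling time.
    """
    out = bn.copy()
    for node, value in spec.targets.items():
        if node not in out.levels:
            raise SimulationError(f"unknown target node {node!r}")
        L = out.levels[node]
        out.parents[node] = ()
        if isinstance(value, (int, np.integer)):
            if not (0 <= int(value) < L):
                raise SimulationError(f"invalid level {value} for node {node!r}")
            cpt = np.zeros(L)
            cpt[int(value)] = 1.0
            out.cpts[node] = cpt
        else:
            out.cpts[node] = np.full(L, 1.0 / L)
    return DiscreteBN(out.nodes, out.levels, out.parents, out.cpts, out.alpha)


def simulate_intervention(bn: DiscreteBN, spec: InterventionSpec,
                          n: int | None = None) -> pd.DataFrame:
    """Sample from p(. | do(targets)) in the mutilated network.

    Intervened nodes are roots of the mutilated BN, so logic sampling
    reduces to forward sampling with the target columns pinned.
    """
    rows = spec.n_rows() if n is None else n
    if rows is None:
        raise SimulationError("sample size not given (spec.n or n)")
    if rows == 0:
        return pd.DataFrame(columns=bn.nodes)
    mut = mutilate(bn, spec)
    fixed = {}
    for node, value in spec.targets.items():
        vals = np.full(rows, int(value)) if isinstance(value, (int, np.integer)) \
            else np.asarray(value, dtype=np.int64)
        if vals.min() < 0 or vals.max() >= bn.levels[node]:
            raise SimulationError(f"invalid level for node {node!r}")
        fixed[node] = vals
    return ancestral_sample(mut, rows, seed=spec.seed, fixed=fixed)


def logic_sample(bn: DiscreteBN, evidence: dict[str, int], n: int,
                 seed: int = 0, max_batches: int = 1000) -> pd.DataFrame:
    """Estimate p(. | evidence) by forward sampling with rejection.

    This is *conditioning*, not intervention: upstream nodes are affected
    by the evidence, unlike under do().
    """
    for node, lvl in evidence.items():
        if node not in bn.levels or not (0 <= int(lvl) < bn.levels[node]):
            raise SimulationError(f"invalid evidence {node!r}={lvl}")
    rng = np.random.default_rng(seed)
    kept: list[pd.DataFrame] = []
    n_kept = 0
    for _ in range(max_batches):
        draw = ancestral_sample(bn, max(n, 1000),
                                seed=int(rng.integers(2**31 - 1)))
        ok = np.ones(len(draw), bool)
        for node, lvl in evidence.items():
            ok &= draw[node].to_numpy() == int(lvl)
        if ok.any():
            kept.append(draw[ok])
            n_kept += int(ok.sum())
        if n_kept >= n:
            return pd.concat(kept, ignore_index=True).head(n)
    raise SimulationError("evidence has (near-)zero support; rejection sampling failed")
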