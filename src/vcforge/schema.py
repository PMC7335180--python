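"""Cohort schema: variable groups, visits, MNAR indicator nodes, constraints.

A longitudinal cohort is modelled as a set of *variable groups* (cognition
tests, CSF markers, imaging volumes, ...) measured at the visits of a study
schedule, plus static features (demographics, genotype).  The Bayesian
network downstream has one node per (group, visit) pair — the group's
autoencoded module score — plus one binary auxiliary node per (group, visit)
block that exhibits systematic missingness (patient drop-out, skipped
assessments).  Auxiliary nodes make the model explicitly missing-not-at-random
aware: missingness of a block is itself a modelled variable.

Edge constraints are declared at the level of *group classes* (demographics,
imaging, cognition, diagnosis, ...) and expanded here into a node-level
blacklist/whitelist consumed by structure learning.  Two constraint families
are structural and always applied: no edge may point backwards in time, and
auxiliary nodes are wired exclusively as aux(g,t) -> score(g,t) and
aux(g,t) -> aux(g,t_next).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

STATIC = "static"
AUX_PREFIX = "aux_"
AUX_CLASS = "aux"
WILDCARD = "*"

#: standard group-class vocabulary; user classes extend it via the group spec
CLASS_VOCABULARY = ("demographics", "history", "imaging", "cognition",
                    "diagnosis", "outcome", "nonmotor", "biomarker", AUX_CLASS)


class SchemaError(ValueError):
    """Raised for inconsistent group specifications or constraint rules."""


def node_name(group: str, visit: str) -> str:
    return f"{group}@{visit}"


def column_name(feature: str, visit: str) -> str:
    return f"{feature}@{visit}"


@dataclass(frozen=True)
class FeatureSpec:
    """One measured feature at one visit (or 'static')."""

    name: str
    dtype: str  # continuous | categorical | ordinal
    group: str
    visit: str

    def __post_init__(self):
        if self.dtype not in ("continuous", "categorical", "ordinal"):
            raise SchemaError(f"unknown dtype {self.dtype!r} for feature {self.name!r}")

    @property
    def column(self) -> str:
        return column_name(self.name, self.visit)

    @property
    def node(self) -> str:
        return node_name(self.group, self.visit)


@dataclass(frozen=True)
class VisitSchedule:
    """Ordered study visits with numeric offsets in months."""

    labels: tuple[str, ...]
    offsets: tuple[float, ...]

    def __post_init__(self):
        if len(self.labels) != len(self.offsets):
            raise SchemaError("labels and offsets differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise SchemaError("duplicate visit labels")
        if any(b <= a for a, b in zip(self.offsets, self.offsets[1:])):
            raise SchemaError("visit offsets must be strictly increasing")
        if STATIC in self.labels:
            raise SchemaError(f"{STATIC!r} is a reserved visit label")

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def offset(self, label: str) -> float:
        return self.offsets[self.index(label)]


@dataclass(frozen=True)
class GroupClassRule:
    """Group-class-level edge rule; classes may be the wildcard '*'."""

    source: str
    target: str
    direction: str  # allowed | forbidden

    def __post_init__(self):
        if self.direction not in ("allowed", "forbidden"):
            raise SchemaError(f"rule direction must be allowed/forbidden, got {self.direction!r}")

    def matches(self, src_class: str, tgt_class: str) -> bool:
        return (self.source in (WILDCARD, src_class)) and (self.target in (WILDCARD, tgt_class))


@dataclass(frozen=True)
class ConstraintSet:
    """Node-level edge constraints for structure learning.

    ``blacklist`` edges may never appear; ``whitelist`` edges are forced
    present and clamped during search.  The two sets are disjoint.
    """

    nodes: tuple[str, ...]
    blacklist: frozenset[tuple[str, str]]
    whitelist: frozenset[tuple[str, str]]

    def __post_init__(self):
        overlap = self.blacklist & self.whitelist
        if overlap:
            raise SchemaError(f"blacklist and whitelist overlap: {sorted(overlap)[:3]}")
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.whitelist)
        if not nx.is_directed_acyclic_graph(g):
            raise SchemaError("whitelist is cyclic")

    def allows(self, u: str, v: str) -> bool:
        return u != v and (u, v) not in self.blacklist


class GroupSpec:
    """Validated collection of feature specs + schedule + group classes."""

    def __init__(self, features: list[FeatureSpec], schedule: VisitSchedule,
                 group_classes: dict[str, str]):
        self.features = list(features)
        self.schedule = schedule
        self.group_classes = dict(group_classes)
        self._validate()

    def _validate(self):
        seen_cols: set[str] = set()
        name_group: dict[str, str] = {}
        for f in self.features:
            if f.column in seen_cols:
                raise SchemaError(f"duplicate feature {f.name!r} at visit {f.visit!r}")
            seen_cols.add(f.column)
            if f.name in name_group and name_group[f.name] != f.group:
                raise SchemaError(
                    f"feature {f.name!r} assigned to two groups "
                    f"({name_group[f.name]!r}, {f.group!r})")
            name_group[f.name] = f.group
            if f.visit != STATIC and f.visit not in self.schedule:
                raise SchemaError(f"unknown visit label {f.visit!r} for feature {f.name!r}")
            if f.group not in self.group_classes:
                raise SchemaError(f"group {f.group!r} has no declared class")

    @property
    def groups(self) -> list[str]:
        out = []
        for f in self.features:
            if f.group not in out:
                out.append(f.group)
        return out

    @property
    def columns(self) -> list[str]:
        return [f.column for f in self.features]

    def group_block(self, group: str, visit: str) -> list[str]:
        """Column names of one group at one visit."""
        return [f.column for f in self.features if f.group == group and f.visit == visit]

    def group_visits(self, group: str) -> list[str]:
        """Visits at which a group is measured, schedule order, static first."""
        vis = {f.visit for f in self.features if f.group == group}
        ordered = [STATIC] if STATIC in vis else []
        ordered += [v for v in self.schedule.labels if v in vis]
        return ordered

    def nodes(self) -> list[tuple[str, str, str]]:
        """(node, class, visit) triples, static nodes first then by visit."""
        out, seen = [], set()
        feats = sorted(
            self.features,
            key=lambda f: (-1.0 if f.visit == STATIC else self.schedule.offset(f.visit), f.group),
        )
        for f in feats:
            key = (f.group, f.visit)
            if key not in seen:
                seen.add(key)
                out.append((node_name(*key), self.group_classes[f.group], f.visit))
        return out

    def to_dict(self) -> dict:
        groups: dict[str, dict] = {}
        for f in self.features:
            g = groups.setdefault(f.group, {"name": f.group,
                                            "class": self.group_classes[f.group],
                                            "features": {}})
            entry = g["features"].setdefault(f.name, {"name": f.name, "dtype": f.dtype,
                                                      "visits": []})
            entry["visits"].append(f.visit)
        return {
            "visits": [{"label": l, "month": o}
                       for l, o in zip(self.schedule.labels, self.schedule.offsets)],
            "groups": [{**g, "features": list(g["features"].values())}
                       for g in groups.values()],
        }

    def save(self, path: str | Path):
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(self.to_dict(), fh, indent=1)
            else:
                yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def __eq__(self, other):
        return (isinstance(other, GroupSpec)
                and self.features == other.features
                and self.schedule == other.schedule
                and self.group_classes == other.group_classes)


def load_group_spec(path: str | Path) -> GroupSpec:
    """Load a YAML/JSON group specification file.

    Expected layout::

        visits:
          - {label: bl,  month: 0}
          - {label: m06, month: 6}
        groups:
          - name: cognition
            class: cognition
            features:
              - {name: adas11, dtype: continuous, visits: [bl, m06]}
          - name: demographics
            class: demographics
            features:
              - {name: age, dtype: continuous, visits: static}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return group_spec_from_dict(raw)


def group_spec_from_dict(raw: dict) -> GroupSpec:
    try:
        schedule = VisitSchedule(
            labels=tuple(v["label"] for v in raw["visits"]),
            offsets=tuple(float(v["month"]) for v in raw["visits"]),
        )
        features: list[FeatureSpec] = []
        classes: dict[str, str] = {}
        for g in raw["groups"]:
            classes[g["name"]] = g["class"]
            for f in g["features"]:
                visits = f["visits"]
                if isinstance(visits, str):
                    visits = [visits]
                for v in visits:
                    features.append(FeatureSpec(f["name"], f["dtype"], g["name"], v))
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed group spec: {exc}") from exc
    return GroupSpec(features, schedule, classes)


class CohortTable:
    """Patients x (feature@visit) raw values with an explicit missingness mask.

    Backed by a pandas DataFrame indexed by patient id; missing cells are NaN
    and the boolean mask is derived from them (mask True <=> value absent).
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.duplicated().any():
            raise SchemaError("duplicated patient identifiers")
        self.data = data.copy()
        self.data.index.name = "patient_id"

    @property
    def mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def n_patients(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data)

    @classmethod
    def from_csv(cls, path: str | Path, sep: str = ",") -> "CohortTable":
        df = pd.read_csv(path, sep=sep, index_col="patient_id",
                         na_values=["NA"], keep_default_na=True)
        return cls(df)

    def to_csv(self, path: str | Path, sep: str = ","):
        self.data.to_csv(path, sep=sep, na_rep="NA")


def add_auxiliary_nodes(cohort: CohortTable, gspec: GroupSpec
                        ) -> tuple[CohortTable, GroupSpec]:
    """Add one binary MNAR indicator per (group, visit) block containing
    missing values.

    The indicator is 0 iff the patient's *entire* group block at that visit
    is missing (systematic missingness: drop-out, skipped assessment) and 1
    otherwise; isolated missing cells inside an otherwise observed block
    leave the indicator at 1 and are handled by imputation.  Indicator
    features live in their own group ``aux_<group>`` with class ``aux``.
    Blocks without any missing cell get no indicator.
    """
    data = cohort.data.copy()
    features = list(gspec.features)
    classes = dict(gspec.group_classes)
    mask = cohort.mask
    for group in gspec.groups:
        if group.startswith(AUX_PREFIX):
            continue
        for visit in gspec.group_visits(group):
            block = [c for c in gspec.group_block(group, visit) if c in data.columns]
            if not block or not mask[block].to_numpy().any():
                continue
            aux_group = AUX_PREFIX + group
            indicator = (~mask[block].all(axis=1)).astype(int)
            spec = FeatureSpec(aux_group, "categorical", aux_group, visit)
            data[spec.column] = indicator
            features.append(spec)
            classes[aux_group] = AUX_CLASS
    return CohortTable(data), GroupSpec(features, gspec.schedule, classes)


def default_rules() -> list[GroupClassRule]:
    """Default class-level edge rules for AD/PD-like observational cohorts.

    Vocabulary: demographics, history, imaging, cognition, diagnosis,
    outcome, nonmotor, biomarker, aux.  Demographics only influence (never
    receive); imaging features relate only to each other; diagnosis depends
    on cognition but never drives it.  Everything not forbidden is allowed;
    temporal ordering and aux wiring are structural and added automatically
    by :func:`expand_constraints`.
    """
    return [
        GroupClassRule(WILDCARD, "demographics", "forbidden"),
        GroupClassRule("imaging", WILDCARD, "forbidden"),
        GroupClassRule("imaging", "imaging", "allowed"),
        GroupClassRule("diagnosis", "cognition", "forbidden"),
    ]


def load_rules(path: str | Path) -> list[GroupClassRule]:
    """Load class-level rules from YAML/JSON: a list of
    {source, target, direction} mappings under key ``rules``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    items = raw["rules"] if isinstance(raw, dict) else raw
    return [GroupClassRule(r["source"], r["target"], r["direction"]) for r in items]


def expand_constraints(gspec: GroupSpec, rules: list[GroupClassRule] | None = None
                       ) -> ConstraintSet:
    """Expand class-level rules + structural constraints into node-level sets.

    Blacklist = rule-forbidden class pairs (minus explicit 'allowed'
    exceptions) + all time-backward edges + everything touching an aux node
    except its fixed wiring.  Whitelist = aux(g,t) -> score(g,t) and
    aux(g,t) -> aux(g,t_next).  Deterministic given (gspec, rules).
    """
    if rules is None:
        rules = default_rules()
    nodes = gspec.nodes()
    declared = set(gspec.group_classes.values()) | set(CLASS_VOCABULARY) | {WILDCARD}
    for r in rules:
        for cls in (r.source, r.target):
            if cls not in declared:
                raise SchemaError(f"rule references undeclared class {cls!r}")

    node_names = tuple(n for n, _, _ in nodes)
    cls_of = {n: c for n, c, _ in nodes}
    visit_of = {n: v for n, _, v in nodes}

    def toffset(n: str) -> float | None:
        v = visit_of[n]
        return None if v == STATIC else gspec.schedule.offset(v)

    blacklist: set[tuple[str, str]] = set()
    whitelist: set[tuple[str, str]] = set()

    forbidden = [r for r in rules if r.direction == "forbidden"]
    allowed = [r for r in rules if r.direction == "allowed"]
    for u in node_names:
        for v in node_names:
            if u == v:
                continue
            cu, cv = cls_of[u], cls_of[v]
            if any(r.matches(cu, cv) for r in forbidden) and \
               not any(r.matches(cu, cv) for r in allowed):
                blacklist.add((u, v))
            ou, ov = toffset(u), toffset(v)
            if ou is not None and ov is not None and ou > ov:
                blacklist.add((u, v))

    # aux wiring: aux(g,t) -> score(g,t), aux(g,t) -> aux(g,t_next); nothing else
    aux_nodes = [n for n in node_names if cls_of[n] == AUX_CLASS]
    aux_allowed: set[tuple[str, str]] = set()
    for group in gspec.groups:
        if not group.startswith(AUX_PREFIX):
            continue
        base = group[len(AUX_PREFIX):]
        chain = [node_name(group, v) for v in gspec.group_visits(group)]
        for a in chain:
            score = node_name(base, visit_of[a])
            if score in cls_of:
                aux_allowed.add((a, score))
        for a, b in zip(chain, chain[1:]):
            aux_allowed.add((a, b))
    for a in aux_nodes:
        for v in node_names:
            if v != a and (a, v) not in aux_allowed:
                blacklist.add((a, v))
            if v != a and (v, a) not in aux_allowed:
                blacklist.add((v, a))
    whitelist |= aux_allowed
    blacklist -= whitelist
    return ConstraintSet(node_names, frozenset(blacklist), frozenset(whitelist))
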