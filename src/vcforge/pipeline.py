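"""End-to-end model fitting: raw cohort -> fitted generative model.

Chains the module stages in the order the method prescribes:

1. add auxiliary MNAR indicator nodes per (group, visit) block;
2. impute remaining scattered missing cells (missForest);
3. train one sparse autoencoder per multi-feature group@visit and encode
   each block to its module score (single-feature groups and aux
   indicators pass through);
4. discretize module scores (supervised tree or unsupervised GMM);
5. expand class-level constraint rules to a node-level blacklist/whitelist
   and learn the BN structure + Dirichlet-smoothed parameters.

The result bundles everything needed to generate and evaluate virtual
cohorts and to decode interventions back to raw feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import autoencoder as ae
from . import bayesnet, discretize, missing_data, schema


@dataclass
class GroupEncoder:
    """Preprocessing + trained autoencoder for one group@visit block."""

    columns: list[str]
    means: np.ndarray
    sds: np.ndarray
    encoder: ae.TrainedEncoder

    def transform(self, data: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.columns if c not in data.columns]
        if missing:
            raise ae.AutoencoderError(f"unseen features: {missing}")
        X = data[self.columns].to_numpy(float)
        return (X - self.means) / self.sds

    def encode(self, data: pd.DataFrame) -> np.ndarray:
        return self.encoder.encode(self.transform(data))

    def decode(self, Z: np.ndarray) -> pd.DataFrame:
        X = self.encoder.decode(np.asarray(Z, float))
        return pd.DataFrame(X * self.sds + self.means, columns=self.columns)


def fit_encoders(cohort: schema.CohortTable, gspec: schema.GroupSpec,
                 q: int = 1, grid: list[ae.AutoencoderSpec] | None = None,
                 seed: int = 0) -> dict[str, GroupEncoder]:
    """Train one autoencoder per multi-feature (group, visit) block.

    Continuous columns are z-scored with training statistics; the
    standardization is stored and reused at encode/decode time.  Blocks
    with a single feature get an identity encoder.
    """
    encoders: dict[str, GroupEncoder] = {}
    for node, cls, visit in gspec.nodes():
        if cls == schema.AUX_CLASS:
            continue
        group = node.split("@")[0]
        cols = [c for c in gspec.group_block(group, visit)
                if c in cohort.data.columns]
        if not cols:
            continue
        X = cohort.data[cols].to_numpy(float)
        if np.isnan(X).any():
            raise ae.AutoencoderError(f"missing values in block {node!r}; impute first")
        means = X.mean(axis=0)
        sds = X.std(axis=0)
        sds[sds == 0] = 1.0
        Xs = (X - means) / sds
        if len(cols) == 1:
            enc = ae.IdentityEncoder(1)
        else:
            g = grid or ae.default_grid(q=q, d=len(cols), seed=seed)
            enc = ae.train_group_autoencoder(Xs, g, seed=seed)
        encoders[node] = GroupEncoder(cols, means, sds, enc)
    return encoders


def encode_cohort(cohort: schema.CohortTable, gspec: schema.GroupSpec,
                  encoders: dict[str, GroupEncoder]) -> pd.DataFrame:
    """Patients x module-score table; aux indicators pass through."""
    out: dict[str, np.ndarray] = {}
    for node, cls, visit in gspec.nodes():
        group = node.split("@")[0]
        if cls == schema.AUX_CLASS:
            col = schema.column_name(group, visit)
            out[node] = cohort.data[col].to_numpy(float)
            continue
        enc = encoders[node]
        Z = enc.encode(cohort.data)
        if Z.shape[1] == 1:
            out[node] = Z[:, 0]
        else:
            for j in range(Z.shape[1]):
                out[f"{node}#{j}"] = Z[:, j]
    return pd.DataFrame(out, index=cohort.data.index)


def decode_scores(scores: pd.DataFrame,
                  encoders: dict[str, GroupEncoder]) -> pd.DataFrame:
    """Map module scores back to raw feature space (continuous blocks)."""
    parts = []
    for node, enc in encoders.items():
        cols = [c for c in scores.columns
                if c == node or c.startswith(f"{node}#")]
        if not cols:
            continue
        part = enc.decode(scores[cols].to_numpy(float))
        part.index = scores.index
        parts.append(part)
    return pd.concat(parts, axis=1)


@dataclass
class FittedPipeline:
    """Everything learned from one cohort."""

    gspec: schema.GroupSpec
    constraints: schema.ConstraintSet
    encoders: dict[str, GroupEncoder]
    maps: dict[str, discretize.DiscretizationMap | None]
    bn: bayesnet.DiscreteBN
    node_table: pd.DataFrame  # discretized training data, BN node space

    def encode_discrete(self, cohort: schema.CohortTable) -> pd.DataFrame:
        scores = encode_cohort(cohort, self.gspec, self.encoders)
        return discretize.apply_discretization(scores, self.maps)


def fit_pipeline(cohort: schema.CohortTable, gspec: schema.GroupSpec,
                 rules: list[schema.GroupClassRule] | None = None,
                 labels=None, algorithm: str = "hc", restarts: int = 10,
                 alpha: float = 1.0, max_components: int = 5,
                 impute_trees: int = 100, impute_iter: int = 10,
                 grid: list[ae.AutoencoderSpec] | None = None,
                 q: int = 1, seed: int = 0) -> FittedPipeline:
    """Fit the full generative model on a raw cohort.

    ``labels`` switches discretization to the supervised tree mode (one
    label per patient, e.g. baseline diagnosis); without labels the
    unsupervised GMM mode is used.
    """
    cohort2, gspec2 = schema.add_auxiliary_nodes(cohort, gspec)
    if cohort2.mask.to_numpy().any():
        result = missing_data.rf_impute(cohort2, n_trees=impute_trees,
                                        max_iter=impute_iter, seed=seed)
        cohort2 = result.cohort
    encoders = fit_encoders(cohort2, gspec2, q=q, grid=grid, seed=seed)
    scores = encode_cohort(cohort2, gspec2, encoders)

    aux_nodes = {n for n, cls, _ in gspec2.nodes() if cls == schema.AUX_CLASS}
    maps: dict[str, discretize.DiscretizationMap | None] = {}
    for col in scores.columns:
        base = col.split("#")[0]
        if base in aux_nodes:
            maps[col] = None  # binary indicator, already discrete
        elif labels is not None:
            maps[col] = discretize.tree_discretize(scores[col].to_numpy(),
                                                   np.asarray(labels))
        else:
            maps[col] = discretize.gmm_discretize(scores[col].to_numpy(),
                                                  max_components=max_components,
                                                  seed=seed)
    node_table = discretize.apply_discretization(scores, maps)

    constraints = schema.expand_constraints(gspec2, rules)
    dag = bayesnet.learn_structure(node_table, constraints, algorithm=algorithm,
                                   restarts=restarts, seed=seed, alpha=alpha)
    bn = bayesnet.fit_parameters(dag, node_table, alpha=alpha)
    return FittedPipeline(gspec2, constraints, encoders, maps, bn, node_table)
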