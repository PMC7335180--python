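"""Discretization of module scores and continuous static features.

Two modes mirror the two kinds of cohorts this tool targets:

* supervised tree discretization — when a clinically meaningful label
  exists (e.g. baseline diagnosis), a depth-limited univariate CART
  classifier is fit to (value -> label) and its split thresholds become the
  cut points; levels are the tree leaves, ordered by value;
* unsupervised GMM discretization — univariate Gaussian mixtures with the
  component count selected by BIC; values are assigned to their
  maximum-responsibility component, levels ordered by component mean.

Both produce a variable number of levels per feature.  Cut-point maps are
monotone; GMM maps assign by responsibility (robust to overlapping
components).  Out-of-range values clamp to the nearest boundary level and
missing values stay missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture
from sklearn.tree import DecisionTreeClassifier


class DiscretizationError(ValueError):
    pass


@dataclass
class DiscretizationMap:
    """Invertible value -> level map for one feature.

    ``kind`` is "cuts" (ordered thresholds, level = number of cuts below the
    value) or "gmm" (component parameters, level = max-responsibility
    component after ordering by mean).
    """

    kind: str
    n_levels: int
    cuts: np.ndarray | None = None                 # kind == "cuts"
    means: np.ndarray | None = None                # kind == "gmm"
    sds: np.ndarray | None = None
    weights: np.ndarray | None = None
    vmin: float = float("nan")
    vmax: float = float("nan")

    def __post_init__(self):
        if self.kind not in ("cuts", "gmm"):
            raise DiscretizationError(f"unknown map kind {self.kind!r}")
        if self.n_levels < 1:
            raise DiscretizationError("level count must be >= 1")
        if self.kind == "cuts" and self.cuts is not None and len(self.cuts) > 1:
            if not np.all(np.diff(self.cuts) > 0):
                raise DiscretizationError("cut points must be strictly increasing")

    def apply(self, values) -> np.ndarray:
        """Map values to integer levels (float array; NaN stays NaN)."""
        x = np.asarray(values, float)
        out = np.full(x.shape, np.nan)
        obs = np.isfinite(x)
        if self.n_levels == 1:
            out[obs] = 0
            return out
        if self.kind == "cuts":
            out[obs] = np.searchsorted(self.cuts, x[obs], side="right")
        else:
            logp = (
                -0.5 * ((x[obs, None] - self.means[None, :]) / self.sds[None, :]) ** 2
                - np.log(self.sds[None, :])
                + np.log(self.weights[None, :])
            )
            out[obs] = np.argmax(logp, axis=1)
        return out

    def midpoints(self) -> np.ndarray:
        """Representative value per level (inverse map for round trips)."""
        if self.kind == "gmm":
            return np.asarray(self.means, float)
        edges = np.concatenate(([self.vmin], np.asarray(self.cuts, float), [self.vmax])) \
            if self.n_levels > 1 else np.array([self.vmin, self.vmax])
        return (edges[:-1] + edges[1:]) / 2.0


def tree_discretize(values, labels, max_levels: int = 4,
                    min_leaf: float = 0.05) -> DiscretizationMap:
    """Supervised cut points from a depth-limited univariate CART tree.

    ``min_leaf`` is a fraction of n if < 1, else an absolute count.  Falls
    back to :func:`gmm_discretize` (with a warning) when only one label
    class is present.
    """
    x = np.asarray(values, float)
    y = np.asarray(labels)
    if len(x) != len(y):
        raise DiscretizationError("values and labels differ in length")
    if not np.isfinite(x).all():
        raise DiscretizationError("non-finite values")
    if np.unique(x).size == 1:
        return DiscretizationMap("cuts", 1, cuts=np.array([]),
                                 vmin=float(x.min()), vmax=float(x.max()))
    if np.unique(y).size < 2:
        warnings.warn("single label class; falling back to GMM discretization")
        return gmm_discretize(x, max_components=max_levels, seed=0)

    leaf = int(np.ceil(min_leaf * len(x))) if min_leaf < 1 else int(min_leaf)
    tree = DecisionTreeClassifier(max_leaf_nodes=max_levels,
                                  min_samples_leaf=max(1, leaf),
                                  random_state=0)
    tree.fit(x.reshape(-1, 1), y)
    thr = tree.tree_.threshold[tree.tree_.feature == 0]
    cuts = np.unique(thr)
    return DiscretizationMap("cuts", len(cuts) + 1, cuts=cuts,
                             vmin=float(x.min()), vmax=float(x.max()))


def gmm_discretize(values, max_components: int = 5, seed: int = 0
                   ) -> DiscretizationMap:
    """Unsupervised univariate GMM clustering, component count by BIC."""
    x = np.asarray(values, float)
    if not np.isfinite(x).all():
        raise DiscretizationError("non-finite values")
    if len(x) < 10:
        raise DiscretizationError("need >= 10 observations for GMM discretization")
    if np.unique(x).size == 1:
        return DiscretizationMap("gmm", 1, means=np.array([x[0]]),
                                 sds=np.array([1.0]), weights=np.array([1.0]),
                                 vmin=float(x.min()), vmax=float(x.max()))

    X = x.reshape(-1, 1)
    best, best_bic = None, np.inf
    kmax = min(max_components, np.unique(x).size)
    for k in range(1, kmax + 1):
        gm = GaussianMixture(n_components=k, random_state=seed, n_init=2,
                             reg_covar=1e-6)
        gm.fit(X)
        bic = gm.bic(X)
        if bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    order = np.argsort(best.means_.ravel())
    means = best.means_.ravel()[order]
    sds = np.sqrt(best.covariances_.ravel()[order])
    weights = best.weights_.ravel()[order]
    return DiscretizationMap("gmm", best.n_components, means=means, sds=sds,
                             weights=weights, vmin=float(x.min()), vmax=float(x.max()))


def apply_discretization(table: pd.DataFrame,
                         maps: dict[str, DiscretizationMap]) -> pd.DataFrame:
    """Apply per-feature maps to a scores/cohort table.

    Columns without a map raise; integer/boolean columns may be declared
    pre-discrete by mapping them with ``None``.
    """
    out = {}
    for col in table.columns:
        if col not in maps:
            raise DiscretizationError(f"no discretization map for feature {col!r}")
        m = maps[col]
        if m is None:
            out[col] = table[col].astype(float)
        else:
            out[col] = m.apply(table[col].to_numpy())
    return pd.DataFrame(out, index=table.index)
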