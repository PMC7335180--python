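"""Iterative random-forest (missForest-style) imputation of mixed-type tables.

After block-level missingness has been absorbed by auxiliary indicator
nodes, the remaining scattered missing cells are completed by the missForest
algorithm: initialise with column mean/mode, then repeatedly re-predict the
missing entries of each column from all other columns with a random forest,
looping over columns in increasing order of missingness, until the
convergence statistic first increases.  The returned table is the state of
the iteration *before* that increase.

Continuous columns use regression forests; categorical/ordinal columns use
classification forests, one-hot encoded when acting as predictors.  Observed
cells are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .schema import CohortTable


class ImputationError(ValueError):
    pass


@dataclass
class ImputationResult:
    cohort: CohortTable
    conv_continuous: list[float] = field(default_factory=list)
    conv_categorical: list[float] = field(default_factory=list)
    n_iter: int = 0


def _is_continuous(s: pd.Series) -> bool:
    return pd.api.types.is_float_dtype(s) or (
        pd.api.types.is_numeric_dtype(s) and s.dropna().nunique() > 10)


def _one_hot(df: pd.DataFrame, cat_cols: list[str]) -> pd.DataFrame:
    if not cat_cols:
        return df
    return pd.get_dummies(df, columns=[c for c in cat_cols if c in df.columns],
                          dtype=float)


def rf_impute(cohort: CohortTable, n_trees: int = 100, max_iter: int = 10,
              seed: int = 0) -> ImputationResult:
    """Complete all missing cells of a cohort table via missForest.

    Parameters
    ----------
    n_trees : forest size per column per iteration.
    max_iter : hard cap on missForest sweeps.
    seed : controls forest randomness; identical seeds give identical output.
    """
    if n_trees < 1:
        raise ImputationError("n_trees must be >= 1")
    data = cohort.data.copy()
    mask = cohort.mask

    for col in data.columns:
        if mask[col].all():
            raise ImputationError(f"column {col!r} is entirely missing")
        obs = data[col].dropna()
        if pd.api.types.is_numeric_dtype(obs) and not np.isfinite(obs.to_numpy(float)).all():
            raise ImputationError(f"non-finite observed value in column {col!r}")

    miss_cols = [c for c in data.columns if mask[c].any()]
    if not miss_cols:
        return ImputationResult(CohortTable(data), [], [], 0)

    cont = {c for c in data.columns if _is_continuous(data[c])}
    cat_predictors = [c for c in data.columns if c not in cont]

    # initial fill: mean for continuous, mode for categorical
    for col in miss_cols:
        if col in cont:
            data.loc[mask[col], col] = data[col].mean()
        else:
            data.loc[mask[col], col] = data[col].mode().iloc[0]

    miss_cols.sort(key=lambda c: mask[c].sum())
    rng = np.random.default_rng(seed)

    conv_c: list[float] = []
    conv_f: list[float] = []
    best = data.copy()
    n_done = 0
    for it in range(max_iter):
        old = data.copy()
        for col in miss_cols:
            rows_obs = ~mask[col]
            rows_mis = mask[col]
            X = _one_hot(data.drop(columns=[col]), cat_predictors)
            rs = int(rng.integers(2**31 - 1))
            if col in cont:
                model = RandomForestRegressor(n_estimators=n_trees, random_state=rs,
                                              n_jobs=1)
                model.fit(X[rows_obs], data.loc[rows_obs, col].astype(float))
                data.loc[rows_mis, col] = model.predict(X[rows_mis])
            else:
                model = RandomForestClassifier(n_estimators=n_trees, random_state=rs,
                                               n_jobs=1)
                model.fit(X[rows_obs], data.loc[rows_obs, col])
                data.loc[rows_mis, col] = model.predict(X[rows_mis])

        # convergence statistics over imputed cells only
        gamma_c = 0.0
        cc = [c for c in miss_cols if c in cont]
        if cc:
            new = np.concatenate([data.loc[mask[c], c].to_numpy(float) for c in cc])
            was = np.concatenate([old.loc[mask[c], c].to_numpy(float) for c in cc])
            denom = float(np.sum(new**2))
            gamma_c = float(np.sum((new - was) ** 2) / denom) if denom > 0 else 0.0
        gamma_f = 0.0
        fc = [c for c in miss_cols if c not in cont]
        if fc:
            changed = sum((data.loc[mask[c], c] != old.loc[mask[c], c]).sum() for c in fc)
            total = sum(int(mask[c].sum()) for c in fc)
            gamma_f = changed / total if total else 0.0

        increased_c = bool(cc) and len(conv_c) > 0 and gamma_c > conv_c[-1]
        increased_f = bool(fc) and len(conv_f) > 0 and gamma_f > conv_f[-1]
        conv_c.append(gamma_c)
        conv_f.append(gamma_f)
        n_done = it + 1
        stop = (increased_c or not cc) and (increased_f or not fc) and (cc or fc) \
            and (increased_c or increased_f)
        if stop:
            best = old  # values from the iteration before the increase
            break
        best = data.copy()

    for col in data.columns:  # observed cells must be untouched
        assert (best.loc[~mask[col], col] == cohort.data.loc[~mask[col], col]).all()
    return ImputationResult(CohortTable(best), conv_c, conv_f, n_done)
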