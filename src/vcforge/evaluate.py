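"""Real-vs-virtual similarity evaluation.

The headline metric is the standardized partial AUC of a random-forest
classifier discriminating real from virtual patients, restricted to the
high-sensitivity region (detection rate for *real* patients >= 90%):
misclassifying a virtual patient as real is deliberately under-penalised.
The partial area A is the trapezoidal area under the ROC curve expressed as
specificity over sensitivity in [sens_lo, 1], standardized to [0, 1] via

    A_std = 1/2 * (1 + (A - A_min) / (A_max - A_min)),

with A_max = 1 - sens_lo (perfect classifier) and A_min the area under the
chance diagonal over the same region, so 0.5 is chance level.  The metric
is assessed over repeated stratified k-fold cross-validation.

Univariate similarity uses per-variable chi-square homogeneity tests on the
2 x L level contingency tables with multiple-testing correction
(Benjamini-Hochberg by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import RepeatedStratifiedKFold
from statsmodels.stats.multitest import multipletests


class EvaluationError(ValueError):
    pass


@dataclass
class PaucReport:
    """Fold x repeat matrix of standardized pAUC values."""

    values: np.ndarray  # shape (repeats, k)
    sens_lo: float

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.values, [25, 75])
        return float(lo), float(hi)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))


def pauc(scores, labels, sens_lo: float = 0.9, positive="real") -> float:
    """Standardized partial AUC over sensitivity in [sens_lo, 1].

    ``labels`` mark each subject real/virtual; ``positive`` names the class
    whose detection rate defines sensitivity.  Scores are the classifier's
    probability (or any monotone score) of the positive class.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    if not (0.0 <= sens_lo < 1.0):
        raise EvaluationError("sens_lo must be in [0, 1)")
    y = labels == positive
    if y.all() or not y.any():
        raise EvaluationError("both classes must be present")
    fpr, tpr, _ = roc_curve(y, scores)
    se, sp = tpr, 1.0 - fpr  # ROC as specificity over sensitivity

    area = 0.0
    for i in range(len(se) - 1):
        s0, s1 = se[i], se[i + 1]
        p0, p1 = sp[i], sp[i + 1]
        if s1 <= sens_lo or s1 == s0:
            continue
        if s0 < sens_lo:  # clip segment at the region boundary
            frac = (sens_lo - s0) / (s1 - s0)
            p0 = p0 + frac * (p1 - p0)
            s0 = sens_lo
        area += 0.5 * (p0 + p1) * (s1 - s0)

    a_max = 1.0 - sens_lo
    a_min = 0.5 * (1.0 - sens_lo) ** 2  # chance diagonal sp = 1 - se
    std = 0.5 * (1.0 + (area - a_min) / (a_max - a_min))
    return float(min(max(std, 0.0), 1.0))


def pauc_cv(real: pd.DataFrame, virtual: pd.DataFrame, k: int = 10,
            repeats: int = 10, sens_lo: float = 0.9, seed: int = 0,
            n_trees: int = 100) -> PaucReport:
    """Repeated stratified k-fold CV of a real-vs-virtual random forest.

    An unweighted forest is trained on each training split; the standardized
    pAUC is computed on each held-out fold with "real" as positive class.
    """
    if len(real) < k or len(virtual) < k:
        raise EvaluationError("fewer rows than folds")
    if list(real.columns) != list(virtual.columns):
        raise EvaluationError("real and virtual tables have different columns")
    X = pd.concat([real, virtual], ignore_index=True).to_numpy(float)
    y = np.array(["real"] * len(real) + ["virtual"] * len(virtual))
    cv = RepeatedStratifiedKFold(n_splits=k, n_repeats=repeats, random_state=seed)
    vals = np.empty(repeats * k)
    for i, (tr, te) in enumerate(cv.split(X, y)):
        rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed + i,
                                    n_jobs=1)
        rf.fit(X[tr], y[tr])
        p_real = rf.predict_proba(X[te])[:, list(rf.classes_).index("real")]
        vals[i] = pauc(p_real, y[te], sens_lo=sens_lo)
    return PaucReport(vals.reshape(repeats, k), sens_lo)


@dataclass
class HomogeneityReport:
    """Per-feature chi-square homogeneity tests, real vs virtual."""

    table: pd.DataFrame  # feature, chi2, dof, p, p_adj, skipped
    correction: str

    def rejected(self, alpha: float = 0.05) -> pd.Series:
        ok = ~self.table["skipped"]
        return self.table.loc[ok, "p_adj"] < alpha


def homogeneity_tests(real: pd.DataFrame, virtual: pd.DataFrame,
                      correction: str = "fdr_bh") -> HomogeneityReport:
    """Per-variable 2 x L chi-square tests of identical level distributions.

    Columns with a single observed level pooled across both samples are
    skipped and flagged (the test is undefined there).  Adjusted p-values
    use the configured statsmodels correction method.
    """
    shared = [c for c in real.columns if c in virtual.columns]
    if not shared:
        raise EvaluationError("no shared columns")
    rows = []
    for col in shared:
        r = real[col].dropna()
        v = virtual[col].dropna()
        levels = sorted(set(r.unique()) | set(v.unique()))
        if len(levels) < 2:
            rows.append((col, 0.0, 0, np.nan, np.nan, True))
            continue
        obs = np.array([[int((r == l).sum()) for l in levels],
                        [int((v == l).sum()) for l in levels]], float)
        if (obs.sum(axis=1) == 0).any():
            rows.append((col, 0.0, 0, np.nan, np.nan, True))
            continue
        chi2, p, dof, _ = chi2_contingency(obs, correction=False)
        rows.append((col, float(chi2), int(dof), float(p), np.nan, False))
    df = pd.DataFrame(rows, columns=["feature", "chi2", "dof", "p", "p_adj",
                                     "skipped"])
    tested = ~df["skipped"]
    if tested.any():
        df.loc[tested, "p_adj"] = multipletests(df.loc[tested, "p"],
                                                method=correction)[1]
    return HomogeneityReport(df, correction)
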