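"""Outcome evaluation: group-wise CV statistics and univariate ROC analysis.

Index values are compared between ablation-outcome groups (SR = sinus rhythm
maintained, AR = arrhythmia recurrence) with a protocol designed for small,
patient-clustered data sets:

* *group-wise* 3-fold cross-validation: each fold is an independent
  outcome-stratified random 80/20 split at the *patient* level, so segments
  from one patient never straddle train and test;
* per fold, a Lilliefors normality check on each group decides between
  one-way ANOVA (both normal) and Wilcoxon's rank-sum test; the mean p-value
  over folds is reported;
* a univariate logistic-regression classifier (unpenalized, standardized
  predictor) is fitted on each fold's training segments; ROC/AUC are computed
  on the held-out segments with *fixed orientation* (higher index value
  scores toward AR, the positive class) so that the AUC is a property of the
  index itself — an index lower in AR than SR yields AUC < 0.5 rather than
  being silently re-oriented per fold.  Sensitivity (AR detection rate) and
  specificity (SR detection rate) are reported at the Youden-J-optimal
  threshold of the ROC pooled over test folds.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from statsmodels.stats.diagnostic import lilliefors

from .errors import ConfigError, InsufficientDataError
from .geometry import VestGeometry
from .types import CvReport, ElectrodeSubset

__all__ = [
    "make_index_table",
    "validate_index_table",
    "groupwise_folds",
    "fold_significance",
    "univariate_roc",
    "subset_occurrence",
]

_TABLE_COLUMNS = ["patient_id", "segment_id", "subset_kind", "index_name", "value", "outcome"]


def make_index_table(rows: Sequence[dict]) -> pd.DataFrame:
    """Build and validate a labeled index table from row dicts."""
    df = pd.DataFrame(list(rows), columns=_TABLE_COLUMNS)
    validate_index_table(df)
    return df


def validate_index_table(table: pd.DataFrame) -> None:
    missing = set(_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ConfigError(f"index table is missing columns {sorted(missing)}")
    per_patient = table.groupby("patient_id")["outcome"].nunique()
    bad = per_patient[per_patient > 1]
    if len(bad):
        raise ConfigError(f"patients with multiple outcomes: {list(bad.index)}")
    if not set(table["outcome"]) <= {"SR", "AR"}:
        raise ConfigError("outcomes must be 'SR' or 'AR' for evaluation")


def _patient_outcomes(table: pd.DataFrame) -> pd.Series:
    return table.groupby("patient_id")["outcome"].first()


def groupwise_folds(
    table: pd.DataFrame,
    n_folds: int = 3,
    test_frac: float = 0.2,
    seed: int = 0,
    max_attempts: int = 100,
) -> list[tuple[list, list]]:
    """Independent outcome-stratified random patient-level splits.

    Each fold places ~``test_frac`` of the patients of *each* outcome class in
    the test side; a patient never appears on both sides of a fold.  Folds
    are independent draws (the 3-fold / 80-20 protocol is not a partition).
    """
    validate_index_table(table)
    outcomes = _patient_outcomes(table)
    if len(outcomes) < 5:
        raise InsufficientDataError("group-wise CV requires at least 5 patients")
    by_class = {c: sorted(outcomes.index[outcomes == c]) for c in ("SR", "AR")}
    if any(len(v) < 2 for v in by_class.values()):
        raise InsufficientDataError("need at least 2 patients per outcome class")
    rng = np.random.default_rng(seed)

    folds = []
    for _ in range(n_folds):
        for _attempt in range(max_attempts):
            test: list = []
            for c, patients in by_class.items():
                n_test = max(1, int(round(test_frac * len(patients))))
                if n_test >= len(patients):
                    n_test = len(patients) - 1
                test += list(rng.choice(patients, size=n_test, replace=False))
            train = [p for p in outcomes.index if p not in set(test)]
            train_classes = set(outcomes[train])
            test_classes = set(outcomes[test])
            if train_classes == {"SR", "AR"} and test_classes == {"SR", "AR"}:
                folds.append((sorted(train), sorted(test)))
                break
        else:
            raise InsufficientDataError(
                "could not draw a fold with both classes on both sides"
            )
    return folds


def _class_values(table: pd.DataFrame, index_name: str, patients: Sequence) -> dict:
    sub = table[(table["index_name"] == index_name) & table["patient_id"].isin(patients)]
    return {c: sub.loc[sub["outcome"] == c, "value"].to_numpy(float) for c in ("SR", "AR")}


def _one_fold_p(vals: dict, alpha: float = 0.05) -> tuple[float, str]:
    a, b = vals["SR"], vals["AR"]
    if len(a) < 3 or len(b) < 3:
        raise InsufficientDataError("need >= 3 values per class per fold")

    def _normal(v):
        if len(v) < 4 or np.ptp(v) == 0:
            return False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = lilliefors(v, dist="norm")
        return p > alpha

    if _normal(a) and _normal(b):
        _, p = stats.f_oneway(a, b)
        if np.isfinite(p):  # degenerates (e.g. identical groups) fall through
            return float(p), "anova"
    _, p = stats.ranksums(a, b)
    return float(p), "wilcoxon"


def fold_significance(
    table: pd.DataFrame,
    index_name: str,
    folds: Sequence[tuple[list, list]],
) -> tuple[float, str]:
    """Mean inter-group p-value over folds and the test that dominated.

    Per fold, the p-value is computed on the 80% (train) side: ANOVA when
    both groups pass the Lilliefors normality check, Wilcoxon rank-sum
    otherwise.
    """
    validate_index_table(table)
    ps, names = [], []
    for train, _test in folds:
        p, name = _one_fold_p(_class_values(table, index_name, train))
        ps.append(p)
        names.append(name)
    dominant = max(set(names), key=names.count)
    return float(np.mean(ps)), dominant


def univariate_roc(
    table: pd.DataFrame,
    index_name: str,
    folds: Sequence[tuple[list, list]],
) -> CvReport:
    """Per-fold AUC and pooled ROC for one index, AR as the positive class.

    A univariate logistic model (standardized predictor, no penalty) is
    fitted on each fold's training segments; AUC/ROC use the fixed index
    orientation (see module docstring).  Single-class test folds are skipped
    with a warning.
    """
    validate_index_table(table)
    fold_aucs, fold_ps = [], []
    pooled_y, pooled_s = [], []
    for train, test in folds:
        tr = table[(table["index_name"] == index_name) & table["patient_id"].isin(train)]
        te = table[(table["index_name"] == index_name) & table["patient_id"].isin(test)]
        y_tr = (tr["outcome"] == "AR").to_numpy(int)
        y_te = (te["outcome"] == "AR").to_numpy(int)
        if len(set(y_te)) < 2 or len(set(y_tr)) < 2:
            warnings.warn("degenerate single-class fold skipped", RuntimeWarning,
                          stacklevel=2)
            continue
        x_tr = tr["value"].to_numpy(float)
        x_te = te["value"].to_numpy(float)
        mu, sd = x_tr.mean(), x_tr.std()
        sd = sd if sd > 0 else 1.0
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
        clf.fit(((x_tr - mu) / sd)[:, None], y_tr)

        fold_aucs.append(float(roc_auc_score(y_te, x_te)))
        try:
            p, _ = _one_fold_p(
                {"SR": x_tr[y_tr == 0], "AR": x_tr[y_tr == 1]}
            )
        except InsufficientDataError:
            p = float("nan")
        fold_ps.append(p)
        pooled_y.append(y_te)
        pooled_s.append(x_te)

    if not fold_aucs:
        raise InsufficientDataError("every CV fold was degenerate; no AUC available")
    y = np.concatenate(pooled_y)
    s = np.concatenate(pooled_s)
    fpr, tpr, thresholds = roc_curve(y, s)
    j = tpr - fpr
    best = int(np.argmax(j))
    return CvReport(
        fold_aucs=[float(a) for a in fold_aucs],
        auc_mean=float(np.mean(fold_aucs)),
        auc_std=float(np.std(fold_aucs)),
        sensitivity=float(100 * tpr[best]),
        specificity=float(100 * (1 - fpr[best])),
        fold_pvalues=fold_ps,
        roc_points=[(float(a), float(b)) for a, b in zip(fpr, tpr)],
    )


def subset_occurrence(
    subsets: Sequence[ElectrodeSubset], geometry: VestGeometry
) -> np.ndarray:
    """Per-lead fraction of subsets containing the lead, in [0, 1]."""
    if not subsets:
        raise InsufficientDataError("subset_occurrence requires at least one subset")
    counts = np.zeros(geometry.n_leads)
    for sub in subsets:
        for i in sub.lead_indices:
            if i >= geometry.n_leads:
                raise ConfigError(f"subset lead {i} outside geometry with {geometry.n_leads} leads")
            counts[i] += 1
    return counts / len(subsets)


def plot_occurrence(occurrence: np.ndarray, geometry: VestGeometry, path=None):
    """Optional scatter rendering of per-lead occurrence on the unrolled vest."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    sc = ax.scatter(
        geometry.positions[:, 0], geometry.positions[:, 1],
        c=occurrence, cmap="viridis", vmin=0, vmax=1, s=40,
    )
    fig.colorbar(sc, ax=ax, label="occurrence fraction")
    ax.set_xlabel("x (unrolled torso)")
    ax.set_ylabel("y")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
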