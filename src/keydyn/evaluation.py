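"""Bootstrap ROC analysis, voting curves and group-level statistics.

Classification performance is summarised by ROC analysis of subject-level
probabilities. Confidence intervals come from resampling subjects (the unit
of classification) with replacement; resamples lacking a class are redrawn
and counted. The operating point reported alongside the AUC is the
equal-misclassification-cost optimum (the Youden point, maximising
sensitivity + specificity).

Group-level feature comparisons use the two-sided Mann-Whitney U test over
all sessions pooled per group (exact for small tie-free samples, normal
approximation with tie correction otherwise). Feature-clinical-score
relationships use Spearman rank correlation of per-subject feature means
against UPDRS Part III item scores (controls score zero on every item, which
skews the item variables and motivates the rank-based coefficient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import NoSessionsError
from .features import ALL_FEATURE_NAMES, FEATURE_NAMES, VARIABLES
from .pipeline import LOSOResult, subject_decision

__all__ = [
    "ROCResult",
    "bootstrap_roc",
    "sensitivity_specificity",
    "auc_vs_sessions",
    "group_feature_comparison",
    "selection_frequency",
    "updrs_correlations",
    "HEADLINE_FEATURES",
]

#: The consistently selected, most discriminant features of the study.
HEADLINE_FEATURES = [
    ("HT", "mu_mean"),
    ("HT", "sigma_mean"),
    ("NFT", "skew_mean"),
    ("NP", "mu_mean"),
]

_LABEL_CODE = {"control": 0, "PD": 1}


def _encode(labels) -> np.ndarray:
    arr = np.asarray(list(labels))
    if arr.dtype.kind in "UO":
        return np.array([_LABEL_CODE.get(v, v) for v in arr], dtype=int)
    return arr.astype(int)


@dataclass
class ROCResult:
    fpr: np.ndarray  # 1 - specificity, threshold-ordered
    tpr: np.ndarray  # sensitivity
    thresholds: np.ndarray
    auc: float  # point estimate on the full sample
    auc_mean: float  # bootstrap mean
    ci: tuple[float, float]  # percentile 95% interval
    n_bootstraps: int
    n_redrawn: int  # single-class resamples that were redrawn


def bootstrap_roc(
    scores, labels, n_boot: int = 1000, seed: int | None = None
) -> ROCResult:
    """ROC curve with a bootstrap AUC distribution over subjects.

    ``scores`` are subject-level probabilities, ``labels`` their true groups
    (strings or 0/1). Each bootstrap resamples subjects with replacement;
    class presence is enforced by redrawing (counted in ``n_redrawn``).
    """
    scores = np.asarray(scores, dtype=float)
    y = _encode(labels)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least two subjects per class")
    fpr, tpr, thr = roc_curve(y, scores)
    point = float(roc_auc_score(y, scores))
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    redrawn = 0
    n = len(y)
    for i in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if len(np.unique(y[idx])) == 2:
                break
            redrawn += 1
        aucs[i] = roc_auc_score(y[idx], scores[idx])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return ROCResult(fpr, tpr, thr, point, float(aucs.mean()), (float(lo), float(hi)), n_boot, redrawn)


def sensitivity_specificity(roc: ROCResult) -> tuple[float, float]:
    """Operating point at the equal-cost optimum (Youden index)."""
    j = int(np.argmax(roc.tpr - roc.fpr))
    return float(roc.tpr[j]), float(1.0 - roc.fpr[j])


def auc_vs_sessions(
    loso,
    max_sessions: int = 10,
    n_repeats: int = 20,
    seed: int | None = None,
    labels=None,
) -> pd.DataFrame:
    """Subject-level AUC as a function of the number of test sessions used.

    For s = 1..max_sessions and each repeat, every subject's vote is taken
    over a random subset of s of their fused session probabilities (all of
    them when fewer are available); the AUC across subjects is averaged over
    repeats. Both mean and median voting are reported.

    ``loso`` is an :class:`~keydyn.pipeline.LOSOResult`, or a mapping
    ``subject_id -> array of fused probabilities`` together with ``labels``
    (a mapping or sequence aligned with the mapping's order).
    """
    rng = np.random.default_rng(seed)
    if isinstance(loso, LOSOResult):
        labels = _encode(loso.subject_labels)
        pf = [loso.predictions[s].p_f for s in loso.predictions]
    else:
        if labels is None:
            raise ValueError("labels are required with a plain probability mapping")
        if hasattr(labels, "__getitem__") and not hasattr(labels, "dtype"):
            labels = [labels[s] for s in loso] if isinstance(labels, dict) else labels
        labels = _encode(labels)
        pf = [np.asarray(loso[s], dtype=float) for s in loso]
    rows = []
    for s in range(1, max_sessions + 1):
        accum = {"mean": [], "median": []}
        for _ in range(n_repeats):
            votes = {"mean": [], "median": []}
            for p in pf:
                take = p if len(p) <= s else rng.choice(p, size=s, replace=False)
                for voting in votes:
                    votes[voting].append(subject_decision(take, voting)[0])
            for voting in votes:
                accum[voting].append(roc_auc_score(labels, votes[voting]))
        for voting in accum:
            rows.append({"n_sessions": s, "voting": voting, "auc": float(np.mean(accum[voting]))})
    return pd.DataFrame(rows)


def group_feature_comparison(features: pd.DataFrame) -> pd.DataFrame:
    """Two-sided Mann-Whitney U test per (variable, feature) over sessions.

    ``features`` is the long-format table from ``extract_feature_table``.
    Constant features get a NaN p-value with a note.
    """
    rows = []
    for v in VARIABLES:
        sub = features[features["variable"] == v]
        for f in FEATURE_NAMES[v]:
            x = sub.loc[sub["label"] == "PD", f].dropna().to_numpy()
            y = sub.loc[sub["label"] == "control", f].dropna().to_numpy()
            if len(np.unique(np.concatenate([x, y]))) <= 1 or not len(x) or not len(y):
                rows.append({"variable": v, "feature": f, "U": np.nan, "p_value": np.nan,
                             "note": "degenerate (constant feature)"})
                continue
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
            rows.append({"variable": v, "feature": f, "U": float(res.statistic),
                         "p_value": float(res.pvalue), "note": ""})
    return pd.DataFrame(rows)


def selection_frequency(loso: LOSOResult) -> pd.DataFrame:
    """Percent of LOSO loops in which each (variable, feature) was selected."""
    n_loops = len(loso.selected_features)
    rows = []
    for v in VARIABLES:
        for f in FEATURE_NAMES[v]:
            count = sum(f in loop.get(v, []) for loop in loso.selected_features)
            rows.append({"variable": v, "feature": f,
                         "selected_pct": 100.0 * count / n_loops if n_loops else 0.0})
    return pd.DataFrame(rows)


def updrs_correlations(
    features: pd.DataFrame,
    updrs: pd.DataFrame,
    which: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Spearman correlation of per-subject feature means with UPDRS scores.

    ``updrs`` has one row per subject (indexed or with a ``subject_id``
    column) and one column per item score (plus a total, if desired); every
    numeric column is correlated. Features default to the study's four most
    discriminant ones. Zero-variance items give NaN with a note.
    """
    which = which or HEADLINE_FEATURES
    if "subject_id" in updrs.columns:
        updrs = updrs.set_index("subject_id")
    items = [c for c in updrs.columns if pd.api.types.is_numeric_dtype(updrs[c])]
    rows = []
    for v, f in which:
        sub = features[features["variable"] == v]
        per_subject = sub.groupby("subject_id")[f].mean()
        joined = pd.concat([per_subject.rename("feature"), updrs[items]], axis=1, join="inner")
        for item in items:
            x, s = joined["feature"].to_numpy(float), joined[item].to_numpy(float)
            if np.ptp(s) == 0 or np.ptp(x) == 0:
                rows.append({"variable": v, "feature": f, "item": item,
                             "r_s": np.nan, "p_value": np.nan, "note": "zero variance"})
                continue
            r, p = stats.spearmanr(x, s)
            rows.append({"variable": v, "feature": f, "item": item,
                         "r_s": float(r), "p_value": float(p), "note": ""})
    return pd.DataFrame(rows)
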