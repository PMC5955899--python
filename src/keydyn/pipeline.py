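"""Two-stage multi-model classification under leave-one-subject-out validation.

Each typing session is represented by up to three feature vectors (HT, NFT,
NP). In every leave-one-subject-out (LOSO) loop the remaining sessions are
randomly split 80/20 (label-stratified, the same session split for all three
variables). On the 80% part, each variable gets its own first-stage model:
recursive feature elimination down to at most five features, then a grid
search with an inner stratified 4-fold cross-validation (scored by AUC) over
a small hyperparameter grid, and a refit on the full training part. The
first-stage models score the 20% part, producing per-session probability
triplets v_P = [P_HT, P_NFT, P_NP] on which a logistic-regression fusion
model (the second stage) is trained. The left-out subject's sessions are then
pushed through both stages and the fused probabilities are combined by mean
(or median) voting into one subject-level probability.

Sessions missing a variable channel (e.g. an NFT sequence emptied by the
conditional filter) are skipped when training the fusion model; at prediction
time the missing probability is imputed with 0.5.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import Lasso, LogisticRegression, Ridge
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import NoSessionsError, SchemaError, StratificationError
from .features import FEATURE_NAMES, VARIABLES

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "FirstStageModel",
    "SubjectPrediction",
    "LOSOResult",
    "split_train_test",
    "select_features",
    "train_first_stage",
    "predict_first_stage",
    "train_second_stage",
    "subject_decision",
    "run_loso",
]

CLASSIFIERS = ("linear-svm", "logistic-regression", "random-forest", "k-nearest-neighbours")
SELECTORS = ("lasso", "ridge", "gini-impurity")

_LABEL_CODE = {"control": 0, "PD": 1}


def _default_grids() -> dict[str, dict[str, list]]:
    # Modest, fixed grids: enough to exercise the inner optimisation without
    # dominating runtime. The classifier step is named "clf".
    return {
        "linear-svm": {"clf__C": [0.1, 1.0, 10.0]},
        "logistic-regression": {"clf__C": [0.1, 1.0, 10.0]},
        "random-forest": {"clf__max_depth": [3, None]},
        "k-nearest-neighbours": {"clf__n_neighbors": [3, 5, 7]},
        "fusion": {"clf__C": [0.1, 1.0, 10.0]},
    }


@dataclass
class PipelineConfig:
    """First-stage model family, selector and validation settings.

    The default combination (ridge selection + random forest) is the
    best-performing configuration of the study design.
    """

    classifier: str = "random-forest"
    selector: str = "ridge"
    max_selected_features: int = 5
    inner_folds: int = 4
    train_fraction: float = 0.8
    voting: str = "mean"
    subject_grouped_split: bool = False  # group a training subject's sessions
    n_trees: int = 50
    grids: dict[str, dict[str, list]] = field(default_factory=_default_grids)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classifier not in CLASSIFIERS:
            raise ValueError(f"classifier must be one of {CLASSIFIERS}")
        if self.selector not in SELECTORS:
            raise ValueError(f"selector must be one of {SELECTORS}")
        if self.max_selected_features < 1:
            raise ValueError("max_selected_features must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.voting not in ("mean", "median"):
            raise ValueError("voting must be 'mean' or 'median'")


@dataclass
class FirstStageModel:
    variable: str
    features: list[str]
    estimator: Pipeline
    best_params: dict

    def __post_init__(self) -> None:
        if not self.features:
            raise ValueError("a first-stage model needs at least one feature")


@dataclass
class SubjectPrediction:
    subject_id: str
    label: str
    session_index: list[int]
    first_stage: pd.DataFrame  # columns P_HT, P_NFT, P_NP (NaN = channel missing)
    p_f: np.ndarray  # fused per-session probabilities
    probability: float  # voted subject-level probability
    predicted_label: str


@dataclass
class LOSOResult:
    predictions: dict[str, SubjectPrediction]
    selected_features: list[dict[str, list[str]]]  # per loop, per variable
    config: PipelineConfig

    @property
    def subject_scores(self) -> pd.Series:
        return pd.Series({s: p.probability for s, p in self.predictions.items()})

    @property
    def subject_labels(self) -> pd.Series:
        return pd.Series({s: p.label for s, p in self.predictions.items()})


# ---------------------------------------------------------------------------


def split_train_test(
    keys: Sequence, labels: Sequence[str], seed: int, train_fraction: float = 0.8
):
    """Label-stratified random session split, reproducible under ``seed``."""
    labels = list(labels)
    if len(set(labels)) < 2:
        raise StratificationError("both classes are required to stratify the split")
    try:
        train, test = train_test_split(
            list(keys),
            train_size=train_fraction,
            stratify=labels,
            random_state=int(seed) % (2**31),
        )
    except ValueError as exc:
        raise StratificationError(str(exc)) from exc
    return train, test


def _selector_estimator(selector: str, seed: int, n_trees: int = 50):
    if selector == "lasso":
        return Lasso(alpha=0.01, max_iter=10_000)
    if selector == "ridge":
        return Ridge(alpha=1.0)
    return RandomForestClassifier(n_estimators=n_trees, random_state=int(seed) % (2**31))


def select_features(
    X: pd.DataFrame,
    y: Sequence[int],
    selector: str = "ridge",
    k_max: int = 5,
    seed: int = 0,
    n_trees: int = 50,
) -> list[str]:
    """Recursive feature elimination down to at most ``k_max`` features.

    Features are ranked by the selector's importance scores (lasso/ridge
    coefficient magnitudes on the 0/1 labels, or gini-impurity importances)
    and the least important is dropped each round. Constant features are
    eliminated first (with a warning); if no more than ``k_max`` candidates
    remain, all are retained.
    """
    X = X.copy()
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant feature(s): {constant}", stacklevel=2)
        X = X.drop(columns=constant)
    if X.shape[1] <= k_max:
        return list(X.columns)
    Xs = StandardScaler().fit_transform(X.to_numpy(float))
    rfe = RFE(_selector_estimator(selector, seed, n_trees), n_features_to_select=k_max, step=1)
    rfe.fit(Xs, np.asarray(y))
    return [c for c, keep in zip(X.columns, rfe.support_) if keep]


def _make_classifier(name: str, seed: int, n_trees: int = 50) -> Pipeline:
    seed = int(seed) % (2**31)
    if name == "linear-svm":
        clf = SVC(kernel="linear", probability=True, random_state=seed)
    elif name == "logistic-regression":
        clf = LogisticRegression(max_iter=5_000, random_state=seed)
    elif name == "random-forest":
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    elif name == "k-nearest-neighbours":
        clf = KNeighborsClassifier()
    else:
        raise ValueError(f"unknown classifier {name!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _grid_fit(
    pipe: Pipeline,
    grid: dict[str, list],
    X: np.ndarray,
    y: np.ndarray,
    inner_folds: int,
    seed: int,
) -> tuple[Pipeline, dict]:
    """AUC-scored grid search with an inner stratified k-fold; degrades
    gracefully to a plain fit when the class counts cannot support CV."""
    counts = np.bincount(y, minlength=2)
    folds = min(inner_folds, int(counts[counts > 0].min()))
    if folds < 2 or len(np.unique(y)) < 2:
        logger.warning("inner CV infeasible (class counts %s); plain fit", counts.tolist())
        pipe.fit(X, y)
        return pipe, {}
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    search = GridSearchCV(pipe, grid, scoring="roc_auc", cv=cv, refit=True)
    search.fit(X, y)
    return search.best_estimator_, dict(search.best_params_)


def train_first_stage(
    X: pd.DataFrame,
    y: Sequence[int],
    config: PipelineConfig,
    variable: str,
    seed: int | None = None,
) -> FirstStageModel:
    """Select features, optimise hyperparameters by inner CV, refit.

    ``X`` holds the candidate feature columns of the 80% training part for
    one variable; ``y`` the 0/1 (control/PD) session labels.
    """
    seed = config.seed if seed is None else seed
    y = np.asarray(y)
    feats = select_features(
        X, y, config.selector, config.max_selected_features, seed, config.n_trees
    )
    pipe = _make_classifier(config.classifier, seed, config.n_trees)
    grid = config.grids.get(config.classifier, {})
    est, best = _grid_fit(pipe, grid, X[feats].to_numpy(float), y, config.inner_folds, seed)
    return FirstStageModel(variable, feats, est, best)


def predict_first_stage(model: FirstStageModel, X: pd.DataFrame) -> np.ndarray:
    """Per-session P(PD) from a fitted first-stage model."""
    missing = [f for f in model.features if f not in X.columns]
    if missing:
        raise SchemaError(f"feature table lacks columns {missing}")
    proba = model.estimator.predict_proba(X[model.features].to_numpy(float))
    classes = list(model.estimator.named_steps["clf"].classes_)
    return proba[:, classes.index(1)]


def train_second_stage(
    prob_vectors: pd.DataFrame,
    y: Sequence[int],
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> Pipeline:
    """Logistic-regression fusion of the first-stage probability triplets."""
    config = config or PipelineConfig()
    seed = config.seed if seed is None else seed
    y = np.asarray(y)
    if prob_vectors.drop_duplicates().shape[0] == 1:
        warnings.warn("all probability vectors identical; fusion fit is degenerate", stacklevel=2)
    pipe = Pipeline(
        [("scale", StandardScaler()),
         ("clf", LogisticRegression(max_iter=5_000, random_state=int(seed) % (2**31)))]
    )
    est, _ = _grid_fit(
        pipe, config.grids.get("fusion", {}), prob_vectors.to_numpy(float), y,
        config.inner_folds, seed,
    )
    return est


def subject_decision(p_f: Sequence[float], voting: str = "mean") -> tuple[float, str]:
    """Vote over a subject's fused session probabilities (threshold 0.5)."""
    p_f = np.asarray(list(p_f), dtype=float)
    if p_f.size == 0:
        raise NoSessionsError("no session probabilities to vote over")
    prob = float(np.mean(p_f) if voting == "mean" else np.median(p_f))
    return prob, ("PD" if prob >= 0.5 else "control")


# ---------------------------------------------------------------------------


def _variable_tables(features: pd.DataFrame) -> dict[str, pd.DataFrame]:
    tables = {}
    for v in VARIABLES:
        sub = features[features["variable"] == v]
        tables[v] = sub.set_index(["subject_id", "session_index"])[FEATURE_NAMES[v]]
    return tables


def run_loso(features: pd.DataFrame, config: PipelineConfig | None = None) -> LOSOResult:
    """Leave-one-subject-out evaluation of the two-stage pipeline.

    ``features`` is the long-format table from
    :func:`keydyn.features.extract_feature_table`. Each loop asserts that the
    left-out subject's sessions are absent from every training input. Returns
    per-subject predictions and the per-loop selected-feature records.
    """
    config = config or PipelineConfig()
    required = {"subject_id", "session_index", "variable", "label"}
    if not required.issubset(features.columns):
        raise SchemaError(f"feature table needs columns {sorted(required)}")

    subj_label = features.drop_duplicates("subject_id").set_index("subject_id")["label"]
    if min((subj_label == "PD").sum(), (subj_label == "control").sum()) < 2:
        raise StratificationError("need at least two subjects per class for LOSO")
    tables = _variable_tables(features)
    all_keys = sorted(
        features[["subject_id", "session_index"]].drop_duplicates().itertuples(index=False, name=None)
    )

    subjects = sorted(subj_label.index)
    loop_seeds = np.random.SeedSequence(config.seed).generate_state(3 * len(subjects)) % (2**31)
    predictions: dict[str, SubjectPrediction] = {}
    selected: list[dict[str, list[str]]] = []

    for loop, left_out in enumerate(subjects):
        pool = [k for k in all_keys if k[0] != left_out]
        pool_y = [subj_label[k[0]] for k in pool]
        if config.subject_grouped_split:
            train_subj, _ = split_train_test(
                sorted({k[0] for k in pool}),
                [subj_label[s] for s in sorted({k[0] for k in pool})],
                loop_seeds[3 * loop], config.train_fraction,
            )
            trn = [k for k in pool if k[0] in set(train_subj)]
            tst = [k for k in pool if k[0] not in set(train_subj)]
        else:
            trn, tst = split_train_test(pool, pool_y, loop_seeds[3 * loop], config.train_fraction)

        held = {k for k in all_keys if k[0] == left_out}
        assert not held & set(trn) and not held & set(tst), "left-out subject leaked into training"

        models: dict[str, FirstStageModel | None] = {}
        loop_selected: dict[str, list[str]] = {}
        for v in VARIABLES:
            idx = tables[v].index.intersection(trn)
            Xv = tables[v].loc[idx]
            yv = np.array([_LABEL_CODE[subj_label[s]] for s, _ in idx])
            if len(np.unique(yv)) < 2 or len(yv) < 4:
                logger.warning("loop %d: %s channel untrainable; skipped", loop, v)
                models[v], loop_selected[v] = None, []
                continue
            models[v] = train_first_stage(Xv, yv, config, v, seed=loop_seeds[3 * loop + 1])
            loop_selected[v] = models[v].features
        selected.append(loop_selected)

        def stage_one(keys: list[tuple]) -> pd.DataFrame:
            cols = {}
            for v in VARIABLES:
                p = np.full(len(keys), np.nan)
                if models[v] is not None:
                    idx = tables[v].index.intersection(keys)
                    if len(idx):
                        probs = predict_first_stage(models[v], tables[v].loc[idx])
                        pos = {k: i for i, k in enumerate(keys)}
                        for k, pr in zip(idx, probs):
                            p[pos[k]] = pr
                cols[f"P_{v}"] = p
            return pd.DataFrame(cols, index=pd.MultiIndex.from_tuples(keys))

        vp_tst = stage_one(tst)
        complete = vp_tst.dropna()
        y_fus = np.array([_LABEL_CODE[subj_label[s]] for s, _ in complete.index])
        if len(np.unique(y_fus)) < 2:
            logger.warning("loop %d: fusion training set single-class; widening to all channels", loop)
            complete = vp_tst.fillna(0.5)
            y_fus = np.array([_LABEL_CODE[subj_label[s]] for s, _ in complete.index])
        fusion = train_second_stage(complete, y_fus, config, seed=loop_seeds[3 * loop + 2])

        held_keys = sorted(held)
        vp_held = stage_one(held_keys).fillna(0.5)
        proba = fusion.predict_proba(vp_held.to_numpy(float))
        classes = list(fusion.named_steps["clf"].classes_)
        p_f = proba[:, classes.index(1)]
        prob, label = subject_decision(p_f, config.voting)
        predictions[left_out] = SubjectPrediction(
            subject_id=left_out,
            label=subj_label[left_out],
            session_index=[k[1] for k in held_keys],
            first_stage=vp_held,
            p_f=p_f,
            probability=prob,
            predicted_label=label,
        )
    return LOSOResult(predictions, selected, config)
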