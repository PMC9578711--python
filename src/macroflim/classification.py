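"""Phenotype classification from FLIM features with OOB-tuned random forests.

The feature table carries, per full field-of-view or per cell, the five
admitted predictors tau_avg, tau1, tau2, alpha2 and ORR (alpha1 is
dropped because it is deterministically 1 - alpha2). Hyper-parameters
(ntree, mtry) are tuned by grid search on the out-of-bag (OOB) error
with trees capped at 8 terminal nodes; the full field-of-view model is
scored on its OOB class-probability votes (no holdout exists at that
data size), while donor-level single-cell models use a stratified 75/25
train/test split. Variable importance is reported both as OOB
permutation importance (mean decrease accuracy) and accumulated
impurity reduction (mean decrease Gini).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split

from .errors import ClassCoverageError, DomainError, StratificationError

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "M1"
PREDICTORS = ("tau_avg_ns", "tau1_ns", "tau2_ns", "alpha2", "orr")
PREDICTORS_WITH_ALPHA1 = ("tau_avg_ns", "tau1_ns", "tau2_ns", "alpha1", "alpha2", "orr")
TAU_PREDICTORS = ("tau_avg_ns", "tau1_ns", "tau2_ns")
MAX_TERMINAL_NODES = 8
DEFAULT_NTREE_GRID = (50, 100, 150, 200, 250, 300, 400, 500)


@dataclass(frozen=True)
class RFSearchGrid:
    ntree_candidates: tuple = DEFAULT_NTREE_GRID
    mtry_candidates: tuple | None = None  # default 1..n_predictors
    max_terminal_nodes: int = MAX_TERMINAL_NODES

    def mtry_for(self, n_predictors: int):
        cands = (
            tuple(range(1, n_predictors + 1))
            if self.mtry_candidates is None
            else self.mtry_candidates
        )
        if any(m < 1 or m > n_predictors for m in cands):
            raise DomainError("mtry candidates must lie in 1..n_predictors")
        return cands


@dataclass(frozen=True)
class RFModelReport:
    """Tuned hyper-parameters and evaluation of one random-forests model."""

    ntree: int
    mtry: int
    oob_error: float  # percent
    roc_auc: float
    confusion: tuple  # (TP, FP, FN, TN), positive class = M1
    importance: pd.DataFrame  # index = predictor; mda, mda_se, mdg
    split: str
    seed: int
    n_rows: int

    def to_dict(self) -> dict:
        return dict(
            ntree=self.ntree,
            mtry=self.mtry,
            oob_error=self.oob_error,
            roc_auc=self.roc_auc,
            confusion=dict(zip(("TP", "FP", "FN", "TN"), self.confusion)),
            importance=self.importance.to_dict(orient="index"),
            split=self.split,
            seed=self.seed,
            n_rows=self.n_rows,
        )


def build_feature_table(
    rows: pd.DataFrame,
    treatment: str = "FCCP",
    drop_collinear: bool = True,
    require_good: bool = True,
):
    """Predictor matrix and label vector for one treatment condition.

    Rows failing the chi2 goodness gate are excluded; with
    drop_collinear the alpha1 column is omitted from the predictors.
    """
    df = rows
    if treatment is not None and "treatment" in df.columns:
        df = df[df["treatment"] == treatment]
    if require_good and "good" in df.columns:
        df = df[df["good"].astype(bool)]
    predictors = list(PREDICTORS if drop_collinear else PREDICTORS_WITH_ALPHA1)
    df = df.dropna(subset=predictors)
    if df["phenotype"].nunique() < 2:
        raise ClassCoverageError("need both phenotype classes in the table")
    X = df[predictors].to_numpy(dtype=float)
    y = df["phenotype"].to_numpy()
    meta = df.drop(columns=predictors)
    return X, y, predictors, meta.reset_index(drop=True)


def zscore_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Column-wise z-scores (population SD); zero-variance columns map to
    zeros with a warning."""
    if len(table) < 2:
        raise DomainError("z-scoring needs at least two rows")
    out = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            warnings.warn(f"column {col!r} has zero variance; z-scores set to 0")
            out[col] = np.zeros_like(x)
        else:
            out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=table.index)


def umap_embed(X, metric: str = "cosine", seed: int = 0, n_neighbors: int = 15):
    """2-D UMAP embedding with cosine distance; deterministic given seed."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] <= n_neighbors:
        n_neighbors = max(2, X.shape[0] - 1)
    if X.shape[0] < 4:
        raise DomainError("too few rows to embed")
    import umap  # deferred: numba compilation is slow at import time

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2, metric=metric, random_state=seed, n_neighbors=n_neighbors
        )
        return reducer.fit_transform(X)


def roc_auc(scores, labels, positive=POSITIVE_CLASS) -> float:
    """Probability that a random positive outranks a random negative
    (ties count one half); scores are positive-class probabilities."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = labels == positive
    if pos.all() or (~pos).all():
        raise DomainError("both classes must be present")
    return float(roc_auc_score(pos.astype(int), scores))


def confusion_counts(scores, labels, threshold: float = 0.5, positive=POSITIVE_CLASS):
    """(TP, FP, FN, TN) at the given positive-probability threshold;
    scores >= threshold are called positive."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pred_pos = scores >= threshold
    actual_pos = labels == positive
    tp = int(np.sum(pred_pos & actual_pos))
    fp = int(np.sum(pred_pos & ~actual_pos))
    fn = int(np.sum(~pred_pos & actual_pos))
    tn = int(np.sum(~pred_pos & ~actual_pos))
    return tp, fp, fn, tn


def split_train_test(
    rows: pd.DataFrame, train_fraction: float = 0.75, stratify: str = "phenotype",
    seed: int = 0,
):
    """Disjoint, exhaustive, stratified train/test split of a row table."""
    counts = rows[stratify].value_counts()
    if (counts < 2).any():
        raise StratificationError("every class needs at least two rows")
    train, test = train_test_split(
        rows,
        train_size=train_fraction,
        stratify=rows[stratify],
        random_state=seed,
        shuffle=True,
    )
    return train, test


def _fit_forest(X, y, ntree, mtry, max_nodes, seed):
    clf = RandomForestClassifier(
        n_estimators=ntree,
        max_features=mtry,
        max_leaf_nodes=max_nodes,
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rows never OOB at tiny ntree
        clf.fit(X, y)
    return clf


def _oob_positive_probs(clf, positive=POSITIVE_CLASS):
    pos_idx = list(clf.classes_).index(positive)
    probs = clf.oob_decision_function_[:, pos_idx]
    return np.nan_to_num(probs, nan=0.5)


def train_rf_oob_grid(
    X, y, grid: RFSearchGrid | None = None, seed: int = 0,
    positive=POSITIVE_CLASS, predictor_names=None,
):
    """Grid-search (ntree, mtry) by OOB error with 8-terminal-node trees.

    Ties break toward smaller ntree then smaller mtry. Returns the
    selected fitted forest and an RFModelReport evaluated on the OOB
    class-probability votes.
    """
    grid = grid or RFSearchGrid()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ClassCoverageError("need two classes to train")
    best = None
    for ntree in sorted(grid.ntree_candidates):
        for mtry in sorted(grid.mtry_for(X.shape[1])):
            clf = _fit_forest(X, y, ntree, mtry, grid.max_terminal_nodes, seed)
            oob_err = 1.0 - clf.oob_score_
            if best is None or oob_err < best[0] - 1e-12:
                best = (oob_err, ntree, mtry, clf)
    oob_err, ntree, mtry, clf = best
    probs = _oob_positive_probs(clf, positive)
    report = RFModelReport(
        ntree=ntree,
        mtry=mtry,
        oob_error=100.0 * oob_err,
        roc_auc=roc_auc(probs, y, positive),
        confusion=confusion_counts(probs, y, positive=positive),
        importance=variable_importance(
            clf, X, y, predictor_names=predictor_names, seed=seed
        ),
        split="oob",
        seed=seed,
        n_rows=len(y),
    )
    return clf, report


def variable_importance(model, X, y, predictor_names=None, seed: int = 0):
    """Per-predictor mean decrease accuracy (OOB permutation) and mean
    decrease Gini (impurity) of a fitted forest.

    For each tree, accuracy on its out-of-bag rows is compared before and
    after permuting one predictor at a time; the per-tree decreases are
    averaged (their SE is reported alongside). Gini importance comes from
    the forest's accumulated impurity reduction.
    """
    if not hasattr(model, "oob_decision_function_"):
        raise DomainError("model was trained without OOB bookkeeping")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    rng = np.random.default_rng(seed)
    try:
        import inspect

        from sklearn.ensemble._forest import (
            _generate_unsampled_indices,
            _get_n_samples_bootstrap,
        )

        if "sample_weight" in inspect.signature(_get_n_samples_bootstrap).parameters:
            n_boot = _get_n_samples_bootstrap(n, model.max_samples, None)

            def oob_idx(tree):
                return _generate_unsampled_indices(tree.random_state, n, n_boot, None)

        else:  # pragma: no cover - older sklearn
            n_boot = _get_n_samples_bootstrap(n, model.max_samples)

            def oob_idx(tree):
                return _generate_unsampled_indices(tree.random_state, n, n_boot)

    except ImportError:  # pragma: no cover - fallback mirrors sklearn bagging
        def oob_idx(tree):
            sampled = np.random.RandomState(tree.random_state).randint(0, n, n)
            mask = np.ones(n, dtype=bool)
            mask[sampled] = False
            return np.flatnonzero(mask)

    p = X.shape[1]

    def tree_acc(tree, Xo, yo):
        # forest trees predict class indices into model.classes_
        pred = model.classes_.take(tree.predict(Xo).astype(int))
        return float(np.mean(pred == yo))

    decreases = np.zeros((len(model.estimators_), p))
    for ti, tree in enumerate(model.estimators_):
        idx = oob_idx(tree)
        if idx.size == 0:
            continue
        Xo, yo = X[idx], y[idx]
        base = tree_acc(tree, Xo, yo)
        for j in range(p):
            Xp = Xo.copy()
            Xp[:, j] = Xp[rng.permutation(idx.size), j]
            decreases[ti, j] = base - tree_acc(tree, Xp, yo)
    mda = decreases.mean(axis=0)
    mda_se = decreases.std(axis=0, ddof=1) / np.sqrt(max(len(model.estimators_), 2))
    names = (
        list(predictor_names)
        if predictor_names is not None
        else (
            list(model.feature_names_in_)
            if hasattr(model, "feature_names_in_")
            else [f"x{j}" for j in range(p)]
        )
    )
    return pd.DataFrame(
        {"mda": mda, "mda_se": mda_se, "mdg": model.feature_importances_},
        index=names,
    )


def evaluate_holdout(clf, X_test, y_test, positive=POSITIVE_CLASS):
    """ROC-AUC and confusion counts of a fitted forest on held-out rows."""
    pos_idx = list(clf.classes_).index(positive)
    probs = clf.predict_proba(np.asarray(X_test, dtype=float))[:, pos_idx]
    return (
        roc_auc(probs, y_test, positive),
        confusion_counts(probs, y_test, positive=positive),
    )


def run_donor_models(
    rows: pd.DataFrame,
    grid: RFSearchGrid | None = None,
    seed: int = 0,
    train_fraction: float = 0.75,
    treatment: str = "FCCP",
) -> dict:
    """Per-donor single-cell classifiers: 75/25 stratified split, OOB grid
    search on the training part, ROC-AUC and confusion on the held-out
    part. Donors missing a class are skipped with a logged reason."""
    grid = grid or RFSearchGrid()
    reports = {}
    for k, donor in enumerate(sorted(rows["donor"].unique())):
        sub = rows[rows["donor"] == donor]
        try:
            X, y, predictors, meta = build_feature_table(sub, treatment=treatment)
        except ClassCoverageError as exc:
            logger.warning("donor %s skipped: %s", donor, exc)
            continue
        df = pd.DataFrame(X, columns=predictors)
        df["phenotype"] = y
        try:
            train, test = split_train_test(
                df, train_fraction=train_fraction, seed=seed + k
            )
        except StratificationError as exc:
            logger.warning("donor %s skipped: %s", donor, exc)
            continue
        clf, rep = train_rf_oob_grid(
            train[list(predictors)].to_numpy(),
            train["phenotype"].to_numpy(),
            grid,
            seed=seed + k,
            predictor_names=predictors,
        )
        auc, conf = evaluate_holdout(
            clf, test[list(predictors)].to_numpy(), test["phenotype"].to_numpy()
        )
        reports[donor] = RFModelReport(
            ntree=rep.ntree,
            mtry=rep.mtry,
            oob_error=rep.oob_error,
            roc_auc=auc,
            confusion=conf,
            importance=rep.importance,
            split=f"{train_fraction:.0%}/{1 - train_fraction:.0%} stratified",
            seed=seed + k,
            n_rows=len(df),
        )
    return reports
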