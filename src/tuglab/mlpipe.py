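"""Diagnostic-modelling protocol: ranked forward feature selection and
repeated stratified cross-validation with majority voting.

Per training fold: random-forest impurity ranking, elbow cutoff (point
farthest from the chord through the first and last importance), then
forward AIC minimization over cumulative top-ranked candidates.  The final
classifier is a random forest fit on a training set undersampled to the
minority class size.  Five stratified 5-fold replicates yield five
predictions per participant; the final class is their majority vote.

The AIC of a forest is defined here from out-of-bag class probabilities
(clipped away from 0 and 1) with the feature count as the parameter count;
this convention is a documented, seeded choice.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "MLConfig",
    "FeatureMatrix",
    "ModelEvaluation",
    "rank_features",
    "find_elbow",
    "select_by_aic",
    "evaluate",
    "duration_only_model",
    "compare_trial_models",
    "build_feature_matrix",
]

log = logging.getLogger(__name__)

FEATURE_SETS = ("trial1", "trial2", "both", "duration_only")
_PROB_CLIP = 1e-6


@dataclass(frozen=True)
class MLConfig:
    n_trees: int = 10_000  # final-model forest size; tests/reports override to 500
    rank_trees: int = 200
    aic_trees: int = 200
    #: cap on the elbow candidate list, bounding the AIC sweep cost
    max_candidates: int = 15
    n_folds: int = 5
    n_replicates: int = 5
    min_class_size: int = 5


DEFAULT_CONFIG = MLConfig()


@dataclass
class FeatureMatrix:
    """Participants x measures with binary labels (1 = patient subgroup, 0 = control)."""

    X: pd.DataFrame
    y: np.ndarray
    task: str = ""
    group: str = ""
    feature_set: str = ""

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y lengths differ")
        if self.X.isna().any().any():
            raise ValueError("feature matrix must be imputed before modelling")
        if self.X.columns.duplicated().any():
            raise ValueError("duplicate feature names")


@dataclass
class ModelEvaluation:
    task: str
    group: str
    feature_set: str
    accuracy: float  # percent of correct majority votes
    votes: pd.DataFrame  # one row per participant: replicate predictions, final, label
    folds: list[dict] = field(default_factory=list)  # per replicate x fold diagnostics


def rank_features(
    X: pd.DataFrame, y: np.ndarray, seed: int = 0, n_trees: int | None = None
) -> list[tuple[str, float]]:
    """Impurity-based random-forest importances, descending."""
    if X.shape[1] < 1:
        raise ValueError("need at least one feature")
    if len(np.unique(y)) < 2:
        raise ValueError("labels are degenerate (single class)")
    rf = RandomForestClassifier(
        n_estimators=n_trees or DEFAULT_CONFIG.rank_trees, random_state=seed, n_jobs=1
    )
    rf.fit(X.to_numpy(), y)
    order = np.argsort(rf.feature_importances_)[::-1]
    return [(X.columns[i], float(rf.feature_importances_[i])) for i in order]


def find_elbow(importances: np.ndarray | list[float]) -> int:
    """1-based cutoff index: the point farthest from the chord through the
    first and last points of the descending importance curve.

    Ties (including perfectly collinear input) resolve to the smallest index.
    """
    v = np.asarray(importances, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 points to locate an elbow")
    x = np.arange(1, len(v) + 1, dtype=float)
    x0, y0 = x[0], v[0]
    x1, y1 = x[-1], v[-1]
    # perpendicular distance from each point to the chord
    norm = np.hypot(x1 - x0, y1 - y0)
    if norm == 0:
        return 1
    dist = np.abs((y1 - y0) * x - (x1 - x0) * v + x1 * y0 - y1 * x0) / norm
    best = int(np.argmax(np.isclose(dist, dist.max())))  # smallest index among ties
    if np.allclose(dist, 0.0):
        return 1
    return best + 1


def _forest_aic(X: np.ndarray, y: np.ndarray, n_features: int, seed: int, n_trees: int) -> float:
    rf = RandomForestClassifier(
        n_estimators=n_trees, oob_score=True, bootstrap=True, random_state=seed, n_jobs=1
    )
    rf.fit(X, y)
    probs = rf.oob_decision_function_
    # rows never out of bag get an uninformative probability
    probs = np.where(np.isnan(probs), 0.5, probs)
    class_index = np.searchsorted(rf.classes_, y)
    p_true = np.clip(probs[np.arange(len(y)), class_index], _PROB_CLIP, 1.0 - _PROB_CLIP)
    return 2.0 * n_features - 2.0 * float(np.log(p_true).sum())


def select_by_aic(
    X: pd.DataFrame,
    y: np.ndarray,
    candidates: list[str],
    seed: int = 0,
    n_trees: int | None = None,
) -> list[str]:
    """Forward selection over cumulative top-ranked candidates, minimizing AIC."""
    if not candidates:
        raise ValueError("candidates must be non-empty")
    n_trees = n_trees or DEFAULT_CONFIG.aic_trees
    aics = []
    for j in range(1, len(candidates) + 1):
        aics.append(_forest_aic(X[candidates[:j]].to_numpy(), y, j, seed, n_trees))
    best_j = int(np.argmin(aics)) + 1  # ties resolve to the smaller subset
    return list(candidates[:best_j])


def _select_features(X: pd.DataFrame, y: np.ndarray, seed: int, config: MLConfig) -> list[str]:
    ranked = rank_features(X, y, seed=seed, n_trees=config.rank_trees)
    names = [f for f, _ in ranked]
    if len(ranked) < 3:
        candidates = names
    else:
        cutoff = find_elbow([imp for _, imp in ranked])
        candidates = names[:cutoff]
    candidates = candidates[: config.max_candidates]
    return select_by_aic(X, y, candidates, seed=seed, n_trees=config.aic_trees)


def _undersample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a balanced subsample: majority reduced to minority size."""
    classes, counts = np.unique(y, return_counts=True)
    n_min = counts.min()
    keep: list[np.ndarray] = []
    for cls in classes:
        idx = np.nonzero(y == cls)[0]
        if len(idx) > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(np.sort(idx))
    return np.sort(np.concatenate(keep))


def _run_protocol(
    fm: FeatureMatrix,
    seed: int,
    config: MLConfig,
    classifier: str,
    do_selection: bool,
) -> ModelEvaluation:
    X, y = fm.X, fm.y
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < config.min_class_size:
        raise ValueError(
            f"minimum class size is {config.min_class_size}, got {counts.min()}"
        )
    n = len(y)
    preds = np.full((n, config.n_replicates), -1, dtype=int)
    folds: list[dict] = []
    for rep in range(config.n_replicates):
        rep_seed = seed + rep
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True, random_state=rep_seed)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            fold_seed = int(np.random.SeedSequence([seed, rep, fold]).generate_state(1)[0] % 2**31)
            if do_selection:
                selected = _select_features(X.iloc[tr], y[tr], fold_seed, config)
            else:
                selected = list(X.columns)
            rng = np.random.default_rng(fold_seed)
            bal = tr[_undersample(y[tr], rng)]
            Xtr = X.iloc[bal][selected].to_numpy()
            ytr = y[bal]
            if classifier == "forest":
                model = RandomForestClassifier(
                    n_estimators=config.n_trees, random_state=fold_seed, n_jobs=1
                )
            elif classifier == "logistic":
                model = LogisticRegression(max_iter=1000, random_state=fold_seed)
            else:
                raise ValueError(f"unknown classifier {classifier!r}")
            model.fit(Xtr, ytr)
            preds[te, rep] = model.predict(X.iloc[te][selected].to_numpy())
            folds.append(
                {
                    "replicate": rep,
                    "fold": fold,
                    "train_idx": tr,
                    "test_idx": te,
                    "selected": selected,
                    "train_class_counts": dict(zip(*np.unique(ytr, return_counts=True))),
                }
            )
    assert (preds >= 0).all(), "every participant must receive one prediction per replicate"
    vote_sum = preds.sum(axis=1)
    # with an odd replicate count ties cannot occur; otherwise they fall to class 1
    final = (vote_sum * 2 >= config.n_replicates).astype(int)
    accuracy = float(np.mean(final == y) * 100.0)
    votes = pd.DataFrame(
        preds, index=X.index, columns=[f"replicate_{r + 1}" for r in range(config.n_replicates)]
    )
    votes["final"] = final
    votes["label"] = y
    return ModelEvaluation(fm.task, fm.group, fm.feature_set, accuracy, votes, folds)


def evaluate(fm: FeatureMatrix, seed: int = 0, config: MLConfig | None = None) -> ModelEvaluation:
    """Full protocol: per-fold selection, undersampled forest, majority vote."""
    return _run_protocol(fm, seed, config or DEFAULT_CONFIG, "forest", do_selection=True)


def duration_only_model(
    mean_durations: pd.Series | np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    config: MLConfig | None = None,
) -> ModelEvaluation:
    """Logistic regression on the single mean-duration predictor, same CV protocol."""
    if isinstance(mean_durations, pd.Series):
        X = mean_durations.to_frame("mean_total_duration")
    else:
        X = pd.DataFrame({"mean_total_duration": np.asarray(mean_durations, dtype=float)})
    fm = FeatureMatrix(X, np.asarray(labels), feature_set="duration_only")
    return _run_protocol(fm, seed, config or DEFAULT_CONFIG, "logistic", do_selection=False)


def compare_trial_models(accuracies: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell accuracy differences vs the trial-1 model, plus mean differences.

    ``accuracies`` is long format with columns ``task, group, feature_set,
    accuracy``.  Every (task, group) cell must have a ``trial1`` entry and
    every feature set must cover the same cells.
    """
    required = {"task", "group", "feature_set", "accuracy"}
    if not required.issubset(accuracies.columns):
        raise ValueError(f"accuracies must have columns {sorted(required)}")
    wide = accuracies.pivot_table(
        index=["task", "group"], columns="feature_set", values="accuracy"
    )
    if "trial1" not in wide.columns:
        raise ValueError("no trial1 accuracies provided")
    missing = [
        f"{task}/{group}/{fset}"
        for (task, group), row in wide.iterrows()
        for fset in wide.columns
        if pd.isna(row[fset])
    ]
    if missing:
        raise ValueError(f"unmatched cells: {missing}")
    cells = wide.copy()
    others = [c for c in wide.columns if c != "trial1"]
    for fset in others:
        cells[f"{fset}_diff"] = wide[fset] - wide["trial1"]
    summary = pd.DataFrame(
        {
            "feature_set": others,
            "mean_diff": [float(cells[f"{fset}_diff"].mean()) for fset in others],
            "n_cells": [int(cells[f"{fset}_diff"].notna().sum()) for fset in others],
        }
    )
    return cells.reset_index(), summary


def load_reference_accuracies() -> pd.DataFrame:
    """Bundled published accuracy table (percent) for the trial-set comparison.

    Long format with columns ``task, group, feature_set, accuracy``; nine
    task x severity cells, four feature sets each.  These are fixed reference
    inputs for :func:`compare_trial_models`, not outputs of this package.
    """
    ref = importlib.resources.files("tuglab").joinpath("data/reference_accuracies.csv")
    with ref.open("rb") as fh:
        return pd.read_csv(fh)


def build_feature_matrix(
    measures: pd.DataFrame,
    manifest: pd.DataFrame,
    task: str,
    group: str,
    feature_set: str,
    control_group: str = "control",
) -> FeatureMatrix:
    """Assemble a participants x features matrix for one task and group pair.

    ``feature_set``: ``trial1`` / ``trial2`` use one trial's measures;
    ``both`` concatenates trial-1, trial-2 and per-feature mean columns;
    ``duration_only`` keeps the mean total duration.  Missing values are
    imputed with the column median; all-missing columns are dropped.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"feature_set must be one of {FEATURE_SETS}")
    groups = manifest.drop_duplicates("participant_id").set_index("participant_id")["group"]
    sub = measures[(measures["task"] == task)]
    wide = sub.pivot_table(
        index="participant_id", columns=["measure", "trial"], values="value"
    )
    t1 = wide.xs(1, axis=1, level="trial")
    t2 = wide.xs(2, axis=1, level="trial")
    common = t1.index.intersection(t2.index)
    t1, t2 = t1.loc[common], t2.loc[common]
    if feature_set == "trial1":
        X = t1.copy()
    elif feature_set == "trial2":
        X = t2.copy()
    elif feature_set == "both":
        X = pd.concat(
            [t1.add_suffix("_t1"), t2.add_suffix("_t2"), ((t1 + t2) / 2).add_suffix("_mean")],
            axis=1,
        )
    else:  # duration_only
        X = ((t1[["total_duration"]] + t2[["total_duration"]]) / 2).rename(
            columns={"total_duration": "mean_total_duration"}
        )
    part_groups = groups.reindex(X.index)
    keep = part_groups.isin([group, control_group])
    X = X.loc[keep]
    y = (part_groups.loc[keep] == group).astype(int).to_numpy()
    X = X.dropna(axis=1, how="all")
    X = X.fillna(X.median())
    return FeatureMatrix(X, y, task=task, group=group, feature_set=feature_set)
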