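"""Random-forest filtering of merged CNV calls.

Each merged call is summarized as a numeric feature vector capturing what
the ensemble knows about it: its type, its (log) size, how many and which
callers concur, and the median paired-end / split-read support.  A random
forest trained on calls with known labels (true/false positive, e.g. from
long-read validation) assigns each call a posterior probability of being a
true positive; calls below a user cutoff are dropped.

Hyperparameters (tree count, maximum depth, features per split) are chosen
by grid search with stratified k-fold cross-validation on the training set,
optimizing plain validation accuracy; ties prefer the smallest forest, then
the shallowest trees.  Held-out evaluation splits by chromosome, never by
random rows, so that linked calls cannot leak between train and test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score

from .model import UNKNOWN, MergedCall, ValidationError

#: Column order of the feature matrix.
FEATURE_COLUMNS = [
    "is_del", "is_ins", "is_tdup", "is_ddup",
    "size_log10", "size_known",
    "n_tools", "tool_delly", "tool_gridss", "tool_lumpy", "tool_manta",
    "pe_support", "sr_support", "total_support",
]

_TOOL_FLAGS = [("tool_delly", "DELLY"), ("tool_gridss", "GRIDSS"),
               ("tool_lumpy", "LUMPY"), ("tool_manta", "MANTA")]


def extract_features(call) -> dict:
    """Deterministic feature vector for one call; see FEATURE_COLUMNS.

    Unknown sizes (unresolved insertions) get ``size_log10 = 0`` with the
    explicit ``size_known = 0`` missingness flag rather than a fake size.
    """
    size = call.size
    known = size is not UNKNOWN
    row = {
        "is_del": int(call.cnv_type.value == "DEL"),
        "is_ins": int(call.cnv_type.value == "INS"),
        "is_tdup": int(call.cnv_type.value == "TDUP"),
        "is_ddup": int(call.cnv_type.value == "DDUP"),
        "size_log10": math.log10(max(size, 1)) if known else 0.0,
        "size_known": int(known),
        "pe_support": float(call.pe_support),
        "sr_support": float(call.sr_support),
        "total_support": float(call.pe_support) + float(call.sr_support),
    }
    for col, tool in _TOOL_FLAGS:
        row[col] = int(tool in call.source_tools)
    row["n_tools"] = len(call.source_tools)
    return row


def build_feature_matrix(calls) -> pd.DataFrame:
    rows = [extract_features(c) for c in calls]
    df = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    if len(df) and not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValidationError("non-finite value in feature matrix")
    return df


@dataclass
class LabeledCallSet:
    """Merged calls with binary true-positive labels."""

    calls: list
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.calls) != len(self.labels):
            raise ValidationError("calls and labels differ in length")
        if len(self.labels) and not set(np.unique(self.labels)) <= {0, 1}:
            raise ValidationError("labels must be 0/1")

    def __len__(self):
        return len(self.calls)

    @property
    def chromosomes(self) -> list[str]:
        return [c.region.chrom for c in self.calls]

    def subset(self, mask) -> "LabeledCallSet":
        mask = np.asarray(mask, dtype=bool)
        return LabeledCallSet(
            [c for c, keep in zip(self.calls, mask) if keep], self.labels[mask]
        )


def split_by_chromosome(
    labeled: LabeledCallSet, holdout
) -> tuple[LabeledCallSet, LabeledCallSet]:
    """Disjoint, exhaustive split: calls on holdout chromosomes become the
    test set, everything else the training set."""
    holdout = set(holdout)
    present = set(labeled.chromosomes)
    missing = holdout - present
    if missing:
        raise ValidationError(f"holdout chromosomes absent from data: {sorted(missing)}")
    mask = np.array([c in holdout for c in labeled.chromosomes], dtype=bool)
    if not mask.any():
        raise ValidationError("empty test partition: no calls on holdout chromosomes")
    if mask.all():
        raise ValidationError("empty train partition: all calls on holdout chromosomes")
    return labeled.subset(~mask), labeled.subset(mask)


def default_grid() -> list[dict]:
    return [
        {"n_estimators": n, "max_depth": d, "max_features": f}
        for n in (100, 250, 500)
        for d in (None, 5, 10)
        for f in ("sqrt", None)
    ]


@dataclass
class RFModel:
    estimator: RandomForestClassifier
    feature_names: list[str]
    hyperparams: dict
    cv_report: pd.DataFrame
    seed: int
    folds: int


def _grid_sort_key(point):
    depth = point.get("max_depth")
    return (
        point.get("n_estimators", 0),
        math.inf if depth is None else depth,
        str(point.get("max_features")),
    )


def train_rf(
    train: LabeledCallSet,
    grid: list[dict] | None = None,
    folds: int = 10,
    seed: int = 0,
) -> RFModel:
    """Grid search with stratified k-fold CV, then refit on the full set.

    The best grid point by mean validation accuracy wins; exact ties go to
    the smallest forest, then the shallowest trees (unbounded depth sorts
    last).  The seed fixes both fold assignment and tree randomness, so the
    same data and seed give identical hyperparameters and scores.
    """
    grid = sorted(grid if grid is not None else default_grid(), key=_grid_sort_key)
    X = build_feature_matrix(train.calls).to_numpy(dtype=float)
    y = train.labels
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValidationError("training labels contain a single class")
    if counts.min() < folds:
        raise ValidationError(
            f"need >= {folds} examples per class for {folds}-fold CV, "
            f"got {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)

    rows = []
    best = None  # (mean accuracy, grid index)
    for idx, point in enumerate(grid):
        clf = RandomForestClassifier(random_state=seed, n_jobs=1, **point)
        scores = cross_val_score(clf, X, y, cv=skf, scoring="accuracy")
        mean = float(scores.mean())
        rows.append({**point, "mean_cv_accuracy": mean,
                     "fold_accuracies": list(np.round(scores, 6))})
        if best is None or mean > best[0]:
            best = (mean, idx)
    chosen = grid[best[1]]
    final = RandomForestClassifier(random_state=seed, n_jobs=1, **chosen)
    final.fit(X, y)
    report = pd.DataFrame(rows)
    report["chosen"] = [i == best[1] for i in range(len(grid))]
    return RFModel(
        estimator=final,
        feature_names=list(FEATURE_COLUMNS),
        hyperparams=dict(chosen),
        cv_report=report,
        seed=seed,
        folds=folds,
    )


def score_calls(model: RFModel, calls) -> list:
    """Annotate calls with the forest's posterior true-positive probability."""
    X = build_feature_matrix(calls)
    missing = [c for c in model.feature_names if c not in X.columns]
    if missing or list(X.columns) != list(model.feature_names):
        raise ValidationError(
            f"feature schema mismatch; missing or misordered columns: {missing}"
        )
    if not len(calls):
        return []
    proba = model.estimator.predict_proba(X.to_numpy(dtype=float))
    pos_col = int(np.where(model.estimator.classes_ == 1)[0][0])
    return [c.with_score(float(p)) for c, p in zip(calls, proba[:, pos_col])]


def filter_by_score(calls, cutoff: float) -> list:
    """Keep exactly the calls with score >= cutoff, order preserved."""
    if not (0.0 <= cutoff <= 1.0):
        raise ValidationError(f"cutoff {cutoff} outside [0, 1]")
    for c in calls:
        if c.score is None:
            raise ValidationError("call without score; run score_calls first")
    return [c for c in calls if c.score >= cutoff]


def save_model(model: RFModel, path):
    joblib.dump(
        {
            "format_version": 1,
            "estimator": model.estimator,
            "feature_names": model.feature_names,
            "hyperparams": model.hyperparams,
            "cv_report": model.cv_report,
            "seed": model.seed,
            "folds": model.folds,
        },
        path,
    )


def load_model(path) -> RFModel:
    blob = joblib.load(path)
    return RFModel(
        estimator=blob["estimator"],
        feature_names=blob["feature_names"],
        hyperparams=blob["hyperparams"],
        cv_report=blob["cv_report"],
        seed=blob["seed"],
        folds=blob["folds"],
    )
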