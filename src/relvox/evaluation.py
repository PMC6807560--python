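"""Dataset splitting, classification metrics, trial repetition and SVM baselines.

The experimental protocol: subjects are split once into a holdout set (15%)
used only for final evaluation and a remainder split again into training
(85%) and validation (15%); the split is stratified by class and operates on
subject ids, so a subject with multiple scans lands in exactly one set.  CNN
experiments are repeated over several trials (default 10) on the same split
with per-trial seeds derived from a master seed, and reported metrics are
across-trial means; the trial with the best validation balanced accuracy is
flagged for heatmap analysis.

Metrics: sensitivity and specificity at score threshold 0.5 (class 1 =
patient = positive), balanced accuracy as their mean, and AUC computed from
the rank (Mann-Whitney) statistic with tie adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "SplitSpec",
    "Metrics",
    "TrialResults",
    "split_dataset",
    "evaluate",
    "select_threshold",
    "mean_metrics",
    "run_trials",
    "trial_seed",
    "svm_baseline",
    "DEFAULT_SVM_GRID",
]


@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/validation/holdout subject-id sets."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    holdout_ids: tuple[str, ...]
    seed: int = 0

    def __post_init__(self):
        sets = [set(self.train_ids), set(self.val_ids), set(self.holdout_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise ValueError("split sets must be pairwise disjoint")

    def all_ids(self) -> set[str]:
        return set(self.train_ids) | set(self.val_ids) | set(self.holdout_ids)


def split_dataset(
    subjects,
    labels=None,
    fractions: tuple[float, float] = (0.85, 0.15),
    val_fraction: float = 0.15,
    seed: int = 0,
) -> SplitSpec:
    """Stratified subject-level split into train / validation / holdout.

    ``subjects`` is either a CohortManifest, a DataFrame with subject_id and
    label columns (possibly with repeated subject ids for multiple scans), or
    a list of ids with ``labels`` given separately.  ``fractions`` controls
    the (development, holdout) proportions; within the development portion a
    further ``val_fraction`` goes to validation.
    """
    if hasattr(subjects, "records"):  # CohortManifest
        ids = subjects.subject_ids()
        labels = subjects.labels()
    elif isinstance(subjects, pd.DataFrame):
        ids = subjects["subject_id"].astype(str).tolist()
        labels = subjects["label"].to_numpy()
    else:
        ids = list(subjects)
        if labels is None:
            raise ValueError("labels required when passing raw subject ids")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")

    # subject-level de-duplication (multi-scan subjects keep one label)
    subj_label: dict[str, int] = {}
    for sid, lab in zip(ids, labels):
        sid = str(sid)
        if sid in subj_label and subj_label[sid] != int(lab):
            raise ValueError(f"subject {sid} appears with conflicting labels")
        subj_label[sid] = int(lab)

    rng = np.random.default_rng(seed)
    train, val, holdout = [], [], []
    for cls in sorted(set(subj_label.values())):
        cls_ids = sorted(s for s, l in subj_label.items() if l == cls)
        if len(cls_ids) < 3:
            raise ValueError(f"class {cls} has fewer than 3 subjects; cannot stratify")
        cls_ids = [cls_ids[i] for i in rng.permutation(len(cls_ids))]
        n_hold = max(1, round(fractions[1] * len(cls_ids)))
        n_val = max(1, round(val_fraction * (len(cls_ids) - n_hold)))
        holdout += cls_ids[:n_hold]
        val += cls_ids[n_hold : n_hold + n_val]
        train += cls_ids[n_hold + n_val :]
    return SplitSpec(tuple(sorted(train)), tuple(sorted(val)), tuple(sorted(holdout)), seed)


@dataclass
class Metrics:
    """Classification metrics on one evaluation set (fractions in [0,1])."""

    sensitivity: float
    specificity: float
    balanced_accuracy: float
    auc: float
    n: int = 0

    def __post_init__(self):
        for name in ("sensitivity", "specificity", "balanced_accuracy", "auc"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        expected = (self.sensitivity + self.specificity) / 2.0
        if abs(self.balanced_accuracy - expected) > 1e-9:
            raise ValueError("balanced_accuracy must equal mean(sensitivity, specificity)")

    def as_percent(self) -> dict[str, float]:
        return {
            "sensitivity": 100 * self.sensitivity,
            "specificity": 100 * self.specificity,
            "balanced_accuracy": 100 * self.balanced_accuracy,
            "auc": 100 * self.auc,
        }


def evaluate(scores, labels, threshold: float = 0.5) -> Metrics:
    """Compute sensitivity/specificity/balanced accuracy/AUC for scores.

    Class 1 is the positive (patient) class; a score above ``threshold``
    predicts it.  AUC uses the tie-adjusted rank statistic.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if len(set(labels.tolist())) < 2:
        raise ValueError("both classes must be present to evaluate")
    pred = scores > threshold
    pos = labels == 1
    sens = float(np.mean(pred[pos]))
    spec = float(np.mean(~pred[~pos]))
    auc = float(roc_auc_score(labels, scores))
    return Metrics(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        auc=auc,
        n=len(labels),
    )


def select_threshold(scores, labels) -> float:
    """Operating point maximizing balanced accuracy on a calibration set.

    Scans the midpoints between consecutive sorted scores (plus 0.5 as a
    candidate) and returns the threshold with the highest balanced accuracy;
    ties resolve to the candidate closest to 0.5.  Intended to be applied to
    *validation* scores, never to the evaluation set itself.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    order = np.sort(np.unique(scores))
    candidates = [0.5] + [(a + b) / 2 for a, b in zip(order, order[1:])]
    best = (0.0, np.inf, 0.5)
    for t in candidates:
        pred = scores > t
        pos = labels == 1
        sens = float(np.mean(pred[pos]))
        spec = float(np.mean(~pred[~pos]))
        bal = (sens + spec) / 2
        key = (bal, -abs(t - 0.5))
        if key > (best[0], -best[1]):
            best = (bal, abs(t - 0.5), t)
    return float(best[2])


def mean_metrics(per_trial: list[Metrics]) -> Metrics:
    sens = float(np.mean([m.sensitivity for m in per_trial]))
    spec = float(np.mean([m.specificity for m in per_trial]))
    return Metrics(
        sensitivity=sens,
        specificity=spec,
        balanced_accuracy=(sens + spec) / 2.0,
        auc=float(np.mean([m.auc for m in per_trial])),
        n=per_trial[0].n,
    )


def trial_seed(master_seed: int, trial: int) -> int:
    """Documented counter scheme: seed_t = master*1000 + trial (mod 2^31)."""
    return int((master_seed * 1000 + trial) % (2**31))


@dataclass
class TrialResults:
    per_trial: list[Metrics]
    mean: Metrics
    best_trial: int  # index of the trial with the best validation balanced accuracy
    networks: list = field(default_factory=list)
    histories: list = field(default_factory=list)
    log: pd.DataFrame | None = None


def run_trials(
    trial_fn,
    n_trials: int = 10,
    master_seed: int = 0,
    keep_networks: bool = True,
) -> TrialResults:
    """Repeat one experiment ``n_trials`` times on the same split.

    ``trial_fn(seed)`` runs a full training with the given seed and returns
    ``(holdout_metrics, validation_balanced_accuracy, network, history)``.
    Reported metrics are the across-trial means; the trial with the best
    validation balanced accuracy is flagged (used for heatmap analysis).
    Any trial exception aborts the experiment.
    """
    per_trial, val_accs, nets, hists, rows = [], [], [], [], []
    for t in range(n_trials):
        seed = trial_seed(master_seed, t)
        metrics, val_acc, net, history = trial_fn(seed)
        per_trial.append(metrics)
        val_accs.append(val_acc)
        nets.append(net if keep_networks else None)
        hists.append(history)
        rows.append(dict(trial=t, seed=seed, val_balanced_accuracy=val_acc, **metrics.as_percent()))
    best = int(np.argmax(val_accs))
    return TrialResults(
        per_trial=per_trial,
        mean=mean_metrics(per_trial),
        best_trial=best,
        networks=nets,
        histories=hists,
        log=pd.DataFrame(rows),
    )


DEFAULT_SVM_GRID = {
    "kernel": ["linear", "rbf"],
    "C": [0.001, 0.1, 1, 10],
    "gamma": [0.001, 0.1, 1, 10],
}


def svm_baseline(
    features: np.ndarray,
    labels: np.ndarray,
    subject_ids: list[str],
    split: SplitSpec,
    grid: dict | None = None,
    pca: bool = False,
    pca_variance: float = 0.95,
) -> tuple[Metrics, dict]:
    """SVM baseline with nested grid search.

    ``features`` is (n_subjects, n_features): either the scalar lesion load
    (one column) or a flattened volume per subject.  Hyperparameters (kernel
    in {linear, rbf}, C and gamma over the configured grid) are chosen by
    grid search nested within a 5-fold cross-validation on the training+
    validation subjects; the returned metrics are computed on the holdout.
    With ``pca=True`` a PCA keeping ``pca_variance`` explained variance is
    prepended (for volume features).

    Returns ``(holdout_metrics, info)`` with the chosen hyperparameters and
    the number of grid points explored.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim == 1:
        features = features[:, None]
    if not np.all(np.isfinite(features)):
        raise ValueError("features must be finite")
    grid = grid or DEFAULT_SVM_GRID
    idx = {s: i for i, s in enumerate(subject_ids)}
    dev_ids = list(split.train_ids) + list(split.val_ids)
    dev = [idx[s] for s in dev_ids]
    hold = [idx[s] for s in split.holdout_ids]
    y = np.asarray(labels, dtype=int)
    if len(dev) < 10:
        raise ValueError(
            f"only {len(dev)} development subjects; the nested 5-fold grid "
            "search needs at least 10 (5 per class)"
        )

    steps = [("scale", StandardScaler())]
    if pca:
        steps.append(("pca", PCA(n_components=pca_variance, svd_solver="full")))
    steps.append(("svm", SVC()))
    pipe = Pipeline(steps)
    param_grid = {f"svm__{k}": v for k, v in grid.items()}
    search = GridSearchCV(pipe, param_grid, cv=5, scoring="balanced_accuracy", n_jobs=1)
    search.fit(features[dev], y[dev])

    decision = search.decision_function(features[hold])
    metrics = evaluate(decision, y[hold], threshold=0.0)
    n_grid = int(np.prod([len(v) for v in grid.values()]))
    info = dict(
        best_params={k.removeprefix("svm__"): v for k, v in search.best_params_.items()},
        n_grid_points=n_grid,
        n_candidates=len(search.cv_results_["params"]),
        cv_best_score=float(search.best_score_),
    )
    return metrics, info
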