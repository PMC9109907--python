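"""Model selection and risk assessment: splits, undersampling, metrics, grids.

The evaluation protocol holds out a test fraction (default 20%) for a single
final risk assessment, and selects models by k-fold cross-validation (default
k = 3) inside the remaining development set.  Fold assignment is stratified
in one of two ways:

* ``simple``  -- preserve the outcome-label distribution;
* ``complex`` -- preserve the joint distribution of label, molecule size
  (quartile bins of atom counts over the development set) and dose, merging
  strata too small to split.

The majority *no change* class is undersampled afresh at each training
epoch so that every epoch sees balanced classes while, across epochs, the
whole majority class is eventually visited.  Ranking quality is measured by
macro-AUROC: the unweighted mean of one-vs-rest AUROCs over the classes.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .screenlab import ScreenDataset

__all__ = [
    "SplitPlan", "EvalReport", "make_split", "undersample_epoch",
    "macro_auroc", "confusion", "grid_search",
]

logger = logging.getLogger(__name__)

STRATEGIES = ("simple", "complex")


@dataclass(frozen=True)
class SplitPlan:
    """Holdout + k-fold assignment of dataset records.

    After :func:`make_split`, ``assignments`` maps each record index to
    ``"test"`` or a 1-based development fold number.
    """

    holdout_fraction: float = 0.20
    k: int = 3
    strategy: str = "simple"
    seed: int = 0
    assignments: dict[int, object] | None = None

    def __post_init__(self):
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")

    @property
    def resolved(self) -> bool:
        return self.assignments is not None

    def test_indices(self) -> np.ndarray:
        return np.array(sorted(i for i, a in self.assignments.items() if a == "test"))

    def dev_indices(self) -> np.ndarray:
        return np.array(sorted(i for i, a in self.assignments.items() if a != "test"))

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.array(sorted(i for i, a in self.assignments.items() if a == fold))


def _atom_counts(dataset: ScreenDataset) -> np.ndarray:
    from .molgraph import parse_smiles

    cache: dict[str, int] = {}
    out = np.zeros(len(dataset), dtype=int)
    for i, r in enumerate(dataset.records):
        if r.smiles not in cache:
            cache[r.smiles] = parse_smiles(r.smiles).n_atoms
        out[i] = cache[r.smiles]
    return out


def _size_bins(counts: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Quartile bins of atom counts computed over the records in ``idx``."""
    edges = np.percentile(counts[idx], [25, 50, 75])
    return np.searchsorted(edges, counts, side="right")


def _strat_keys(
    labels: list[str], counts: np.ndarray, doses: np.ndarray,
    idx: np.ndarray, strategy: str, min_size: int,
) -> list[str]:
    """Stratification key per record in ``idx``; tiny strata merge coarser.

    Merge ladder for the complex strategy: (y, size-bin, dose) ->
    (y, dose) -> (y).  A stratum smaller than ``min_size`` cannot be
    distributed across that many parts, so it falls back with a warning.
    """
    if strategy == "simple":
        return [labels[i] for i in idx]
    bins = _size_bins(counts, idx)
    levels = [
        [f"{labels[i]}|{bins[i]}|{doses[i]}" for i in idx],
        [f"{labels[i]}|{doses[i]}" for i in idx],
        [labels[i] for i in idx],
    ]
    keys = levels[0]
    for coarser in levels[1:]:
        from collections import Counter

        sizes = Counter(keys)
        small = {k for k, v in sizes.items() if v < min_size}
        if not small:
            break
        warnings.warn(
            f"{len(small)} strata smaller than {min_size} merged into coarser bins",
            stacklevel=3,
        )
        keys = [c if k in small else k for k, c in zip(keys, coarser)]
    return keys


def make_split(dataset: ScreenDataset, plan: SplitPlan) -> SplitPlan:
    """Resolve a split plan into explicit record assignments.

    Deterministic under the plan's seed; the test set is disjoint from every
    development fold and the folds partition the development set.
    """
    from sklearn.model_selection import StratifiedKFold, train_test_split

    n = len(dataset)
    labels = dataset.labels()
    for c in dataset.classes:
        if labels.count(c) < plan.k + 1:
            raise ValueError(f"class {c!r} has fewer than k+1={plan.k + 1} records")
    doses = np.array([r.dose for r in dataset.records])
    counts = _atom_counts(dataset) if plan.strategy == "complex" else np.zeros(n, dtype=int)

    all_idx = np.arange(n)
    holdout_keys = _strat_keys(labels, counts, doses, all_idx, plan.strategy, 2)
    dev_idx, test_idx = train_test_split(
        all_idx,
        test_size=plan.holdout_fraction,
        random_state=plan.seed,
        stratify=holdout_keys,
    )

    fold_keys = _strat_keys(labels, counts, doses, dev_idx, plan.strategy, plan.k)
    skf = StratifiedKFold(n_splits=plan.k, shuffle=True, random_state=plan.seed)
    assignments: dict[int, object] = {int(i): "test" for i in test_idx}
    for fold, (_, val_pos) in enumerate(skf.split(dev_idx, fold_keys), start=1):
        for pos in val_pos:
            assignments[int(dev_idx[pos])] = fold
    return replace(plan, assignments=assignments)


def undersample_epoch(
    train_indices, labels, seed: int, epoch: int, mode: str = "min"
) -> np.ndarray:
    """Per-epoch majority undersampling; a fresh draw every epoch.

    ``labels`` is aligned with ``train_indices``.  With the default
    ``mode="min"`` every class is sampled down to the smallest class size,
    so each epoch subset is exactly balanced; ``mode="mean"`` downsamples
    only the majority class, to the mean of the other class sizes, keeping
    minority classes whole.  Epoch draws come from one seed stream, so
    successive epochs rotate through different majority subsets.
    """
    train_indices = np.asarray(train_indices)
    labels = np.asarray(labels)
    if len(train_indices) != len(labels):
        raise ValueError("indices and labels must be aligned")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to undersample")
    if (counts == counts[0]).all() and mode == "min":
        return train_indices.copy()
    rng = np.random.default_rng([abs(int(seed)), int(epoch), 0x5EED])
    if mode == "min":
        targets = {c: int(counts.min()) for c in classes}
    elif mode == "mean":
        majority = classes[np.argmax(counts)]
        others = counts[classes != majority]
        targets = {c: len(labels[labels == c]) for c in classes}
        targets[majority] = int(round(others.mean()))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep: list[np.ndarray] = []
    for c in classes:
        members = train_indices[labels == c]
        t = targets[c]
        if len(members) > t:
            members = rng.choice(members, size=t, replace=False)
        keep.append(np.sort(members))
    return np.concatenate(keep)


def macro_auroc(scores: np.ndarray, labels, classes: tuple[str, ...]) -> float:
    """Unweighted mean of one-vs-rest AUROCs (midrank tie handling).

    ``scores`` columns follow ``classes``.  Errors if a class has no
    positive instances in ``labels`` (its AUROC is undefined).
    """
    from sklearn.metrics import roc_auc_score

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if scores.shape != (len(labels), len(classes)):
        raise ValueError("scores must be (n_instances, n_classes)")
    aurocs = []
    for j, c in enumerate(classes):
        pos = labels == c
        if not pos.any() or pos.all():
            raise ValueError(f"class {c!r} has no {'positive' if not pos.any() else 'negative'} instances")
        aurocs.append(roc_auc_score(pos, scores[:, j]))
    return float(np.mean(aurocs))


def confusion(
    predictions, labels, classes: tuple[str, ...], normalize: bool = True
) -> np.ndarray:
    """Confusion matrix; row i, column j = (fraction of) true-i predicted-j."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if len(predictions) != len(labels):
        raise ValueError("predictions and labels must be the same length")
    c = len(classes)
    index = {cls: i for i, cls in enumerate(classes)}
    mat = np.zeros((c, c), dtype=float)
    for t, p in zip(labels, predictions):
        mat[index[t], index[p]] += 1
    if normalize:
        row_sums = mat.sum(axis=1, keepdims=True)
        mat = np.divide(mat, row_sums, out=np.zeros_like(mat), where=row_sums > 0)
    return mat


@dataclass
class EvalReport:
    """Outcome of a grid search: CV scores, the chosen point, test metrics."""

    strategy: str
    chosen_params: dict
    train_auroc_mean: float
    train_auroc_std: float
    valid_auroc_mean: float
    valid_auroc_std: float
    test_auroc: float
    test_confusion: np.ndarray
    cv_results: list[dict] = field(default_factory=list)
    failures: list[dict] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "chosen_params": self.chosen_params,
            "train_auroc_mean": self.train_auroc_mean,
            "train_auroc_std": self.train_auroc_std,
            "valid_auroc_mean": self.valid_auroc_mean,
            "valid_auroc_std": self.valid_auroc_std,
            "test_auroc": self.test_auroc,
            "test_confusion": self.test_confusion.tolist(),
            "cv_results": self.cv_results,
            "failures": self.failures,
        }


def _subset(dataset: ScreenDataset, idx: np.ndarray) -> ScreenDataset:
    return ScreenDataset(
        records=tuple(dataset.records[i] for i in idx),
        doses=dataset.doses,
        classes=dataset.classes,
    )


def _eval_on(model, dataset: ScreenDataset, idx: np.ndarray) -> tuple[float, np.ndarray, list]:
    from .models import predict_batch

    records = [dataset.records[i] for i in idx]
    scores = predict_batch(
        model, [r.smiles for r in records], np.array([r.dose for r in records])
    )
    labels = [r.label for r in records]
    return macro_auroc(scores, labels, dataset.classes), scores, labels


def grid_search(
    spec_template, grid: dict, dataset: ScreenDataset, plan: SplitPlan
) -> EvalReport:
    """Grid search by k-fold CV on the development set, then one test pass.

    Every grid point is trained on each fold; the point with the best mean
    validation macro-AUROC wins, is refitted on the full development set,
    and is evaluated exactly once on the held-out test records.  Failing
    grid points are recorded and skipped.
    """
    from .models import fit

    if not plan.resolved:
        plan = make_split(dataset, plan)
    keys = sorted(grid) if grid else []
    points = (
        [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]
        if keys
        else [{}]
    )
    if not points:
        raise ValueError("empty hyper-parameter grid")

    test_idx = plan.test_indices()
    folds = [plan.fold_indices(f) for f in range(1, plan.k + 1)]
    dev_idx = plan.dev_indices()

    cv_results, failures = [], []
    for point in points:
        train_scores, valid_scores = [], []
        try:
            for f in range(plan.k):
                val_idx = folds[f]
                tr_idx = np.concatenate([folds[g] for g in range(plan.k) if g != f])
                model = fit(spec_template, _subset(dataset, tr_idx), config=point)
                train_scores.append(_eval_on(model, dataset, tr_idx)[0])
                valid_scores.append(_eval_on(model, dataset, val_idx)[0])
        except Exception as err:  # noqa: BLE001 - a failed point is reported, not fatal
            failures.append({"params": point, "error": f"{type(err).__name__}: {err}"})
            logger.warning("grid point %s failed: %s", point, err)
            continue
        cv_results.append(
            {
                "params": point,
                "fold_train_auroc": train_scores,
                "fold_valid_auroc": valid_scores,
                "mean_valid_auroc": float(np.mean(valid_scores)),
            }
        )
    if not cv_results:
        raise RuntimeError(f"every grid point failed: {failures}")

    best = max(cv_results, key=lambda r: r["mean_valid_auroc"])
    final = fit(spec_template, _subset(dataset, dev_idx), config=best["params"])
    test_auroc, test_scores, test_labels = _eval_on(final, dataset, test_idx)
    pred_labels = [dataset.classes[j] for j in np.argmax(test_scores, axis=1)]
    report = EvalReport(
        strategy=plan.strategy,
        chosen_params=best["params"],
        train_auroc_mean=float(np.mean(best["fold_train_auroc"])),
        train_auroc_std=float(np.std(best["fold_train_auroc"])),
        valid_auroc_mean=float(np.mean(best["fold_valid_auroc"])),
        valid_auroc_std=float(np.std(best["fold_valid_auroc"])),
        test_auroc=test_auroc,
        test_confusion=confusion(pred_labels, test_labels, dataset.classes),
        cv_results=cv_results,
        failures=failures,
    )
    return report
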