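"""Splits, stratification, undersampling, macro-AUROC, confusion, grid search."""

import itertools
from collections import Counter

import numpy as np
import pytest

import phagoscreen as ps
from phagoscreen.evaluate import (
    SplitPlan,
    confusion,
    grid_search,
    macro_auroc,
    make_split,
    undersample_epoch,
)
from phagoscreen.screenlab import ScreenDataset, ScreenRecord

CLASSES3 = ("increase", "no_change", "decrease")


def make_dataset(n_per_class, smiles_pool=("CCO", "CCN", "CCC", "CCCC", "CCCCC", "c1ccccc1")):
    """Balanced-ish labeled dataset without going through beta thresholds."""
    records = []
    doses = (1.39, 22.22)
    i = 0
    for label, n in zip(CLASSES3, n_per_class):
        for _ in range(n):
            records.append(
                ScreenRecord(
                    compound_id=f"c{i}",
                    smiles=smiles_pool[i % len(smiles_pool)],
                    dose=doses[i % 2],
                    label=label,
                )
            )
            i += 1
    return ScreenDataset(records=tuple(records), doses=doses)


# -- splits -----------------------------------------------------------------

def test_simple_split_balanced_fixture():
    ds = make_dataset((30, 30, 30))
    plan = make_split(ds, SplitPlan(holdout_fraction=0.2, k=3, seed=0))
    test = plan.test_indices()
    assert len(test) == 18
    labels = np.array(ds.labels())
    for f in range(1, 4):
        fold = plan.fold_indices(f)
        assert len(fold) == 24
        counts = Counter(labels[fold])
        assert all(c == 8 for c in counts.values())


def test_split_partition_and_disjointness():
    ds = make_dataset((25, 140, 35))
    plan = make_split(ds, SplitPlan(seed=3))
    test = set(plan.test_indices().tolist())
    folds = [set(plan.fold_indices(f).tolist()) for f in range(1, 4)]
    assert not test & set().union(*folds)
    for a, b in itertools.combinations(folds, 2):
        assert not a & b
    assert test | set().union(*folds) == set(range(len(ds)))


def test_split_deterministic_under_seed():
    ds = make_dataset((20, 80, 20))
    p1 = make_split(ds, SplitPlan(seed=11))
    p2 = make_split(ds, SplitPlan(seed=11))
    assert p1.assignments == p2.assignments
    p3 = make_split(ds, SplitPlan(seed=12))
    assert p1.assignments != p3.assignments


def test_simple_stratification_within_one_record():
    ds = make_dataset((23, 121, 31))
    plan = make_split(ds, SplitPlan(seed=5))
    labels = np.array(ds.labels())
    dev = plan.dev_indices()
    dev_counts = Counter(labels[dev])
    for f in range(1, 4):
        fold = plan.fold_indices(f)
        for c in CLASSES3:
            expected = dev_counts[c] * len(fold) / len(dev)
            got = int((labels[fold] == c).sum())
            assert abs(got - expected) <= 1, (c, f)


def test_complex_stratification_joint_histogram():
    # 2 molecule sizes x 3 classes x 2 doses, large enough strata
    small, large = "CCO", "CCCCCCCCCCCC"
    records = []
    i = 0
    for label in CLASSES3:
        for smiles in (small, large):
            for dose in (1.39, 22.22):
                for _ in range(12):
                    records.append(ScreenRecord(f"c{i}", smiles, dose, label=label))
                    i += 1
    ds = ScreenDataset(records=tuple(records), doses=(1.39, 22.22))
    plan = make_split(ds, SplitPlan(strategy="complex", seed=1))
    keys = [(r.label, r.smiles, r.dose) for r in ds.records]
    dev = plan.dev_indices()
    dev_key_counts = Counter(keys[i] for i in dev)
    for f in range(1, 4):
        fold = plan.fold_indices(f)
        fold_counts = Counter(keys[i] for i in fold)
        for key, total in dev_key_counts.items():
            expected = total * len(fold) / len(dev)
            assert abs(fold_counts.get(key, 0) - expected) <= 1, (key, f)


def test_tiny_class_rejected():
    ds = make_dataset((2, 50, 30))
    with pytest.raises(ValueError, match="increase"):
        make_split(ds, SplitPlan(k=3))


# -- undersampling ----------------------------------------------------------

def test_undersample_exactly_balanced():
    rng = np.random.default_rng(0)
    labels = np.array(["no_change"] * 810 + ["increase"] * 100 + ["decrease"] * 90)
    idx = np.arange(len(labels))
    for epoch in range(5):
        sub = undersample_epoch(idx, labels, seed=1, epoch=epoch)
        counts = Counter(labels[sub])
        assert set(counts.values()) == {90}
        assert len(sub) == 270


def test_undersample_mean_mode_keeps_minorities_whole():
    labels = np.array(["no_change"] * 810 + ["increase"] * 100 + ["decrease"] * 90)
    sub = undersample_epoch(np.arange(len(labels)), labels, 1, 0, mode="mean")
    counts = Counter(labels[sub])
    assert counts["increase"] == 100 and counts["decrease"] == 90
    assert counts["no_change"] == 95  # mean of the minority sizes


def test_undersample_balanced_input_is_identity():
    labels = np.array(["a"] * 10 + ["b"] * 10)
    idx = np.arange(20)
    assert np.array_equal(undersample_epoch(idx, labels, 0, 0), idx)


def test_undersample_epochs_differ_and_cover_majority():
    labels = np.array(["no_change"] * 800 + ["increase"] * 100 + ["decrease"] * 100)
    idx = np.arange(1000)
    nc = set(range(800))
    seen = set()
    draws = []
    for epoch in range(200):
        sub = undersample_epoch(idx, labels, seed=9, epoch=epoch)
        nc_drawn = frozenset(int(i) for i in sub if i < 800)
        draws.append(nc_drawn)
        seen |= nc_drawn
    assert len(set(draws)) > 190          # epochs draw different subsets
    assert len(seen) / len(nc) > 0.99     # union covers the majority class


# -- macro-AUROC ------------------------------------------------------------

def auroc_pair_counting(pos_scores, neg_scores):
    """Brute-force concordant-pair count with ties counted 1/2."""
    wins = sum(
        1.0 if p > q else (0.5 if p == q else 0.0)
        for p in pos_scores
        for q in neg_scores
    )
    return wins / (len(pos_scores) * len(neg_scores))


def macro_auroc_oracle(scores, labels, classes):
    per_class = []
    labels = np.asarray(labels)
    for j, c in enumerate(classes):
        pos = scores[labels == c, j]
        neg = scores[labels != c, j]
        per_class.append(auroc_pair_counting(pos, neg))
    return float(np.mean(per_class))


def test_macro_auroc_perfect_separation():
    scores = np.eye(3)[[0, 1, 2, 0, 1, 2]]
    labels = np.array(CLASSES3 * 2)
    assert macro_auroc(scores, labels, CLASSES3) == 1.0


def test_macro_auroc_chance_level():
    rng = np.random.default_rng(0)
    n = 10_000
    labels = np.array(CLASSES3)[rng.integers(0, 3, n)]
    scores = rng.random((n, 3))
    assert macro_auroc(scores, labels, CLASSES3) == pytest.approx(0.5, abs=0.02)


def test_macro_auroc_matches_pair_counting_oracle():
    rng = np.random.default_rng(4)
    for _ in range(25):
        n = rng.integers(6, 13)
        labels = np.array(CLASSES3)[rng.integers(0, 3, n)]
        if len(set(labels)) < 3:
            continue
        scores = np.round(rng.random((n, 3)), 1)  # coarse grid forces ties
        assert macro_auroc(scores, labels, CLASSES3) == pytest.approx(
            macro_auroc_oracle(scores, labels, CLASSES3), abs=1e-12
        )


def test_macro_auroc_monotone_transform_invariant():
    rng = np.random.default_rng(5)
    labels = np.array(CLASSES3)[rng.integers(0, 3, 60)]
    scores = rng.random((60, 3))
    ref = macro_auroc(scores, labels, CLASSES3)
    transformed = np.exp(5 * scores)  # strictly monotone, per class
    assert macro_auroc(transformed, labels, CLASSES3) == pytest.approx(ref)


def test_macro_auroc_missing_class_named():
    scores = np.random.default_rng(0).random((5, 3))
    labels = np.array(["no_change"] * 5)
    with pytest.raises(ValueError, match="increase"):
        macro_auroc(scores, labels, CLASSES3)


# -- confusion --------------------------------------------------------------

def test_confusion_perfect_predictions_identity():
    labels = list(CLASSES3) * 3
    mat = confusion(labels, labels, CLASSES3)
    assert np.array_equal(mat, np.eye(3))


def test_confusion_all_one_class_column():
    labels = list(CLASSES3) * 2
    preds = ["no_change"] * 6
    mat = confusion(preds, labels, CLASSES3)
    assert np.array_equal(mat[:, 1], np.ones(3))
    assert mat[:, [0, 2]].sum() == 0


def test_confusion_hand_tally():
    labels = ["increase"] * 3 + ["no_change"] * 3 + ["decrease"] * 3
    preds = ["increase", "no_change", "no_change",
             "no_change", "no_change", "decrease",
             "decrease", "decrease", "increase"]
    mat = confusion(preds, labels, CLASSES3, normalize=False)
    assert np.array_equal(
        mat, np.array([[1, 2, 0], [0, 2, 1], [1, 0, 2]], dtype=float)
    )
    norm = confusion(preds, labels, CLASSES3)
    assert np.allclose(norm.sum(axis=1), 1.0)


# -- grid search ------------------------------------------------------------

@pytest.fixture(scope="module")
def grid_dataset():
    lib = ps.generate_library(30, seed=2)
    recs = ps.plant_screen(lib, ps.default_rules(noise_rate=0.0), seed=2)
    return ps.build_dataset(recs)


def test_one_point_grid_equals_plain_cv(grid_dataset):
    spec = ps.ModelSpec("linear", "mlp", dict(layers=1, hidden=4, head_hidden=[4], epochs=2, seed=0))
    plan = SplitPlan(seed=0)
    r1 = grid_search(spec, {}, grid_dataset, plan)
    r2 = grid_search(spec, {"epochs": [2]}, grid_dataset, plan)
    assert r1.valid_auroc_mean == pytest.approx(r2.valid_auroc_mean)
    assert r1.test_auroc == pytest.approx(r2.test_auroc)


def test_degenerate_grid_point_not_selected(grid_dataset):
    spec = ps.ModelSpec("linear", "mlp", dict(layers=1, hidden=4, head_hidden=[4], seed=0))
    # 0 epochs leaves the head at its random initialization
    report = grid_search(spec, {"epochs": [0, 6]}, grid_dataset, SplitPlan(seed=0))
    assert report.chosen_params == {"epochs": 6}
    assert len(report.cv_results) == 2


def test_grid_search_deterministic(grid_dataset):
    spec = ps.ModelSpec("linear", "mlp", dict(layers=1, hidden=4, head_hidden=[4], epochs=2, seed=0))
    r1 = grid_search(spec, {"lr": [1e-3, 1e-2]}, grid_dataset, SplitPlan(seed=4))
    r2 = grid_search(spec, {"lr": [1e-3, 1e-2]}, grid_dataset, SplitPlan(seed=4))
    assert r1.chosen_params == r2.chosen_params
    assert r1.test_auroc == r2.test_auroc


def test_failing_grid_point_recorded(grid_dataset):
    spec = ps.ModelSpec("linear", "mlp", dict(layers=1, hidden=4, head_hidden=[4], epochs=2, seed=0))
    report = grid_search(
        spec, {"readout": ["mean", "not-a-readout"]}, grid_dataset, SplitPlan(seed=0)
    )
    assert len(report.failures) == 1
    assert report.failures[0]["params"] == {"readout": "not-a-readout"}
    assert report.chosen_params == {"readout": "mean"}
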