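"""Population decoding: single-region MLP decoding, cross-stimulus transfer,
three-class CS discrimination, and multi-region random-forest decoding with
per-region feature importance.

The common pipeline per iteration: draw a random neuron subset, balance
classes by random under-sampling, then stratified 5-fold cross-validation
with z-scoring fit on the training folds only (no leakage).  Decoder
accuracy Da is the mean held-out accuracy over folds and repeats; the
shuffled-label control reruns the identical pipeline on a permuted class
vector and must sit at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .binning import LabeledDataset

__all__ = [
    "DecodingResult",
    "TransferResult",
    "DiscriminationResult",
    "ImportanceProfile",
    "decode_single_region",
    "rank_best_neurons",
    "cross_stimulus_transfer",
    "discriminate_cs",
    "decode_multi_region",
    "contrast_importance",
]


@dataclass
class DecodingResult:
    task: str
    accuracies: np.ndarray  # per repeat
    shuffled_accuracies: np.ndarray
    n_neurons: int
    n_draws: int
    seed: int

    @property
    def da(self) -> float:
        """Decoder accuracy: mean held-out accuracy over all iterations."""
        return float(np.mean(self.accuracies))

    @property
    def da_shuffled(self) -> float:
        return float(np.mean(self.shuffled_accuracies)) if len(self.shuffled_accuracies) else np.nan


@dataclass
class TransferResult:
    train_stimulus: str
    test_stimulus: str
    accuracies: np.ndarray  # per repeat
    shuffled_accuracies: np.ndarray

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))


@dataclass
class DiscriminationResult:
    overall_accuracy: float
    conditional_cs_accuracy: float  # correct CS assignments / bins predicted as CS
    undefined: bool = False  # no bin predicted as a CS class


@dataclass
class ImportanceProfile:
    regions: list[str]
    per_region: dict[str, np.ndarray]  # region -> per-iteration mean importance
    per_neuron: np.ndarray  # mean importance per neuron in draw order
    n_iterations: int

    def mean_by_region(self) -> dict[str, float]:
        return {r: float(np.mean(v)) for r, v in self.per_region.items()}


def _default_mlp(seed: int) -> MLPClassifier:
    # one hidden layer of 100 rectified units, adam, <= 200 epochs
    return MLPClassifier(
        hidden_layer_sizes=(100,),
        activation="relu",
        solver="adam",
        max_iter=200,
        random_state=seed,
    )


def _undersample(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Indices of a class-balanced subset (random under-sampling)."""
    classes, counts = np.unique(y, return_counts=True)
    n = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        keep.append(rng.choice(idx, size=n, replace=False))
    return np.sort(np.concatenate(keep))


def _cv_accuracy(
    X: np.ndarray,
    y: np.ndarray,
    clf_factory,
    folds: int,
    rng: np.random.Generator,
    return_importance: bool = False,
) -> float | tuple[float, np.ndarray]:
    """Stratified k-fold CV with fold-local z-scoring; returns mean held-out
    accuracy (and, optionally, impurity feature importances from a fit on
    the full balanced set)."""
    skf = StratifiedKFold(
        n_splits=folds, shuffle=True, random_state=int(rng.integers(0, 2**31 - 1))
    )
    accs = []
    for tr_idx, te_idx in skf.split(X, y):
        pipe = make_pipeline(
            StandardScaler(), clf_factory(int(rng.integers(0, 2**31 - 1)))
        )
        pipe.fit(X[tr_idx], y[tr_idx])
        accs.append(pipe.score(X[te_idx], y[te_idx]))
    acc = float(np.mean(accs))
    if not return_importance:
        return acc
    clf = clf_factory(int(rng.integers(0, 2**31 - 1)))
    clf.fit(StandardScaler().fit_transform(X), y)
    return acc, clf.feature_importances_


def _check_classes(y: np.ndarray, expected: int | None = None) -> None:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least two classes present")
    if expected is not None and len(classes) != expected:
        raise ValueError(f"expected {expected} classes, found {len(classes)}")


def decode_single_region(
    data: LabeledDataset,
    n_neurons: int,
    n_draws: int = 1,
    repeats: int = 40,
    folds: int = 5,
    seed: int = 0,
    classifier: str = "mlp",
    shuffled_control: bool = True,
) -> DecodingResult:
    """Single-region decoding of a binary task (Da over CV repeats).

    Each iteration draws ``n_neurons`` without replacement, balances classes
    by under-sampling, and runs stratified 5-fold CV with an MLP (z-scoring
    fit per training fold).  ``repeats`` iterations per draw; Da is the mean
    over everything.  The shuffled control permutes y and reruns the
    identical procedure.
    """
    if n_neurons > data.n_neurons:
        raise ValueError(f"n_neurons={n_neurons} > available {data.n_neurons}")
    _check_classes(data.y)
    factory = _default_mlp if classifier == "mlp" else (
        lambda s: RandomForestClassifier(n_estimators=100, random_state=s)
    )
    rng = np.random.default_rng(seed)
    accs, sh_accs = [], []
    for _ in range(n_draws):
        cols = rng.choice(data.n_neurons, size=n_neurons, replace=False)
        for _ in range(repeats):
            rows = _undersample(data.y, rng)
            X, y = data.X[rows][:, cols], data.y[rows]
            accs.append(_cv_accuracy(X, y, factory, folds, rng))
            if shuffled_control:
                y_sh = rng.permutation(y)
                sh_accs.append(_cv_accuracy(X, y_sh, factory, folds, rng))
    return DecodingResult(
        task=data.task,
        accuracies=np.asarray(accs),
        shuffled_accuracies=np.asarray(sh_accs),
        n_neurons=n_neurons,
        n_draws=n_draws,
        seed=seed,
    )


def rank_best_neurons(
    data: LabeledDataset,
    repeats: int = 5,
    folds: int = 5,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Rank neurons by their single-neuron decoder accuracy, descending;
    ties break on neuron index (ascending)."""
    _check_classes(data.y)
    rng = np.random.default_rng(seed)
    scores = []
    for i in range(data.n_neurons):
        accs = []
        for _ in range(repeats):
            rows = _undersample(data.y, rng)
            accs.append(
                _cv_accuracy(data.X[rows][:, [i]], data.y[rows], _default_mlp, folds, rng)
            )
        scores.append((i, float(np.mean(accs))))
    return sorted(scores, key=lambda t: (-t[1], t[0]))


def cross_stimulus_transfer(
    train: LabeledDataset,
    test: LabeledDataset,
    repeats: int = 10,
    seed: int = 0,
    classifier: str = "mlp",
) -> TransferResult:
    """Train a decoder on one stimulus and apply it to another.

    Balancing and z-scoring are fit on the training set only and applied
    unchanged to the (balanced) test set.  Covers the four combinations of
    interest: US-on-CS within valence and R-CS-on-F-CS across valences.
    A shuffled-test-label control is included.
    """
    if train.n_neurons != test.n_neurons:
        raise ValueError("train/test feature dimensions differ")
    _check_classes(train.y)
    _check_classes(test.y)
    factory = _default_mlp if classifier == "mlp" else (
        lambda s: RandomForestClassifier(n_estimators=100, random_state=s)
    )
    rng = np.random.default_rng(seed)
    accs, sh = [], []
    for _ in range(repeats):
        tr_rows = _undersample(train.y, rng)
        te_rows = _undersample(test.y, rng)
        pipe = make_pipeline(StandardScaler(), factory(int(rng.integers(0, 2**31 - 1))))
        pipe.fit(train.X[tr_rows], train.y[tr_rows])
        accs.append(pipe.score(test.X[te_rows], test.y[te_rows]))
        sh.append(pipe.score(test.X[te_rows], rng.permutation(test.y[te_rows])))
    return TransferResult(
        train_stimulus=train.task,
        test_stimulus=test.task,
        accuracies=np.asarray(accs),
        shuffled_accuracies=np.asarray(sh),
    )


def discriminate_cs(
    data: LabeledDataset,
    n_neurons: int | None = None,
    repeats: int = 10,
    folds: int = 5,
    seed: int = 0,
) -> DiscriminationResult:
    """Three-class discrimination (pre-CS / R-CS / F-CS).

    Reports the overall 3-class accuracy and the conditional CS accuracy:
    among held-out bins that are truly CS bins *and* predicted as either CS
    class, the fraction assigned to the correct CS.
    """
    _check_classes(data.y, expected=3)
    n_neurons = n_neurons or data.n_neurons
    if n_neurons > data.n_neurons:
        raise ValueError("n_neurons exceeds available neurons")
    rng = np.random.default_rng(seed)
    overall, cond_num, cond_den = [], 0, 0
    for _ in range(repeats):
        cols = rng.choice(data.n_neurons, size=n_neurons, replace=False)
        rows = _undersample(data.y, rng)
        X, y = data.X[rows][:, cols], data.y[rows]
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(0, 2**31 - 1)))
        for tr_idx, te_idx in skf.split(X, y):
            pipe = make_pipeline(StandardScaler(), _default_mlp(int(rng.integers(0, 2**31 - 1))))
            pipe.fit(X[tr_idx], y[tr_idx])
            pred = pipe.predict(X[te_idx])
            overall.append(np.mean(pred == y[te_idx]))
            is_cs = (y[te_idx] > 0) & (pred > 0)
            cond_den += int(is_cs.sum())
            cond_num += int((pred[is_cs] == y[te_idx][is_cs]).sum())
    if cond_den == 0:
        return DiscriminationResult(float(np.mean(overall)), np.nan, undefined=True)
    return DiscriminationResult(
        overall_accuracy=float(np.mean(overall)),
        conditional_cs_accuracy=cond_num / cond_den,
    )


def _largest_remainder(pool: dict[str, int], n_total: int) -> dict[str, int]:
    total = sum(pool.values())
    if total <= n_total:
        return dict(pool)
    quotas = {r: n_total * c / total for r, c in pool.items()}
    alloc = {r: int(np.floor(q)) for r, q in quotas.items()}
    short = n_total - sum(alloc.values())
    for r in sorted(quotas, key=lambda r: (-(quotas[r] - alloc[r]), r))[:short]:
        alloc[r] += 1
    return alloc


def decode_multi_region(
    data: LabeledDataset,
    n_total: int = 100,
    repeats: int = 40,
    folds: int = 5,
    seed: int = 0,
    n_trees: int = 100,
) -> tuple[DecodingResult, ImportanceProfile]:
    """Multi-region random-forest decoding with per-region importances.

    Each iteration draws ``n_total`` neurons with per-region counts
    proportional to the pool composition (largest-remainder rounding), runs
    the balanced 5-fold CV pipeline with a random forest, and records the
    impurity-based feature importances (summing to 1 per iteration).  The
    profile carries per-iteration per-region mean importances for the
    permutation contrast.
    """
    _check_classes(data.y)
    regions = list(data.regions)
    if not regions:
        raise ValueError("dataset has no region labels")
    reg_arr = np.asarray(regions)
    region_set = sorted(set(regions))
    pool = {r: int((reg_arr == r).sum()) for r in region_set}
    alloc = _largest_remainder(pool, n_total)

    rng = np.random.default_rng(seed)
    factory = lambda s: RandomForestClassifier(n_estimators=n_trees, random_state=s)
    accs = []
    per_region: dict[str, list[float]] = {r: [] for r in region_set}
    neuron_imp_sum = np.zeros(data.n_neurons)
    neuron_imp_cnt = np.zeros(data.n_neurons)
    for _ in range(repeats):
        cols = []
        for r in region_set:
            idx = np.flatnonzero(reg_arr == r)
            k = min(alloc.get(r, 0), len(idx))
            if k > 0:
                cols.append(rng.choice(idx, size=k, replace=False))
        cols = np.sort(np.concatenate(cols))
        col_regions = reg_arr[cols]
        rows = _undersample(data.y, rng)
        X, y = data.X[rows][:, cols], data.y[rows]
        acc, imp = _cv_accuracy(X, y, factory, folds, rng, return_importance=True)
        accs.append(acc)
        for r in region_set:
            sel = col_regions == r
            if sel.any():
                per_region[r].append(float(imp[sel].mean()))
        neuron_imp_sum[cols] += imp
        neuron_imp_cnt[cols] += 1
    with np.errstate(invalid="ignore"):
        per_neuron = np.where(neuron_imp_cnt > 0, neuron_imp_sum / np.maximum(neuron_imp_cnt, 1), np.nan)
    result = DecodingResult(
        task=data.task,
        accuracies=np.asarray(accs),
        shuffled_accuracies=np.asarray([]),
        n_neurons=n_total,
        n_draws=repeats,
        seed=seed,
    )
    profile = ImportanceProfile(
        regions=region_set,
        per_region={r: np.asarray(v) for r, v in per_region.items()},
        per_neuron=per_neuron,
        n_iterations=repeats,
    )
    return result, profile


def contrast_importance(
    a: ImportanceProfile,
    b: ImportanceProfile,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Per-region contrast of mean feature importance between two decoding
    conditions: difference of means and a two-sided permutation p-value over
    the pooled per-iteration values."""
    if sorted(a.regions) != sorted(b.regions):
        raise ValueError("region sets differ")
    if a.n_iterations != b.n_iterations:
        raise ValueError("iteration counts differ")
    rng = np.random.default_rng(seed)
    out = {}
    for r in sorted(a.regions):
        va, vb = a.per_region[r], b.per_region[r]
        obs = float(va.mean() - vb.mean())
        pooled = np.concatenate([va, vb])
        n = len(va)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            d = perm[:n].mean() - perm[n:].mean()
            if abs(d) >= abs(obs) - 1e-15:
                count += 1
        out[r] = (obs, count / n_perm)
    return out
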