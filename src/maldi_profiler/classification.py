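"""The three classifier families applied to peak matrices.

* **GA** — genetic-algorithm selection of a fixed-size peak subset whose
  fitness is the stratified internal cross-validation accuracy of a
  k-nearest-neighbour classifier on the selected, standardized columns.
  Defaults: 10 best peaks, 50 generations, mutation rate 0.2, crossover
  rate 0.5, 5 nearest neighbours.
* **SNN** — a prototype ("supervised neural network") classifier trained
  LVQ1-style: per class a fixed number of prototypes (default 5) initialized
  by k-means, then attract-correct / repel-incorrect updates for a fixed
  number of generations (default 50) with a linearly decaying learning rate.
  Its peak subset is chosen by PTTA ranking with the subset size maximizing
  internal CV accuracy.
* **QC** — the quick classifier: a weighted class-average rule.  Peaks are
  sorted by p-value; the prefix size is chosen automatically (smallest size
  within one standard error of the best internal-CV accuracy); per-peak
  weights are -log10(p); prediction assigns every spectrum a weight for each
  class (softmax of negative weighted distance to the class mean, summing
  to 1), the reported label being the heaviest class.

All trainers standardize features column-wise with training statistics
before any distance computation, are deterministic under a fixed seed, and
produce JSON-serializable :class:`~maldi_profiler.core_io.ClassifierModel`
objects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core_io import ClassifierModel, PeakMatrix
from .stats import class_tests


@dataclass
class GAParams:
    max_best_peaks: int = 10
    max_generations: int = 50
    mutation_rate: float = 0.2
    crossover_rate: float = 0.5
    k_neighbors: int = 5
    population_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.mutation_rate <= 1 and 0 <= self.crossover_rate <= 1):
            raise ValueError("rates must lie in [0, 1]")


@dataclass
class SNNParams:
    max_generations: int = 50
    prototypes_per_class: int = 5
    learning_rate: float = 0.3
    candidate_subset_sizes: Optional[list] = None
    seed: int = 0


@dataclass
class QCParams:
    peak_count: object = "auto"      # "auto" or explicit count
    sort_statistic: str = "ptta"     # "ptta" | "pwkw"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sort_statistic not in ("ptta", "pwkw"):
            raise ValueError("sort_statistic must be 'ptta' or 'pwkw'")


@dataclass
class Prediction:
    """Per-sample predicted labels; QC additionally carries class weights."""

    labels: np.ndarray
    class_names: list
    weights: Optional[np.ndarray] = None  # n_samples x n_classes, rows sum to 1


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _standardize_fit(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return mean, sd


def _stratified_folds(labels, n_folds: int, rng: np.random.Generator) -> list:
    """Deal each class's shuffled indices round-robin into folds."""
    labels = np.asarray(labels)
    folds: list = [[] for _ in range(n_folds)]
    for c in dict.fromkeys(labels.tolist()):
        idx = np.flatnonzero(labels == c)
        idx = idx[rng.permutation(len(idx))]
        for i, s in enumerate(idx):
            folds[i % n_folds].append(int(s))
    return [np.array(sorted(f), dtype=int) for f in folds]


def _knn_predict(train_X, train_y, test_X, k: int, class_names) -> np.ndarray:
    """Deterministic Euclidean kNN with majority vote; ties broken by the
    nearest neighbour among the tied classes."""
    k = min(k, len(train_X))
    d = np.sqrt(((test_X[:, None, :] - train_X[None, :, :]) ** 2).sum(axis=2))
    out = []
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    for row in order:
        votes: dict = {}
        for j in row:
            votes[train_y[j]] = votes.get(train_y[j], 0) + 1
        best = max(votes.values())
        tied = {c for c, v in votes.items() if v == best}
        if len(tied) == 1:
            out.append(next(iter(tied)))
        else:
            for j in row:  # nearest neighbour in a tied class wins
                if train_y[j] in tied:
                    out.append(train_y[j])
                    break
    return np.asarray(out)


def _cv_accuracy(X, y, folds, fit_predict) -> tuple:
    """Mean held-out accuracy over folds; ``fit_predict(train_X, train_y,
    test_X) -> labels``.  Returns (mean, per-fold array)."""
    accs = []
    n = len(y)
    for f in folds:
        test = np.zeros(n, dtype=bool)
        test[f] = True
        if test.all() or not test.any():
            continue
        pred = fit_predict(X[~test], y[~test], X[test])
        accs.append(float(np.mean(pred == y[test])))
    accs = np.array(accs)
    return float(accs.mean()), accs


def _knn_subset_fitness(X, y, subset, folds, k, class_names) -> float:
    cols = np.asarray(subset, dtype=int)

    def fp(tr_X, tr_y, te_X):
        mean, sd = _standardize_fit(tr_X[:, cols])
        return _knn_predict((tr_X[:, cols] - mean) / sd, tr_y,
                            (te_X[:, cols] - mean) / sd, k, class_names)

    return _cv_accuracy(X, y, folds, fp)[0]


def _n_folds_for(labels, wanted: int = 5) -> int:
    counts = np.unique(np.asarray(labels), return_counts=True)[1]
    return max(2, min(wanted, int(counts.min())))


# ---------------------------------------------------------------------------
# GA
# ---------------------------------------------------------------------------

def train_ga(matrix: PeakMatrix, params: GAParams | None = None
             ) -> ClassifierModel:
    """Evolve a fixed-size peak subset maximizing internal-CV kNN accuracy.

    Chromosomes are index subsets of size exactly ``max_best_peaks``;
    selection is 2-way tournament with elitism of 1, crossover is
    single-point on the sorted index lists (with repair), and mutation
    replaces individual genes with unused peaks.
    """
    params = params or GAParams()
    X, y = matrix.values, np.asarray(matrix.labels)
    n_peaks = matrix.n_peaks
    m = params.max_best_peaks
    if m > n_peaks:
        raise ValueError(f"max_best_peaks={m} exceeds {n_peaks} available peaks")
    if len(X) < params.k_neighbors + 1:
        raise ValueError("too few samples for the kNN fitness")
    classes = matrix.class_names
    rng = np.random.default_rng(params.seed)
    folds = _stratified_folds(y, _n_folds_for(y), rng)
    cache: dict = {}

    def fitness(subset: tuple) -> float:
        if subset not in cache:
            cache[subset] = _knn_subset_fitness(X, y, subset, folds,
                                                params.k_neighbors, classes)
        return cache[subset]

    def random_subset() -> tuple:
        return tuple(sorted(rng.choice(n_peaks, size=m, replace=False).tolist()))

    def mutate(subset: tuple) -> tuple:
        genes = list(subset)
        for i in range(m):
            if rng.random() < params.mutation_rate:
                unused = [g for g in range(n_peaks) if g not in genes]
                if unused:
                    genes[i] = unused[rng.integers(len(unused))]
        return tuple(sorted(genes))

    def crossover(a: tuple, b: tuple) -> tuple:
        cut = int(rng.integers(1, m)) if m > 1 else 1
        child = list(a[:cut])
        for g in b:
            if len(child) >= m:
                break
            if g not in child:
                child.append(g)
        while len(child) < m:  # repair with unused genes
            unused = [g for g in range(n_peaks) if g not in child]
            child.append(unused[rng.integers(len(unused))])
        return tuple(sorted(child))

    pop = [random_subset() for _ in range(params.population_size)]
    fits = [fitness(s) for s in pop]
    initial_max = max(fits)
    best_subset = pop[int(np.argmax(fits))]
    best_fit = initial_max

    def tournament() -> tuple:
        i, j = rng.integers(len(pop)), rng.integers(len(pop))
        return pop[i] if fits[i] >= fits[j] else pop[j]

    for _ in range(params.max_generations):
        new_pop = [best_subset]  # elitism of 1
        while len(new_pop) < params.population_size:
            a, b = tournament(), tournament()
            child = crossover(a, b) if rng.random() < params.crossover_rate else a
            new_pop.append(mutate(child))
        pop = new_pop
        fits = [fitness(s) for s in pop]
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = fits[gen_best]
            best_subset = pop[gen_best]

    cols = np.asarray(best_subset, dtype=int)
    mean, sd = _standardize_fit(X[:, cols])
    return ClassifierModel(
        model_type="GA",
        peak_indices=list(best_subset),
        class_names=list(classes),
        params={
            "k_neighbors": params.k_neighbors,
            "feature_means": mean, "feature_sds": sd,
            "exemplars": (X[:, cols] - mean) / sd,
            "exemplar_labels": y.tolist(),
            "peak_centroids": [matrix.peaks[i].centroid_mz for i in best_subset],
            "best_fitness": best_fit,
            "initial_max_fitness": initial_max,
            "seed": params.seed,
        },
    )


# ---------------------------------------------------------------------------
# SNN (LVQ1 prototype classifier)
# ---------------------------------------------------------------------------

def _fit_lvq(Xs, y, prototypes_per_class, epochs, lr0, rng, class_names):
    from sklearn.cluster import KMeans

    protos, proto_labels = [], []
    for c in class_names:
        rows = Xs[np.asarray(y) == c]
        km = KMeans(n_clusters=prototypes_per_class, n_init=4,
                    random_state=int(rng.integers(2 ** 31)))
        km.fit(rows)
        protos.append(km.cluster_centers_)
        proto_labels.extend([c] * prototypes_per_class)
    W = np.vstack(protos)
    proto_labels = np.asarray(proto_labels)
    n = len(Xs)
    for t in range(epochs):
        lr = lr0 * (1.0 - t / epochs)
        for i in rng.permutation(n):
            x = Xs[i]
            j = int(np.argmin(((W - x) ** 2).sum(axis=1)))
            if proto_labels[j] == y[i]:
                W[j] += lr * (x - W[j])
            else:
                W[j] -= lr * (x - W[j])
    return W, proto_labels


def _lvq_predict(W, proto_labels, Xs) -> np.ndarray:
    d = ((Xs[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
    return proto_labels[np.argmin(d, axis=1)]


def train_snn(matrix: PeakMatrix, params: SNNParams | None = None
              ) -> ClassifierModel:
    """Train the prototype classifier on a PTTA-ranked peak subset whose
    size maximizes internal-CV accuracy."""
    params = params or SNNParams()
    X, y = matrix.values, np.asarray(matrix.labels)
    classes = matrix.class_names
    counts = {c: int((y == c).sum()) for c in classes}
    small = [c for c, n in counts.items() if n < params.prototypes_per_class]
    if small:
        raise ValueError(
            f"classes {small} have fewer samples than "
            f"{params.prototypes_per_class} prototypes")
    rows = class_tests(matrix)
    p = np.array([r.ptta for r in rows])
    ranked = np.argsort(p, kind="stable")
    n_peaks = matrix.n_peaks
    sizes = params.candidate_subset_sizes or [1, 2, 3, 5, 7, 10, 15, 20, 25]
    sizes = sorted({min(s, n_peaks) for s in sizes if s >= 1})
    rng = np.random.default_rng(params.seed)
    folds = _stratified_folds(y, _n_folds_for(y), rng)

    def fp_factory(cols, fit_seed):
        def fp(tr_X, tr_y, te_X):
            r = np.random.default_rng(fit_seed)
            mean, sd = _standardize_fit(tr_X[:, cols])
            ppc = min(params.prototypes_per_class,
                      min(np.unique(tr_y, return_counts=True)[1]))
            W, pl = _fit_lvq((tr_X[:, cols] - mean) / sd, tr_y, ppc,
                             params.max_generations, params.learning_rate,
                             r, classes)
            return _lvq_predict(W, pl, (te_X[:, cols] - mean) / sd)
        return fp

    best_size, best_acc = sizes[0], -1.0
    for s_i, size in enumerate(sizes):
        cols = ranked[:size]
        acc, _ = _cv_accuracy(X, y, folds,
                              fp_factory(cols, params.seed * 1000 + s_i))
        if acc > best_acc:
            best_acc, best_size = acc, size
    cols = np.sort(ranked[:best_size])
    mean, sd = _standardize_fit(X[:, cols])
    W, pl = _fit_lvq((X[:, cols] - mean) / sd, y,
                     params.prototypes_per_class, params.max_generations,
                     params.learning_rate, np.random.default_rng(params.seed),
                     classes)
    return ClassifierModel(
        model_type="SNN",
        peak_indices=cols.tolist(),
        class_names=list(classes),
        params={
            "prototypes": W, "prototype_labels": pl.tolist(),
            "feature_means": mean, "feature_sds": sd,
            "peak_centroids": [matrix.peaks[i].centroid_mz for i in cols],
            "internal_cv_accuracy": best_acc,
            "subset_size": int(best_size),
            "seed": params.seed,
        },
    )


# ---------------------------------------------------------------------------
# QC (weighted class-average classifier)
# ---------------------------------------------------------------------------

def _qc_fit_predict_factory(cols, weights):
    cols = np.asarray(cols, dtype=int)
    w = np.asarray(weights, dtype=float)

    def fp(tr_X, tr_y, te_X):
        mean, sd = _standardize_fit(tr_X[:, cols])
        Xt = (tr_X[:, cols] - mean) / sd
        Xe = (te_X[:, cols] - mean) / sd
        classes = list(dict.fromkeys(tr_y.tolist()))
        mus = np.vstack([Xt[tr_y == c].mean(axis=0) for c in classes])
        d = np.sqrt((w * (Xe[:, None, :] - mus[None, :, :]) ** 2).sum(axis=2))
        return np.asarray(classes)[np.argmin(d, axis=1)]

    return fp


def train_qc(matrix: PeakMatrix, params: QCParams | None = None
             ) -> ClassifierModel:
    """Fit the quick classifier: p-value-ranked peaks, automatic prefix-size
    selection (smallest within one SE of the best internal-CV accuracy),
    -log10(p) peak weights, and per-class mean vectors."""
    params = params or QCParams()
    X, y = matrix.values, np.asarray(matrix.labels)
    classes = matrix.class_names
    rows = class_tests(matrix)
    p = np.array([getattr(r, params.sort_statistic) for r in rows])
    if np.all(p >= 1.0):
        raise ValueError("no discriminative peaks: all p-values are 1")
    order = np.argsort(p, kind="stable")
    weights_all = -np.log10(np.clip(p, 1e-300, 1.0))
    rng = np.random.default_rng(params.seed)
    folds = _stratified_folds(y, _n_folds_for(y), rng)
    if params.peak_count == "auto":
        accs, ses = [], []
        for m in range(1, matrix.n_peaks + 1):
            cols = order[:m]
            acc, per_fold = _cv_accuracy(
                X, y, folds, _qc_fit_predict_factory(cols, weights_all[cols]))
            accs.append(acc)
            ses.append(per_fold.std(ddof=1) / np.sqrt(len(per_fold))
                       if len(per_fold) > 1 else 0.0)
        accs = np.array(accs)
        best = int(np.argmax(accs))
        thr = accs[best] - ses[best]
        m_sel = int(np.flatnonzero(accs >= thr)[0]) + 1
    else:
        m_sel = int(params.peak_count)
        if not (1 <= m_sel <= matrix.n_peaks):
            raise ValueError("peak_count out of range")
    cols = np.sort(order[:m_sel])
    w = weights_all[cols]
    mean, sd = _standardize_fit(X[:, cols])
    Xs = (X[:, cols] - mean) / sd
    class_means = {c: Xs[y == c].mean(axis=0) for c in classes}
    return ClassifierModel(
        model_type="QC",
        peak_indices=cols.tolist(),
        class_names=list(classes),
        params={
            "class_means": class_means,
            "weights": w,
            "feature_means": mean, "feature_sds": sd,
            "peak_centroids": [matrix.peaks[i].centroid_mz for i in cols],
            "sort_statistic": params.sort_statistic,
            "seed": params.seed,
        },
    )


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _check_alignment(model: ClassifierModel, matrix: PeakMatrix) -> np.ndarray:
    cols = np.asarray(model.peak_indices, dtype=int)
    if cols.max() >= matrix.n_peaks:
        raise ValueError(
            f"matrix has {matrix.n_peaks} peaks; model needs columns "
            f"{[int(c) for c in cols if c >= matrix.n_peaks]}")
    stored = np.asarray(model.params.get("peak_centroids", []), dtype=float)
    if len(stored):
        have = matrix.centroids()[cols]
        off = ~np.isclose(have, stored, rtol=1e-6)
        if off.any():
            raise ValueError(
                f"matrix peaks misaligned with model: expected centroids "
                f"{stored[off].tolist()}, found {have[off].tolist()}")
    return cols


def predict(model: ClassifierModel, matrix: PeakMatrix) -> Prediction:
    """Classify every row of a peak matrix with a trained model.

    GA and SNN emit a single label per sample; QC additionally emits a
    normalized weight per class.
    """
    cols = _check_alignment(model, matrix)
    pr = model.params
    mean = np.asarray(pr["feature_means"], dtype=float)
    sd = np.asarray(pr["feature_sds"], dtype=float)
    Xs = (matrix.values[:, cols] - mean) / sd
    classes = list(model.class_names)
    if model.model_type == "GA":
        labels = _knn_predict(np.asarray(pr["exemplars"], dtype=float),
                              np.asarray(pr["exemplar_labels"]),
                              Xs, int(pr["k_neighbors"]), classes)
        return Prediction(labels=labels, class_names=classes)
    if model.model_type == "SNN":
        labels = _lvq_predict(np.asarray(pr["prototypes"], dtype=float),
                              np.asarray(pr["prototype_labels"]), Xs)
        return Prediction(labels=labels, class_names=classes)
    # QC
    w = np.asarray(pr["weights"], dtype=float)
    mus = np.vstack([np.asarray(pr["class_means"][c], dtype=float)
                     for c in classes])
    d = np.sqrt((w * (Xs[:, None, :] - mus[None, :, :]) ** 2).sum(axis=2))
    z = -d
    z -= z.max(axis=1, keepdims=True)
    weights = np.exp(z)
    weights /= weights.sum(axis=1, keepdims=True)
    labels = np.asarray(classes)[np.argmax(weights, axis=1)]
    return Prediction(labels=labels, class_names=classes, weights=weights)
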