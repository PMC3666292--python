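"""One-vs-one three-class SVM with max-wins voting, grid search and
chain-level cross-validation.

The three-class problem {H, E, C} is decomposed into the three pairwise
binary problems H/E, E/C and C/H, each solved by an RBF-kernel support
vector machine (the binary optimizer is scikit-learn's SVC, which wraps
LIBSVM).  Prediction lets each binary classifier cast a vote and returns
the class with the most votes; ties are broken by training-set class
frequency and then by the fixed order C > H > E, making prediction
deterministic.  Class labels carry the conventional numeric mapping
H -> -1, E -> +1, C -> +2.

Hyper-parameters (cost C, kernel width gamma, window size WS) are selected
by exhaustive grid search over C in {2^0..2^5} and gamma in {2^-6..2^-1}
for each window size, scored by mean cross-validated Q3.  Folds partition
whole chains, never residues, so overlapping windows of one chain can never
straddle the train/test boundary.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from .features import WindowEncoder, feature_dimension
from .metrics import q3
from .pssm import PssmProfile, normalize_profile
from .sequences import ProteinChain, StructureString

#: conventional numeric labels for the three states
LABEL_MAP = {"H": -1, "E": +1, "C": +2}

#: the three pairwise problems of the one-vs-one decomposition
CLASS_PAIRS = (("H", "E"), ("E", "C"), ("C", "H"))

#: fixed-order tie break, applied after training-set frequency
TIE_ORDER = ("C", "H", "E")

DEFAULT_C_GRID = tuple(2.0**k for k in range(0, 6))
DEFAULT_GAMMA_GRID = tuple(2.0**k for k in range(-6, 0))


class OneVsOneStructureSVM(ClassifierMixin, BaseEstimator):
    """Three-class secondary-structure SVM (one-vs-one, max-wins voting).

    Parameters
    ----------
    C : float, default 2.0
        Soft-margin cost of each binary RBF SVM.
    gamma : float, default 2**-4
        RBF kernel width.
    cache_size : float, default 500
        LIBSVM kernel cache in MB.

    Attributes
    ----------
    estimators_ : dict mapping class pairs to fitted binary SVCs (always 3).
    classes_ : array of the three class labels.
    class_counts_ : training-set frequency of each class (tie-breaking).
    """

    def __init__(self, C: float = 2.0, gamma: float = 2.0**-4,
                 cache_size: float = 500.0):
        self.C = C
        self.gamma = gamma
        self.cache_size = cache_size

    def fit(self, X: np.ndarray, y) -> "OneVsOneStructureSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(list(y))
        if X.ndim != 2 or X.shape[0] != len(y):
            raise ValueError("X must be 2-D with one row per label")
        present = set(y.tolist())
        missing = sorted(set(LABEL_MAP) - present)
        if missing:
            raise ValueError(f"training labels missing class(es): {missing}")
        unknown = sorted(present - set(LABEL_MAP))
        if unknown:
            raise ValueError(f"unknown class label(s): {unknown}")
        self.classes_ = np.array(sorted(LABEL_MAP))
        self.class_counts_ = {c: int(np.sum(y == c)) for c in LABEL_MAP}
        self.n_features_in_ = X.shape[1]
        self.estimators_ = {}
        for a, b in CLASS_PAIRS:
            mask = (y == a) | (y == b)
            yn = np.where(y[mask] == a, LABEL_MAP[a], LABEL_MAP[b])
            clf = SVC(kernel="rbf", C=self.C, gamma=self.gamma,
                      cache_size=self.cache_size)
            clf.fit(X[mask], yn)
            self.estimators_[(a, b)] = clf
        return self

    @property
    def binary_classifier_count(self) -> int:
        return len(self.estimators_)

    def _votes(self, X: np.ndarray) -> dict[str, np.ndarray]:
        votes = {c: np.zeros(X.shape[0], dtype=int) for c in LABEL_MAP}
        inverse = {v: k for k, v in LABEL_MAP.items()}
        for (a, b), clf in self.estimators_.items():
            pred = clf.predict(X)
            for cls in (a, b):
                votes[cls] += pred == LABEL_MAP[cls]
            # guard against a stub/binary model emitting a third label
            for num, cls in inverse.items():
                if cls not in (a, b):
                    votes[cls] += pred == num
        return votes

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Max-wins voting over the three binary decisions."""
        if not hasattr(self, "estimators_"):
            raise RuntimeError("model is not fitted")
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            return np.array([], dtype="<U1")
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got "
                f"{X.shape[1] if X.ndim == 2 else 'non-2D input'}"
            )
        votes = self._votes(X)
        stacked = np.stack([votes[c] for c in LABEL_MAP])  # order H, E, C
        names = list(LABEL_MAP)
        out = np.empty(X.shape[0], dtype="<U1")
        best = stacked.max(axis=0)
        for i in range(X.shape[0]):
            tied = [names[k] for k in range(3) if stacked[k, i] == best[i]]
            if len(tied) == 1:
                out[i] = tied[0]
            else:
                top = max(self.class_counts_[c] for c in tied)
                tied = [c for c in tied if self.class_counts_[c] == top]
                out[i] = min(tied, key=TIE_ORDER.index)
        return out


def chain_kfold(
    n_chains: int, n_folds: int = 3, seed: int = 0
) -> list[np.ndarray]:
    """Partition chain indices into folds: seeded shuffle, then round-robin."""
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_chains < n_folds:
        raise ValueError("fewer chains than folds")
    order = np.random.default_rng(seed).permutation(n_chains)
    return [order[k::n_folds] for k in range(n_folds)]


@dataclass
class GridSearchResult:
    best_C: float
    best_gamma: float
    best_ws: int
    best_accuracy: float
    #: rows (ws, features, C, gamma, mean CV Q3), all grid points
    table: list[tuple[int, int, float, float, float]] = field(default_factory=list)

    def best_per_ws(self) -> list[tuple[int, int, float, float, float]]:
        """One row per window size, the layout benchmarks are reported in."""
        rows = []
        for ws in sorted({r[0] for r in self.table}):
            rows.append(max((r for r in self.table if r[0] == ws),
                            key=lambda r: r[4]))
        return rows


def cross_validate_q3(
    dataset: list[tuple[ProteinChain, StructureString, PssmProfile]],
    window_size: int,
    C: float,
    gamma: float,
    n_folds: int = 3,
    seed: int = 0,
) -> float:
    """Mean chain-level cross-validated Q3 for one hyper-parameter point.

    The conformation table is re-estimated from the training folds of each
    split, so no test-label information leaks into the features.
    """
    folds = chain_kfold(len(dataset), n_folds, seed)
    normalized = {
        c.id: p if p.normalized else normalize_profile(p) for c, _, p in dataset
    }
    dataset = [(c, s, normalized[c.id]) for c, s, _ in dataset]
    scores = []
    for k, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train = [dataset[i] for i in range(len(dataset)) if i not in test_set]
        test = [dataset[i] for i in test_idx]
        enc = WindowEncoder(window_size=window_size)
        enc.fit([(c, s) for c, s, _ in train])
        Xtr = enc.transform([c for c, _, _ in train],
                            {c.id: p for c, _, p in train})
        ytr = np.array([st for _, s, _ in train for st in s.states])
        model = OneVsOneStructureSVM(C=C, gamma=gamma).fit(Xtr, ytr)
        Xte = enc.transform([c for c, _, _ in test],
                            {c.id: p for c, _, p in test})
        truth = "".join(s.states for _, s, _ in test)
        pred = "".join(model.predict(Xte))
        scores.append(q3(truth, pred))
    return float(np.mean(scores))


def grid_search(
    dataset: list[tuple[ProteinChain, StructureString, PssmProfile]],
    window_sizes=(7, 9, 11, 13, 15, 17, 19),
    C_values=DEFAULT_C_GRID,
    gamma_values=DEFAULT_GAMMA_GRID,
    n_folds: int = 3,
    seed: int = 0,
    verbose: bool = False,
) -> GridSearchResult:
    """Exhaustive (ws, C, gamma) search scored by mean CV Q3.

    Accuracy ties are resolved toward the smallest window size, then the
    smallest C, then the smallest gamma (iteration order guarantees this
    with a strictly-greater replacement rule).
    """
    best = None
    table = []
    for ws in sorted(window_sizes):
        for C, gamma in itertools.product(sorted(C_values), sorted(gamma_values)):
            acc = cross_validate_q3(dataset, ws, C, gamma, n_folds, seed)
            table.append((ws, feature_dimension(ws), C, gamma, acc))
            if verbose:
                print(f"ws={ws} C={C:g} gamma={gamma:g} Q3={acc:.4f}")
            if best is None or acc > best[3]:
                best = (C, gamma, ws, acc)
    return GridSearchResult(*best, table=table)
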