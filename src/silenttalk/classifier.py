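"""Pairwise linear-SVM bank with majority voting.

For n classes, one soft-margin linear machine is trained per unordered
class pair — n(n-1)/2 machines.  At prediction time every machine casts
one vote and:

* a unique relative majority wins;
* an exactly-two-way tie between classes k and l is settled by the
  "specialist" machine (k, l), the one trained on precisely that pair;
* a three-or-more-way tie is unresolvable and yields the sentinel
  Unknown class (code 0), which downstream evaluation counts as an
  error, never drops.

The base learner is scikit-learn's SVC with a linear kernel; only its
weight vector and bias are kept, so a trained bank is a plain bundle of
hyperplanes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "UNKNOWN_CODE",
    "BinaryClassifier",
    "ClassifierBank",
    "train_binary",
    "train_bank",
    "predict",
    "predict_batch",
    "save_bank",
    "load_bank",
]

#: Sentinel class returned when the vote tally is unresolvable.
UNKNOWN_CODE: int = 0


@dataclass(frozen=True)
class BinaryClassifier:
    """A linear decision boundary between classes i and j (i < j).

    ``decision_value(x) = w . x + b``; positive values vote j,
    non-positive vote i.
    """

    class_pair: tuple[int, int]
    weights: np.ndarray
    bias: float

    def __post_init__(self) -> None:
        i, j = self.class_pair
        if i >= j:
            raise ValueError(f"class_pair must be ordered i < j, got {self.class_pair}")

    def decision_value(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Vote i or j for each row of X."""
        i, j = self.class_pair
        return np.where(self.decision_value(np.atleast_2d(X)) > 0, j, i)


@dataclass(frozen=True)
class ClassifierBank:
    """All n(n-1)/2 pairwise machines for a set of class codes."""

    classes: tuple[int, ...]
    machines: Mapping[tuple[int, int], BinaryClassifier]
    unknown_code: int = UNKNOWN_CODE

    def __post_init__(self) -> None:
        expected = set(combinations(sorted(self.classes), 2))
        if set(self.machines) != expected:
            raise ValueError("bank must hold exactly one machine per class pair")
        if self.unknown_code in self.classes:
            raise ValueError("unknown_code collides with a class code")

    @property
    def n_machines(self) -> int:
        return len(self.machines)

    @property
    def n_features(self) -> int:
        return len(next(iter(self.machines.values())).weights)


def _as_matrix(features) -> np.ndarray:
    """Accept a 2-D array or a sequence of FeatureVector-likes."""
    if hasattr(features, "ndim"):
        return np.atleast_2d(np.asarray(features, dtype=float))
    rows = [f.values if hasattr(f, "values") else np.asarray(f, dtype=float)
            for f in features]
    return np.atleast_2d(np.stack(rows))


def train_binary(features_i, features_j, seed=None, *,
                 class_pair: tuple[int, int] | None = None,
                 C: float = 1.0) -> BinaryClassifier:
    """Fit one soft-margin linear machine separating two classes.

    ``features_i``/``features_j`` are matrices or lists of
    FeatureVector; class codes are taken from the vectors when present,
    else from ``class_pair``.  The fit is deterministic for fixed inputs
    (linear SVC on a fixed QP); ``seed`` is accepted for interface
    symmetry with stochastic learners.
    """
    codes = class_pair
    if codes is None:
        try:
            codes = (features_i[0].class_code, features_j[0].class_code)
        except (AttributeError, TypeError, IndexError):
            codes = (0, 1)
    Xi = _as_matrix(features_i)
    Xj = _as_matrix(features_j)
    if Xi.shape[0] == 0 or Xj.shape[0] == 0:
        raise ValueError("both classes must be non-empty")
    if Xi.shape[1] != Xj.shape[1]:
        raise ValueError(
            f"feature lengths differ: {Xi.shape[1]} vs {Xj.shape[1]}")
    i, j = sorted(codes)
    if codes[0] != i:  # keep data aligned with the ordered pair
        Xi, Xj = Xj, Xi
    X = np.vstack([Xi, Xj])
    if np.allclose(X, X[0]):
        raise ValueError(
            "degenerate data: all feature vectors identical across both classes")
    y = np.concatenate([np.zeros(len(Xi)), np.ones(len(Xj))])
    svm = SVC(kernel="linear", C=C)
    svm.fit(X, y)
    # sklearn orders classes [0, 1]; decision > 0 means class 1 (= j)
    return BinaryClassifier(class_pair=(i, j),
                            weights=svm.coef_.ravel().copy(),
                            bias=float(svm.intercept_[0]))


def train_bank(class_data: Mapping[int, object], seed=None, *,
               C: float = 1.0) -> ClassifierBank:
    """Train one machine per unordered pair of the given classes.

    ``class_data`` maps class code -> feature matrix (or list of
    FeatureVector) for that class.
    """
    classes = tuple(sorted(int(c) for c in class_data))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    machines = {
        (i, j): train_binary(class_data[i], class_data[j],
                             seed, class_pair=(i, j), C=C)
        for i, j in combinations(classes, 2)
    }
    return ClassifierBank(classes=classes, machines=machines)


def tally_votes(bank: ClassifierBank, X: np.ndarray) -> np.ndarray:
    """Vote counts per class: [n_samples x n_classes] in bank class order."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    index = {c: k for k, c in enumerate(bank.classes)}
    counts = np.zeros((X.shape[0], len(bank.classes)), dtype=int)
    for (i, j), m in bank.machines.items():
        votes = m.predict(X)
        counts[votes == i, index[i]] += 1
        counts[votes == j, index[j]] += 1
    return counts


def majority_decision(bank: ClassifierBank, counts: np.ndarray,
                      X: np.ndarray) -> np.ndarray:
    """Apply the majority / specialist-tie-break / Unknown rule."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    classes = np.array(bank.classes)
    out = np.empty(counts.shape[0], dtype=int)
    top = counts.max(axis=1)
    n_top = (counts == top[:, None]).sum(axis=1)
    for r in range(counts.shape[0]):
        tied = classes[counts[r] == top[r]]
        if n_top[r] == 1:
            out[r] = tied[0]
        elif n_top[r] == 2:
            k, l = int(tied[0]), int(tied[1])
            out[r] = int(bank.machines[(k, l)].predict(X[r:r + 1])[0])
        else:
            out[r] = bank.unknown_code
    return out


def predict_batch(bank: ClassifierBank, X: np.ndarray) -> np.ndarray:
    """Classify each row of X; returns class codes (0 = Unknown)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != bank.n_features:
        raise ValueError(
            f"feature length {X.shape[1]} does not match bank "
            f"({bank.n_features})")
    return majority_decision(bank, tally_votes(bank, X), X)


def predict(bank: ClassifierBank, x) -> int:
    """Classify a single feature vector (FeatureVector or 1-D array)."""
    if hasattr(x, "values"):
        x = x.values
    return int(predict_batch(bank, np.atleast_2d(x))[0])


def save_bank(bank: ClassifierBank, path, *,
              feature_fingerprint: str = "") -> None:
    """Serialize a bank to one portable JSON file.

    ``feature_fingerprint`` should identify the feature configuration
    the bank was trained under, so a mismatched featurizer at predict
    time can be caught by the caller.
    """
    payload = {
        "classes": list(bank.classes),
        "unknown_code": bank.unknown_code,
        "feature_fingerprint": feature_fingerprint,
        "machines": [
            {"pair": list(pair), "weights": m.weights.tolist(),
             "bias": m.bias}
            for pair, m in sorted(bank.machines.items())
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_bank(path) -> tuple[ClassifierBank, str]:
    """Load a bank saved by :func:`save_bank`; returns (bank, fingerprint)."""
    with open(path) as fh:
        payload = json.load(fh)
    machines = {
        tuple(m["pair"]): BinaryClassifier(
            class_pair=tuple(m["pair"]),
            weights=np.asarray(m["weights"], dtype=float),
            bias=float(m["bias"]))
        for m in payload["machines"]
    }
    bank = ClassifierBank(classes=tuple(payload["classes"]),
                          machines=machines,
                          unknown_code=int(payload["unknown_code"]))
    return bank, payload.get("feature_fingerprint", "")
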