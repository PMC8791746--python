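"""Monte-Carlo cross-validated evaluation under three time modes.

EEG is nonstationary, so how far apart in time the train and test
material of each class was recorded drives accuracy.  Three dataset
assembly modes make this explicit:

* **long-time** — every class pools all its records (weeks apart);
* **short-time** — all classes come from one record (minutes apart);
* **mixed-time** — each class comes from a *different* record, so the
  record effect itself helps separate the classes.

Evaluation repeats a stratified 70/30 split ``Nr`` times: per round r a
bank is trained on the train split and a confusion matrix ``C_r`` (true
classes x predicted classes + an extra Unknown column) is accumulated on
the test split.  Round accuracy is ``A_r = trace(C_r) / sum(C_r)`` —
Unknowns count in the denominator — and the final figures are the summed
matrix ``C``, the per-round vector ``Mc``, their mean ``A`` and the
population standard deviation ``sigma``.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from typing import Callable, Sequence

import numpy as np

from .classifier import ClassifierBank, UNKNOWN_CODE, predict_batch, train_bank
from .features import FeatureStore
from .synthetic import as_seed_sequence

__all__ = [
    "ALL_RECORDS",
    "ModeSpec",
    "EvaluationResult",
    "assemble_mode_dataset",
    "count_mixed_assignments",
    "confusion_with_unknown",
    "accuracy_from_confusion",
    "monte_carlo_cv",
    "label_independence_benchmark",
    "evaluate_mode",
    "report",
    "plot_confusion",
]

#: Record sentinel for long-time assignments (all records of the word).
ALL_RECORDS = None

_MODES = ("long_time", "short_time", "mixed_time")


@dataclass(frozen=True)
class ModeSpec:
    """Which (word, record) combination defines each class.

    ``class_assignments`` maps each class to a word code and a record
    id: record ``None`` (= ALL_RECORDS) pools the word's instances over
    every record.  Mode constraints: long_time uses ALL for every class;
    short_time one common record; mixed_time pairwise-distinct records.
    """

    mode: str
    class_assignments: tuple[tuple[int, int | None], ...]

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        records = [r for _, r in self.class_assignments]
        if len(self.class_assignments) < 2:
            raise ValueError("need at least 2 class assignments")
        if self.mode == "long_time":
            if any(r is not None for r in records):
                raise ValueError("long_time assignments must all use ALL_RECORDS")
        else:
            if any(r is None for r in records):
                raise ValueError(f"{self.mode} assignments need explicit records")
            if self.mode == "short_time" and len(set(records)) != 1:
                raise ValueError("short_time requires one common record")
            if self.mode == "mixed_time" and len(set(records)) != len(records):
                raise ValueError("mixed_time requires pairwise-distinct records")
        words = [(w, r) for w, r in self.class_assignments]
        if len(set(words)) != len(words):
            raise ValueError("duplicate class assignment")

    def labels(self) -> tuple[int, ...]:
        """Class codes: single-digit for long-time, two-digit otherwise."""
        return tuple(w if r is None else w * 10 + r
                     for w, r in self.class_assignments)


@dataclass(frozen=True)
class EvaluationResult:
    """Accumulated Monte-Carlo evaluation output.

    ``C`` is the summed confusion matrix [n x (n + 1)], last column
    Unknown; ``Mc`` the per-round accuracies; ``A`` their mean and
    ``sigma`` their population standard deviation.
    """

    labels: tuple[int, ...]
    C: np.ndarray
    Mc: np.ndarray
    A: float
    sigma: float

    @property
    def n_iterations(self) -> int:
        return len(self.Mc)

    @property
    def unknown_rate(self) -> float:
        return float(self.C[:, -1].sum() / self.C.sum())

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "C": self.C.tolist(),
            "Mc": self.Mc.tolist(),
            "A": self.A,
            "sigma": self.sigma,
            "n_iterations": self.n_iterations,
            "unknown_rate": self.unknown_rate,
        }


def assemble_mode_dataset(store: FeatureStore, spec: ModeSpec
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Gather (X, y) for a mode's class assignments.

    Labels are the spec's class codes.  Silence instances share their
    part's record id, so all Silence of a part is naturally pooled as
    one record.
    """
    X_parts, y_parts = [], []
    for (word, record), label in zip(spec.class_assignments, spec.labels()):
        mask = store.select(word=word, record=record)
        if not mask.any():
            raise ValueError(f"no instances for word {word}, record {record}")
        X_parts.append(store.X[mask])
        y_parts.append(np.full(int(mask.sum()), label))
    return np.vstack(X_parts), np.concatenate(y_parts)


def count_mixed_assignments(n_records: int, n_classes: int) -> int:
    """Ways to give each class its own record: the falling factorial
    n_records * (n_records - 1) * ... * (n_records - n_classes + 1)."""
    if n_classes > n_records:
        raise ValueError(
            f"cannot place {n_classes} classes on {n_records} distinct records")
    if n_classes < 1 or n_records < 1:
        raise ValueError("counts must be positive")
    out = 1
    for k in range(n_classes):
        out *= n_records - k
    return out


def confusion_with_unknown(y_true: np.ndarray, y_pred: np.ndarray,
                           labels: Sequence[int],
                           unknown_code: int = UNKNOWN_CODE) -> np.ndarray:
    """Confusion counts [n x (n + 1)]; the extra last column collects
    Unknown predictions."""
    labels = list(labels)
    index = {c: k for k, c in enumerate(labels)}
    C = np.zeros((len(labels), len(labels) + 1), dtype=int)
    for t, p in zip(y_true, y_pred):
        col = index[p] if p in index else len(labels)
        C[index[t], col] += 1
    return C


def accuracy_from_confusion(C: np.ndarray) -> float:
    """Correct fraction: diagonal of the square part over all entries
    (Unknown column included in the denominator)."""
    C = np.asarray(C)
    total = C.sum()
    if C.size == 0 or total == 0:
        raise ValueError("empty confusion matrix")
    n = C.shape[0]
    return float(np.trace(C[:, :n]) / total)


def _stratified_split(y: np.ndarray, train_fraction: float,
                      rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random split; train size floors, every class keeps at
    least one sample on each side."""
    train_idx, test_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        if len(idx) < 2:
            raise ValueError(
                f"class {c} has {len(idx)} sample(s); need >= 2 to split")
        idx = rng.permutation(idx)
        n_train = min(max(floor(train_fraction * len(idx)), 1), len(idx) - 1)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def monte_carlo_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_iterations: int = 30,
    train_fraction: float = 0.7,
    seed=None,
    bank_trainer: Callable[..., ClassifierBank] | None = None,
    predictor: Callable[[ClassifierBank, np.ndarray], np.ndarray] = predict_batch,
) -> EvaluationResult:
    """Repeated stratified 70/30 evaluation of the classifier bank.

    A master seed spawns one child seed per round (split and training),
    so any single round can be reproduced in isolation.  ``bank_trainer``
    defaults to :func:`silenttalk.classifier.train_bank`; a stub may be
    injected for testing the arithmetic.
    """
    if n_iterations < 1:
        raise ValueError("need at least one iteration")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    trainer = bank_trainer if bank_trainer is not None else train_bank
    labels = tuple(int(c) for c in np.unique(y))
    ss = as_seed_sequence(seed)
    C_sum = np.zeros((len(labels), len(labels) + 1), dtype=int)
    Mc = np.empty(n_iterations)
    for r, child in enumerate(ss.spawn(n_iterations)):
        rng = np.random.default_rng(child)
        tr, te = _stratified_split(y, train_fraction, rng)
        class_data = {c: X[tr][y[tr] == c] for c in labels}
        bank = trainer(class_data, child)
        y_pred = predictor(bank, X[te])
        Cr = confusion_with_unknown(y[te], y_pred, labels)
        C_sum += Cr
        Mc[r] = accuracy_from_confusion(Cr)
    A = float(Mc.mean())
    sigma = float(np.sqrt(np.mean((A - Mc) ** 2)))
    return EvaluationResult(labels=labels, C=C_sum, Mc=Mc, A=A, sigma=sigma)


def label_independence_benchmark(
    class_codes: Sequence[int],
    n_per_class: int = 40,
    n_iterations: int = 30,
    n_replicates: int = 8,
    n_features: int = 589,
    seed=None,
) -> dict:
    """Chance-level diagnostic for the classifier bank.

    Draws ``n_replicates`` independent datasets of label-independent
    feature vectors (``n_per_class`` per class) and Monte-Carlo
    cross-validates the bank on each.  A sound classifier must recover
    the 1/n chance level; the replicate spread gives an honest standard
    error (single-dataset Monte-Carlo rounds share data and understate
    it).  Returns per-replicate accuracies, their mean, the standard
    error of the mean, and the pooled Unknown rate.
    """
    from .synthetic import generate_label_independent_features

    ss = as_seed_sequence(seed)
    accs, unks = [], []
    for child in ss.spawn(n_replicates):
        data_seed, cv_seed = child.spawn(2)
        X, y = generate_label_independent_features(
            class_codes, n_per_class, n_features=n_features, seed=data_seed)
        res = monte_carlo_cv(X, y, n_iterations=n_iterations, seed=cv_seed)
        accs.append(res.A)
        unks.append(res.unknown_rate)
    accs = np.array(accs)
    sem = float(accs.std(ddof=1) / np.sqrt(len(accs))) if len(accs) > 1 else 0.0
    return {
        "replicate_accuracies": accs,
        "mean_accuracy": float(accs.mean()),
        "sem": sem,
        "unknown_rate": float(np.mean(unks)),
        "chance": 1.0 / len(tuple(class_codes)),
    }


def evaluate_mode(store: FeatureStore, spec: ModeSpec,
                  n_iterations: int = 30, train_fraction: float = 0.7,
                  seed=None) -> EvaluationResult:
    """Assemble a mode's dataset and run the Monte-Carlo evaluation."""
    X, y = assemble_mode_dataset(store, spec)
    return monte_carlo_cv(X, y, n_iterations=n_iterations,
                          train_fraction=train_fraction, seed=seed)


def report(result: EvaluationResult) -> str:
    """Readable summary: accuracy line, row-normalized percentage matrix
    and raw counts."""
    lines = [
        f"classes: {list(result.labels)}  "
        f"({result.n_iterations} Monte-Carlo iterations)",
        f"accuracy: {100 * result.A:.1f} +/- {100 * result.sigma:.1f} %",
        f"unknown rate: {100 * result.unknown_rate:.2f} %",
        "",
        "row-normalized confusion (%):",
    ]
    header = "true\\pred " + " ".join(f"{c:>8}" for c in result.labels) \
        + f" {'Unknown':>8}"
    lines.append(header)
    row_sums = result.C.sum(axis=1, keepdims=True)
    pct = 100 * result.C / np.where(row_sums > 0, row_sums, 1)
    for lab, row in zip(result.labels, pct):
        lines.append(f"{lab:>9} " + " ".join(f"{v:8.1f}" for v in row))
    lines.append("")
    lines.append("raw counts:")
    for lab, row in zip(result.labels, result.C):
        lines.append(f"{lab:>9} " + " ".join(f"{v:8d}" for v in row))
    return "\n".join(lines)


def plot_confusion(result: EvaluationResult, path=None):
    """Heat map of the row-normalized confusion matrix (saved if a path
    is given); returns the matplotlib figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    row_sums = result.C.sum(axis=1, keepdims=True)
    pct = 100 * result.C / np.where(row_sums > 0, row_sums, 1)
    fig, ax = plt.subplots(figsize=(1 + 0.6 * pct.shape[1],
                                    1 + 0.6 * pct.shape[0]))
    im = ax.imshow(pct, cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(pct.shape[1]),
                  [str(c) for c in result.labels] + ["Unk"])
    ax.set_yticks(range(pct.shape[0]), [str(c) for c in result.labels])
    ax.set_xlabel("predicted")
    ax.set_ylabel("true")
    ax.set_title(f"A = {100 * result.A:.1f} +/- {100 * result.sigma:.1f} %")
    for r in range(pct.shape[0]):
        for c in range(pct.shape[1]):
            ax.text(c, r, f"{pct[r, c]:.0f}", ha="center", va="center",
                    color="w" if pct[r, c] < 60 else "k", fontsize=8)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
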