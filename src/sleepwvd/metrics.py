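"""Agreement metrics against technician scoring.

Binary (stage vs rest) confusion matrices with sensitivity, accuracy and
Cohen's kappa, plus the 3-class {WAKE, N3, OTHER} matrix with global
accuracy.  With the binary matrix laid out as

    predicted yes/no (rows) x technician yes/no (columns):  A B / C D,
    N1 = A+C, N2 = B+D, N3 = A+B, N4 = C+D, N = A+B+C+D,

the metrics are

    sensitivity = A / (A + C)
    accuracy    = (A + D) / N
    kappa       = (po - pc) / (1 - pc),
    po = (A + D)/N,  pc = (N1*N3/N + N2*N4/N) / N.

Technician 5-class labels collapse exactly once, here: W -> WAKE,
N3 -> N3, {N1, N2, REM} -> OTHER.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import Hypnogram, PREDICTED_STAGES, TECHNICIAN_STAGES

__all__ = [
    "ConfusionMatrix2",
    "ConfusionMatrixK",
    "map_to_predicted_classes",
    "confusion_counts",
    "sensitivity_accuracy",
    "cohen_kappa",
    "global_accuracy",
    "evaluate_pairs",
]

CLASS_ORDER = ("WAKE", "N3", "OTHER")

_COLLAPSE = {"W": "WAKE", "N1": "OTHER", "N2": "OTHER", "N3": "N3", "REM": "OTHER",
             "WAKE": "WAKE", "OTHER": "OTHER"}


@dataclass(frozen=True)
class ConfusionMatrix2:
    """Binary counts: A=TP, B=FP, C=FN, D=TN (predicted rows x truth cols)."""

    A: int
    B: int
    C: int
    D: int

    def __post_init__(self) -> None:
        if min(self.A, self.B, self.C, self.D) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def N1(self) -> int:  # truth positives
        return self.A + self.C

    @property
    def N2(self) -> int:  # truth negatives
        return self.B + self.D

    @property
    def N3(self) -> int:  # predicted positives
        return self.A + self.B

    @property
    def N4(self) -> int:  # predicted negatives
        return self.C + self.D

    @property
    def N(self) -> int:
        return self.A + self.B + self.C + self.D


@dataclass(frozen=True)
class ConfusionMatrixK:
    """K-class counts, predicted stage by row, technician stage by column."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        k = len(self.classes)
        if c.shape != (k, k) or np.any(c < 0):
            raise ValueError(f"counts must be a non-negative {k}x{k} matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def collapse(self, positive: str) -> ConfusionMatrix2:
        """Binary matrix for one stage vs all the rest."""
        i = self.classes.index(positive)
        c = self.counts
        a = int(c[i, i])
        b = int(c[i].sum() - a)
        cc = int(c[:, i].sum() - a)
        d = int(c.sum() - a - b - cc)
        return ConfusionMatrix2(a, b, cc, d)


def map_to_predicted_classes(h: Hypnogram) -> Hypnogram:
    """Collapse technician labels to {WAKE, N3, OTHER}; idempotent."""
    try:
        labels = tuple(_COLLAPSE[l] for l in h.labels)
    except KeyError as exc:
        raise ValueError(f"unknown stage label {exc.args[0]!r}") from None
    return Hypnogram(labels, PREDICTED_STAGES)


def confusion_counts(
    pred: Hypnogram, truth: Hypnogram, positive: str = "multiclass"
) -> ConfusionMatrix2 | ConfusionMatrixK:
    """Tally predicted vs technician epochs.

    ``positive="multiclass"`` gives the 3-class matrix; naming a stage gives
    the binary one-vs-rest matrix for it.
    """
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} predicted vs {len(truth)} truth epochs")
    p = map_to_predicted_classes(pred).labels
    t = map_to_predicted_classes(truth).labels
    idx = {c: i for i, c in enumerate(CLASS_ORDER)}
    counts = np.zeros((3, 3), dtype=int)
    for pi, ti in zip(p, t):
        counts[idx[pi], idx[ti]] += 1
    full = ConfusionMatrixK(counts)
    if positive == "multiclass":
        return full
    if positive not in CLASS_ORDER:
        raise ValueError(f"positive must be one of {CLASS_ORDER} or 'multiclass'")
    return full.collapse(positive)


def sensitivity_accuracy(m: ConfusionMatrix2) -> tuple[float, float]:
    """(sensitivity, accuracy) as fractions in [0, 1]."""
    if m.N == 0:
        raise ValueError("empty confusion matrix")
    if m.N1 == 0:
        raise ValueError("sensitivity undefined: no positive epochs in truth")
    return m.A / m.N1, (m.A + m.D) / m.N


def cohen_kappa(m: ConfusionMatrix2) -> float:
    """Chance-corrected agreement kappa = (po - pc) / (1 - pc)."""
    if m.N == 0:
        raise ValueError("empty confusion matrix")
    po = (m.A + m.D) / m.N
    pc = (m.N1 * m.N3 / m.N + m.N2 * m.N4 / m.N) / m.N
    if pc >= 1.0:
        raise ValueError("kappa undefined: chance agreement is 1 (degenerate matrix)")
    return (po - pc) / (1 - pc)


def global_accuracy(m: ConfusionMatrixK) -> tuple[float, dict[str, float]]:
    """(overall accuracy, per-class TP rate) for the K-class matrix.

    TP rate of a class is the diagonal count over its technician column
    total (its sensitivity).
    """
    if m.total == 0:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(m.counts)) / m.total
    rates = {}
    for i, c in enumerate(m.classes):
        col = int(m.counts[:, i].sum())
        rates[c] = float(m.counts[i, i]) / col if col else float("nan")
    return acc, rates


def evaluate_pairs(pairs: list[tuple[Hypnogram, Hypnogram]]) -> dict:
    """Pooled evaluation report over (predicted, truth) hypnogram pairs.

    Binary wake and N3 matrices with sensitivity/accuracy/kappa, plus the
    3-class matrix with global accuracy and per-class TP rates.  Percentages
    are reported on the 0-100 scale, rounded to 2 decimals for display.
    """
    if not pairs:
        raise ValueError("no hypnogram pairs to evaluate")
    pooled = np.zeros((3, 3), dtype=int)
    for pred, truth in pairs:
        pooled += confusion_counts(pred, truth).counts
    full = ConfusionMatrixK(pooled)
    report: dict = {"n_epochs": full.total, "classes": list(full.classes)}
    for stage in ("WAKE", "N3"):
        m = full.collapse(stage)
        sens, acc = sensitivity_accuracy(m)
        report[stage.lower()] = {
            "counts": {"A": m.A, "B": m.B, "C": m.C, "D": m.D},
            "sensitivity_pct": round(100 * sens, 2),
            "accuracy_pct": round(100 * acc, 2),
            "kappa": round(cohen_kappa(m), 2),
        }
    acc, rates = global_accuracy(full)
    report["multiclass"] = {
        "counts": full.counts.tolist(),
        "global_accuracy_pct": round(100 * acc, 2),
        "tp_rate_pct": {c: round(100 * r, 2) for c, r in rates.items()},
    }
    return report
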