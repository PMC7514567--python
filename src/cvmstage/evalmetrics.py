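"""Evaluation artifacts: confusion matrix, classification report,
per-class one-vs-rest accuracy, and probability-grid images.

The confusion matrix is the 6x6 count table with rows = true stage and
columns = predicted stage. The report derives, per class j:

    precision_j = cm[j,j] / column-sum_j      (0 when the column is empty)
    recall_j    = cm[j,j] / row-sum_j         (0 when the row is empty)
    f1_j        = 2 P R / (P + R)             (0 when P + R = 0)
    support_j   = row-sum_j

plus overall accuracy = trace / total. Displayed values are rounded
half-away-from-zero to 2 decimals; full precision is kept in the machine
representation. The per-class accuracy of the summary tables is the
one-vs-rest binary accuracy (TP_j + TN_j) / total, a separate quantity
from overall accuracy.
"""

from __future__ import annotations

import dataclasses
import json
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from cvmstage.stages import ALL_STAGES, N_STAGES, StageLabel

STAGE_NAMES = tuple(s.name for s in ALL_STAGES)


class ContractError(ValueError):
    pass


def round2(x: float) -> float:
    """Round half away from zero to 2 decimals (0.675 -> 0.68)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"),
                                                  rounding=ROUND_HALF_UP))


def confusion_matrix(true_stages: Sequence, predicted_stages: Sequence
                     ) -> np.ndarray:
    """6x6 count matrix; rows = true stage CS1..CS6, columns = predicted."""
    t = np.array([int(StageLabel.from_any(s)) for s in true_stages])
    p = np.array([int(StageLabel.from_any(s)) for s in predicted_stages])
    if t.shape != p.shape:
        raise ContractError("label sequences must have equal length")
    if t.size == 0:
        return np.zeros((N_STAGES, N_STAGES), dtype=np.int64)
    return _sk_confusion_matrix(t, p, labels=list(range(1, N_STAGES + 1)))


def _validate_cm(cm: np.ndarray) -> np.ndarray:
    cm = np.asarray(cm)
    if cm.shape != (N_STAGES, N_STAGES) or (cm < 0).any():
        raise ContractError("confusion matrix must be 6x6 with counts >= 0")
    return cm.astype(np.int64)


@dataclasses.dataclass(frozen=True)
class ClassReport:
    """Per-class precision/recall/f1/support and overall accuracy.

    ``precision`` etc. hold full-precision values; :meth:`rounded` and
    :meth:`to_text` give the 2-decimal display form.
    """

    precision: tuple[float, ...]
    recall: tuple[float, ...]
    f1: tuple[float, ...]
    support: tuple[int, ...]
    accuracy: float
    zero_division_hit: bool = False

    def rounded(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for i, name in enumerate(STAGE_NAMES):
            out[name] = {
                "precision": round2(self.precision[i]),
                "recall": round2(self.recall[i]),
                "f1-score": round2(self.f1[i]),
                "support": int(self.support[i]),
            }
        out["accuracy"] = round2(self.accuracy)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"precision": self.precision, "recall": self.recall,
             "f1-score": self.f1, "support": self.support},
            index=list(STAGE_NAMES),
        )

    def to_text(self) -> str:
        lines = [f"{'':6s} {'precision':>9s} {'recall':>7s} "
                 f"{'f1-score':>8s} {'support':>8s}"]
        r = self.rounded()
        for name in STAGE_NAMES:
            row = r[name]
            lines.append(
                f"{name:6s} {row['precision']:9.2f} {row['recall']:7.2f} "
                f"{row['f1-score']:8.2f} {row['support']:8d}")
        lines.append(f"accuracy {self.accuracy:.4f}")
        return "\n".join(lines)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["rounded"] = self.rounded()
        return json.dumps(d, indent=2)


def classification_report(cm: np.ndarray) -> ClassReport:
    """Derive the classification report from a 6x6 confusion matrix."""
    cm = _validate_cm(cm)
    diag = np.diag(cm).astype(float)
    col = cm.sum(axis=0).astype(float)
    row = cm.sum(axis=1).astype(float)
    total = cm.sum()
    zero_hit = False
    precision, recall, f1 = [], [], []
    for j in range(N_STAGES):
        if col[j] > 0:
            p = diag[j] / col[j]
        else:
            p, zero_hit = 0.0, True
        if row[j] > 0:
            r = diag[j] / row[j]
        else:
            r, zero_hit = 0.0, True
        if p + r > 0:
            f = 2 * p * r / (p + r)
        else:
            f, zero_hit = 0.0, True
        precision.append(p)
        recall.append(r)
        f1.append(f)
    accuracy = float(diag.sum() / total) if total > 0 else 0.0
    return ClassReport(
        precision=tuple(precision), recall=tuple(recall), f1=tuple(f1),
        support=tuple(int(s) for s in row), accuracy=accuracy,
        zero_division_hit=zero_hit,
    )


def per_class_accuracy(cm: np.ndarray) -> np.ndarray:
    """One-vs-rest accuracy per class: (TP_j + TN_j) / total.

    TN_j counts samples that are neither true class j nor predicted class j.
    """
    cm = _validate_cm(cm)
    total = cm.sum()
    if total == 0:
        return np.ones(N_STAGES)
    out = np.empty(N_STAGES)
    for j in range(N_STAGES):
        tp = cm[j, j]
        fn = cm[j].sum() - tp
        fp = cm[:, j].sum() - tp
        tn = total - tp - fn - fp
        out[j] = (tp + tn) / total
    return out


@dataclasses.dataclass(frozen=True)
class ProbabilityGrid:
    """Per true class, a 6 x n raster of predicted probabilities.

    Cell (j, i) of ``grids[name]`` is the predicted probability of class
    j+1 for the i-th test image whose true class is ``name`` (manifest
    order); each column sums to 1.
    """

    grids: dict[str, np.ndarray]

    def save_csv(self, directory) -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, g in self.grids.items():
            pd.DataFrame(g, index=list(STAGE_NAMES)).to_csv(
                d / f"probability_grid_{name}.csv")

    def save_png(self, directory) -> None:
        from pathlib import Path

        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for name, g in self.grids.items():
            if g.shape[1] == 0:
                continue
            fig, ax = plt.subplots(figsize=(8, 2))
            ax.imshow(g, aspect="auto", vmin=0, vmax=1, cmap="viridis")
            ax.set_yticks(range(N_STAGES), STAGE_NAMES)
            ax.set_xlabel("test image")
            ax.set_title(f"prediction probabilities, true class {name}")
            fig.tight_layout()
            fig.savefig(d / f"probability_grid_{name}.png", dpi=100)
            plt.close(fig)


def probability_grid(probabilities: np.ndarray, true_stages: Sequence
                     ) -> ProbabilityGrid:
    """Group per-sample probability rows by true class into 6 x n rasters."""
    import warnings

    probs = np.asarray(probabilities, dtype=float)
    stages = [StageLabel.from_any(s) for s in true_stages]
    if probs.ndim != 2 or probs.shape[0] != len(stages) \
            or probs.shape[1] != N_STAGES:
        raise ContractError("need one 6-probability row per sample")
    grids = {}
    for s in ALL_STAGES:
        rows = [probs[i] for i, t in enumerate(stages) if t == s]
        if rows:
            grids[s.name] = np.stack(rows, axis=1)
        else:
            warnings.warn(f"no samples with true class {s.name}")
            grids[s.name] = np.zeros((N_STAGES, 0))
    return ProbabilityGrid(grids)


def save_confusion_csv(cm: np.ndarray, path) -> None:
    pd.DataFrame(_validate_cm(cm), index=list(STAGE_NAMES),
                 columns=list(STAGE_NAMES)).to_csv(path)
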