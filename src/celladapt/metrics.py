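"""Accuracy and macro-F1 for predicted cell-type labels.

Accuracy is the fraction of cells whose predicted label equals the true
one.  Macro-F1 averages per-class F1 (harmonic mean of precision and
recall) uniformly over classes; by default the class set is the classes
present in the truth — the appropriate convention under partial
adaptation, where source-only classes would otherwise zero-pad the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Metrics", "accuracy", "macro_f1", "confusion_matrix", "evaluate_predictions"]


def _as_str_arrays(y_true, y_pred) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray([str(y) for y in y_true])
    y_pred = np.asarray([str(y) for y in y_pred])
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    return y_true, y_pred


def accuracy(y_true, y_pred) -> float:
    """Proportion of correctly predicted cells."""
    y_true, y_pred = _as_str_arrays(y_true, y_pred)
    return float(np.mean(y_true == y_pred))


def confusion_matrix(y_true, y_pred) -> pd.DataFrame:
    """True × predicted counts over the union label set (sorted)."""
    y_true, y_pred = _as_str_arrays(y_true, y_pred)
    labels = sorted(set(y_true) | set(y_pred))
    idx = {l: i for i, l in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        mat[idx[t], idx[p]] += 1
    return pd.DataFrame(mat, index=labels, columns=labels)


def _per_class_prf(y_true: np.ndarray, y_pred: np.ndarray, classes) -> pd.DataFrame:
    rows = []
    for c in classes:
        tp = int(np.sum((y_true == c) & (y_pred == c)))
        fp = int(np.sum((y_true != c) & (y_pred == c)))
        fn = int(np.sum((y_true == c) & (y_pred != c)))
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        rows.append({"class": c, "tp": tp, "fp": fp, "fn": fn,
                     "precision": prec, "recall": rec, "f1": f1})
    return pd.DataFrame(rows).set_index("class")


def macro_f1(y_true, y_pred, class_set: str = "true_only") -> float:
    """Unweighted mean of per-class F1 scores.

    ``class_set``: ``true_only`` (classes present in ``y_true``, default)
    or ``union`` (classes present in either vector; classes with no true
    or predicted occurrence are excluded from the mean).
    """
    y_true, y_pred = _as_str_arrays(y_true, y_pred)
    if class_set == "true_only":
        classes = sorted(set(y_true))
    elif class_set == "union":
        classes = sorted(set(y_true) | set(y_pred))
    else:
        raise ValueError("class_set must be 'true_only' or 'union'")
    table = _per_class_prf(y_true, y_pred, classes)
    active = table[(table.tp + table.fp + table.fn) > 0]
    return float(active.f1.mean())


@dataclass
class Metrics:
    """Bundle of classification metrics for one prediction run."""

    accuracy: float
    macro_f1: float
    per_class: pd.DataFrame
    confusion: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "per_class": self.per_class.reset_index().to_dict(orient="records"),
        }


def evaluate_predictions(y_true, y_pred, class_set: str = "true_only") -> Metrics:
    """Compute accuracy, macro-F1, per-class table and confusion matrix."""
    y_true, y_pred = _as_str_arrays(y_true, y_pred)
    conf = confusion_matrix(y_true, y_pred)
    if class_set == "true_only":
        classes = sorted(set(y_true))
    else:
        classes = sorted(set(y_true) | set(y_pred))
    table = _per_class_prf(y_true, y_pred, classes)
    return Metrics(
        accuracy=accuracy(y_true, y_pred),
        macro_f1=macro_f1(y_true, y_pred, class_set=class_set),
        per_class=table,
        confusion=conf,
    )


def export_embedding(
    latents: np.ndarray,
    domains,
    labels,
    path,
    seed: int = 0,
) -> pd.DataFrame:
    """2-D UMAP of concatenated latents with domain and label columns (CSV)."""
    import umap  # heavy import kept local

    reducer = umap.UMAP(n_components=2, random_state=seed)
    emb = reducer.fit_transform(np.asarray(latents, dtype=float))
    df = pd.DataFrame(
        {"umap1": emb[:, 0], "umap2": emb[:, 1],
         "domain": list(domains), "label": list(labels)}
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df
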