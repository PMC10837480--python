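"""Classification scoring: confusion matrix, precision/sensitivity/F1.

Per class c (one-vs-rest):

    P    = TP / (TP + FP)        (what proportion of detections are correct)
    Sens = TP / (TP + FN)        (what proportion of true items are found)
    F1   = 2 P Sens / (P + Sens) (harmonic mean)

plus class-size-weighted averages across the three classes. Zero
denominators yield NaN with a warning and are excluded (weights
renormalized) from weighted averages — silently zeroing them would bias
method comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import CLASSES, DefectRecord, class_index, coerce_three_class


def confusion(truth, pred) -> np.ndarray:
    """3x3 count matrix; entry (t, p) = items with truth t predicted p.

    Rows/columns follow the canonical class order; 'other' outcomes must be
    coerced upstream (see ``coerce_three_class``).
    """
    truth = list(truth)
    pred = list(pred)
    if len(truth) != len(pred):
        raise ValueError("truth and pred must have equal length")
    mat = np.zeros((3, 3), dtype=int)
    for t, p in zip(truth, pred):
        mat[class_index(t), class_index(p)] += 1
    return mat


def precision_sensitivity_f1(conf: np.ndarray, c: int | str) -> tuple[float, float, float]:
    """(P, Sens, F1) for one class, one-vs-rest; NaN on zero denominators."""
    conf = np.asarray(conf)
    if conf.shape != (3, 3):
        raise ValueError("confusion matrix must be 3x3")
    i = class_index(c) if isinstance(c, str) else int(c)
    tp = conf[i, i]
    fp = conf[:, i].sum() - tp
    fn = conf[i, :].sum() - tp

    def _ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined for class {CLASSES[i]!r} "
                          "(zero denominator)", stacklevel=3)
            return float("nan")
        return num / den

    p = _ratio(tp, tp + fp, "precision")
    s = _ratio(tp, tp + fn, "sensitivity")
    if np.isnan(p) or np.isnan(s) or (p + s) == 0:
        f1 = float("nan")
        if not (np.isnan(p) or np.isnan(s)):
            warnings.warn(f"F1 undefined for class {CLASSES[i]!r}", stacklevel=2)
    else:
        f1 = 2.0 * p * s / (p + s)
    return float(p), float(s), float(f1)


def f1_score(p: float, sens: float) -> float:
    """Harmonic mean of precision and sensitivity."""
    if p + sens == 0:
        return float("nan")
    return 2.0 * p * sens / (p + sens)


def weighted_average(values, sizes) -> float:
    """Class-size-weighted mean, excluding NaN entries with a warning."""
    values = np.asarray(values, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if sizes.sum() <= 0:
        raise ValueError("class sizes must sum to a positive value")
    ok = ~np.isnan(values)
    if not ok.all():
        warnings.warn("NaN metric excluded from weighted average", stacklevel=2)
    if sizes[ok].sum() == 0:
        return float("nan")
    return float(np.sum(values[ok] * sizes[ok]) / sizes[ok].sum())


def accuracy(conf: np.ndarray) -> float:
    """Overall accuracy = trace / n (= class-size-weighted sensitivity)."""
    conf = np.asarray(conf)
    n = conf.sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(conf) / n)


@dataclass
class ClassMetrics:
    """Full scoring of one method against ground truth."""

    confusion: np.ndarray
    per_class: pd.DataFrame  # index = class, columns = P, Sens, F1
    weighted: dict  # P, Sens, F1 weighted by class size
    accuracy: float
    class_sizes: np.ndarray

    def to_table_row(self, method: str) -> pd.DataFrame:
        """One table row: per-class and weighted P/Sens/F1 for a method."""
        cols = {}
        for cls in CLASSES:
            for m in ("P", "Sens", "F1"):
                cols[f"{cls} {m}"] = self.per_class.loc[cls, m]
        for m in ("P", "Sens", "F1"):
            cols[f"Total {m}"] = self.weighted[m]
        return pd.DataFrame(cols, index=[method])


def score(truth, pred) -> ClassMetrics:
    """Score predicted labels against truth; 'other' is mapped to 'none'."""
    truth = [coerce_three_class(t) for t in truth]
    pred = [coerce_three_class(p) for p in pred]
    conf = confusion(truth, pred)
    sizes = conf.sum(axis=1)
    rows = {}
    for cls in CLASSES:
        p, s, f1 = precision_sensitivity_f1(conf, cls)
        rows[cls] = {"P": p, "Sens": s, "F1": f1}
    per_class = pd.DataFrame(rows).T[["P", "Sens", "F1"]]
    weighted = {
        m: weighted_average(per_class[m].to_numpy(), sizes) for m in ("P", "Sens", "F1")
    }
    return ClassMetrics(
        confusion=conf,
        per_class=per_class,
        weighted=weighted,
        accuracy=accuracy(conf),
        class_sizes=sizes,
    )


def match_detections(
    truth: list[DefectRecord],
    pred: list[DefectRecord],
    radius: float,
    box: tuple[float, float] | None = None,
    periodic: bool = False,
) -> tuple[list[str], list[str]]:
    """Pair detections with ground-truth defects by proximity.

    Greedy nearest-pair matching within ``radius`` (per frame). Unmatched
    truth defects count as missed ('none' predicted); unmatched predictions
    count as false detections (truth 'none'). Returns parallel label lists
    suitable for ``score``.
    """
    t_labels: list[str] = []
    p_labels: list[str] = []
    frames = sorted({r.frame for r in truth} | {r.frame for r in pred})
    for f in frames:
        tf = [r for r in truth if r.frame == f]
        pf = [r for r in pred if r.frame == f]
        used_p: set[int] = set()
        pairs = []
        for it, tr in enumerate(tf):
            for ip, pr in enumerate(pf):
                dx = tr.x - pr.x
                dy = tr.y - pr.y
                if periodic and box is not None:
                    dx -= box[0] * np.round(dx / box[0])
                    dy -= box[1] * np.round(dy / box[1])
                d = float(np.hypot(dx, dy))
                if d <= radius:
                    pairs.append((d, it, ip))
        used_t: set[int] = set()
        for d, it, ip in sorted(pairs):
            if it in used_t or ip in used_p:
                continue
            used_t.add(it)
            used_p.add(ip)
            t_labels.append(tf[it].charge)
            p_labels.append(coerce_three_class(pf[ip].charge))
        for it, tr in enumerate(tf):
            if it not in used_t:
                t_labels.append(tr.charge)
                p_labels.append("none")
        for ip, pr in enumerate(pf):
            if ip not in used_p:
                t_labels.append("none")
                p_labels.append(coerce_three_class(pr.charge))
    return t_labels, p_labels
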