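"""Shared label conventions and the defect record container.

The three classification outcomes are ordered (+1/2, none, -1/2) everywhere:
in one-hot label vectors, in classifier output probabilities, and in
confusion-matrix rows/columns. Keeping a single canonical order prevents
label-permutation bugs between the winding-number path and the CNN path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical class order used across the package.
CLASSES: tuple[str, str, str] = ("+1/2", "none", "-1/2")

#: Winding outcomes outside the three classes (e.g. |k| >= 1).
OTHER: str = "other"

_CLASS_INDEX = {c: i for i, c in enumerate(CLASSES)}


def class_index(label: str) -> int:
    """Map a class label to its canonical index; raises on unknown labels."""
    try:
        return _CLASS_INDEX[label]
    except KeyError:
        raise ValueError(f"unknown class label {label!r}; expected one of {CLASSES}")


def coerce_three_class(label: str) -> str:
    """Map 'other' winding outcomes onto 'none' for 3-class comparisons."""
    if label == OTHER:
        return "none"
    class_index(label)
    return label


@dataclass
class DefectRecord:
    """A detected (or planted) defect.

    Attributes
    ----------
    x, y : float
        Core position in frame length units.
    charge : str
        One of ``CLASSES`` or ``"other"`` for out-of-range winding results.
    probabilities : ndarray of shape (3,), optional
        Class probabilities in canonical order (CNN detections only).
    psi : float, optional
        Polarity angle in radians; defined only for +1/2 defects.
    method : str
        Provenance tag: "ground-truth", "winding", "winding-on-lattice", "cnn".
    frame : int
        Frame identifier for multi-frame inputs.
    """

    x: float
    y: float
    charge: str
    probabilities: np.ndarray | None = None
    psi: float | None = None
    method: str = "ground-truth"
    frame: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.charge != OTHER:
            class_index(self.charge)
        if self.psi is not None and self.charge != "+1/2":
            raise ValueError("polarity is defined only for +1/2 defects")
        if self.probabilities is not None:
            p = np.asarray(self.probabilities, dtype=float)
            if p.shape != (3,):
                raise ValueError("probabilities must have shape (3,)")
            if not np.isclose(p.sum(), 1.0, atol=1e-6):
                raise ValueError("probabilities must sum to 1")
            self.probabilities = p
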