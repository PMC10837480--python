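"""End-to-end composition: frame -> director field -> candidates -> labels.

One call per frame; the CLI subcommands are thin wrappers around these
functions, and library users can call them directly.
"""

from __future__ import annotations

import logging

import numpy as np

from .cnn import ClassifierModel, predict
from .config import PipelineConfig
from .detect import BoundaryError, extract_roi, find_low_order_regions
from .fields import CellFrame, build_director_grid, order_parameter_field
from .properties import PolarityUndefinedError, defect_polarity
from .records import CLASSES, DefectRecord
from .winding import classify_on_lattice, classify_roi_winding

log = logging.getLogger(__name__)

METHODS = ("winding", "winding-on-lattice", "cnn")


def detect_frame(
    frame: CellFrame,
    config: PipelineConfig | None = None,
    method: str = "winding",
    model: ClassifierModel | None = None,
    frame_id: int = 0,
) -> list[DefectRecord]:
    """Detect and classify defects in one frame.

    Candidate centers are the centers of mass of contiguous regions with
    S < s_th; each is cropped to a square director ROI and classified by the
    requested method. Candidates classified 'none'/'other' are not reported.
    +1/2 records carry a polarity angle when it is defined.
    """
    cfg = config or PipelineConfig()
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    if method == "cnn" and model is None:
        raise ValueError("method 'cnn' requires a trained model")

    d = frame.cell_diameter
    grid = build_director_grid(
        frame, spacing=cfg.spacing_cells * d, window=cfg.window_cells * d
    )

    if method == "winding-on-lattice":
        records = classify_on_lattice(
            grid, cfg.lattice_spacing_cells * d, tol=cfg.winding_tol
        )
        for r in records:
            r.frame = frame_id
        return records

    order = order_parameter_field(grid, cfg.window_cells * d)
    regions = find_low_order_regions(order, cfg.s_th, cfg.connectivity)

    rois, centers = [], []
    for reg in regions:
        try:
            rois.append(
                extract_roi(
                    grid, reg.centroid,
                    side_points=cfg.roi_side_points,
                    roi_span=cfg.roi_span_cells * d,
                )
            )
            centers.append(reg.centroid)
        except BoundaryError:
            log.warning("candidate at %s skipped: ROI crosses domain boundary",
                        reg.centroid)
    if not rois:
        return []

    if method == "cnn":
        probs, labels = predict(model, rois)
    else:
        labels = [classify_roi_winding(r, tol=cfg.winding_tol) for r in rois]
        probs = [None] * len(rois)

    records = []
    for (cx, cy), label, p in zip(centers, labels, probs):
        if label not in (CLASSES[0], CLASSES[2]):
            continue
        psi = None
        if label == CLASSES[0]:
            try:
                psi = defect_polarity(grid, (cx, cy))
            except PolarityUndefinedError:
                log.warning("polarity undefined for +1/2 at (%.3g, %.3g)", cx, cy)
        records.append(
            DefectRecord(
                x=cx, y=cy, charge=label,
                probabilities=None if p is None else np.asarray(p),
                psi=psi, method=method, frame=frame_id,
            )
        )
    return records


def detect_frames(
    frames: dict[int, CellFrame],
    config: PipelineConfig | None = None,
    method: str = "winding",
    model: ClassifierModel | None = None,
) -> list[DefectRecord]:
    """Run ``detect_frame`` over a frame dictionary."""
    out = []
    for fid, fr in sorted(frames.items()):
        out.extend(detect_frame(fr, config, method, model, frame_id=fid))
    return out
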