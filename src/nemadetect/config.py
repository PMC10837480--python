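"""Resolved pipeline configuration: defaults, YAML round-trip, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class PipelineConfig:
    """Every tunable of the detection pipeline in one place.

    Lengths are in the frame's length units; ``spacing_cells``/
    ``window_cells``/``roi_span_cells`` are expressed in cell diameters
    (estimated as sqrt(box area / n_cells)) and resolved per frame.
    """

    spacing_cells: float = 0.25      # fine-grid step
    window_cells: float = 1.5        # sliding-window side
    s_th: float = 0.15               # low-order threshold on S
    connectivity: int = 8            # region connectivity (4 or 8)
    roi_side_points: int = 9         # ROI nodes per side
    roi_span_cells: float = 6.0      # ROI physical side (5-7 cells)
    winding_tol: float = 0.1         # charge acceptance tolerance
    lattice_spacing_cells: float = 2.0  # on-lattice baseline pitch
    seed: int = 0
    train: dict = field(default_factory=dict)      # TrainConfig overrides
    synthetic: dict = field(default_factory=dict)  # SynthConfig overrides

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def resolved(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        """Stable short hash of the fully resolved configuration."""
        blob = json.dumps(self.resolved(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
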