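"""Readers and writers for frames, defect tables, grids and datasets.

Frames travel as header-bearing delimited text (CSV or TSV) with required
columns ``x, y, theta`` and optional ``vx, vy, frame`` — the format standard
segmentation software exports. Angles are radians; degrees are accepted via a
flag and converted on read. Every writer embeds the resolved configuration
hash and seed as ``#``-prefixed header lines so outputs are traceable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fields import CellFrame, DirectorGrid, OrderField
from .records import DefectRecord
from .synthetic import LabeledDataset

REQUIRED_COLUMNS = ("x", "y", "theta")


class FormatError(ValueError):
    """Malformed input file."""


def _metadata_header(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k} = {v}\n" for k, v in meta.items())


def read_frames(
    path,
    box: tuple[float, float] | None = None,
    periodic: bool = False,
    degrees: bool = False,
) -> dict[int, CellFrame]:
    """Read one or more cell frames from a delimited text file.

    The delimiter is sniffed (comma or whitespace/tab). A ``frame`` column
    splits rows into multiple frames; otherwise everything is frame 0. When
    ``box`` is omitted it is inferred as the ceiling of the coordinate range
    (origin forced to 0) — fine for non-periodic data, but periodic frames
    should state their box explicitly.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if degrees:
        df["theta"] = np.deg2rad(df["theta"])
    if box is None:
        box = (float(np.ceil(df["x"].max())), float(np.ceil(df["y"].max())))
    frames = {}
    groups = df.groupby("frame") if "frame" in df.columns else [(0, df)]
    for fid, sub in groups:
        frames[int(fid)] = CellFrame(
            x=sub["x"].to_numpy(),
            y=sub["y"].to_numpy(),
            theta=sub["theta"].to_numpy(),
            box=box,
            periodic=periodic,
            vx=sub["vx"].to_numpy() if "vx" in sub.columns else None,
            vy=sub["vy"].to_numpy() if "vy" in sub.columns else None,
        )
    return frames


def write_frames(path, frames: dict[int, CellFrame], meta: dict | None = None) -> None:
    """Write frames as CSV with a frame column and ``#`` metadata headers."""
    rows = []
    for fid, fr in sorted(frames.items()):
        d = {"frame": fid, "x": fr.x, "y": fr.y, "theta": fr.theta}
        if fr.vx is not None:
            d["vx"] = fr.vx
            d["vy"] = fr.vy
        rows.append(pd.DataFrame(d))
    df = pd.concat(rows, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_metadata_header(meta))
        df.to_csv(fh, index=False)


def defects_to_table(records: list[DefectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "frame": r.frame, "x": r.x, "y": r.y, "charge": r.charge,
            "psi": r.psi if r.psi is not None else np.nan,
            "method": r.method,
        }
        if r.probabilities is not None:
            row["p_plus"], row["p_none"], row["p_minus"] = r.probabilities
        rows.append(row)
    return pd.DataFrame(rows)


def write_defects(path, records: list[DefectRecord], meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_metadata_header(meta))
        defects_to_table(records).to_csv(fh, index=False)


def read_defects(path) -> list[DefectRecord]:
    df = pd.read_csv(path, comment="#")
    records = []
    for _, row in df.iterrows():
        probs = None
        if "p_plus" in df.columns and not np.isnan(row.get("p_plus", np.nan)):
            probs = np.array([row["p_plus"], row["p_none"], row["p_minus"]])
        psi = row.get("psi", np.nan)
        records.append(
            DefectRecord(
                x=float(row["x"]), y=float(row["y"]), charge=str(row["charge"]),
                psi=None if np.isnan(psi) else float(psi),
                probabilities=probs,
                method=str(row.get("method", "unknown")),
                frame=int(row.get("frame", 0)),
            )
        )
    return records


def write_grid(path, grid: DirectorGrid | OrderField, meta: dict | None = None) -> None:
    """Write a grid as delimited text with origin/spacing metadata headers."""
    values = grid.theta if isinstance(grid, DirectorGrid) else grid.S
    header = {
        "kind": "director" if isinstance(grid, DirectorGrid) else "order",
        "origin_x": grid.origin[0], "origin_y": grid.origin[1],
        "spacing": grid.spacing, "periodic": grid.periodic,
        **(meta or {}),
    }
    with open(path, "w") as fh:
        fh.write(_metadata_header(header))
        np.savetxt(fh, values, fmt="%.8g", delimiter=",")


def read_grid(path) -> DirectorGrid | OrderField:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].partition("=")
            meta[k.strip()] = v.strip()
    values = np.loadtxt(path, comments="#", delimiter=",")
    origin = (float(meta["origin_x"]), float(meta["origin_y"]))
    spacing = float(meta["spacing"])
    periodic = meta.get("periodic", "False") == "True"
    if meta.get("kind") == "order":
        return OrderField(S=values, origin=origin, spacing=spacing,
                          window=float(meta.get("window", spacing)),
                          periodic=periodic)
    return DirectorGrid(theta=values, origin=origin, spacing=spacing,
                        periodic=periodic)


def save_dataset(path, dataset: LabeledDataset) -> None:
    """Labeled ROI stack as an .npz container (a runtime artifact)."""
    arrays = {
        "patches": dataset.patches,
        "labels": dataset.labels,
        "provenance": np.frombuffer(dataset.provenance.encode(), dtype=np.uint8),
    }
    if dataset.kappas is not None:
        arrays["kappas"] = dataset.kappas
    np.savez(path, **arrays)


def load_dataset(path) -> LabeledDataset:
    with np.load(path) as data:
        return LabeledDataset(
            patches=data["patches"],
            labels=data["labels"],
            provenance=bytes(data["provenance"].tobytes()).decode(),
            kappas=data["kappas"] if "kappas" in data else None,
        )


def write_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float) + "\n")
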