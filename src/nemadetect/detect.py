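"""Candidate-defect detection: low-order regions and ROI cropping.

Defects sit where the nematic order parameter S is small, but low order does
not guarantee a defect in tissues whose cells can be nearly isotropic. The
detector therefore only proposes candidates: maximal connected components of
{S < S_th} (default S_th = 0.15), whose centers of mass become the centers of
square director patches (ROIs, default 9x9 nodes spanning about 6 cell
diameters) that a classifier then labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import DirectorGrid, OrderField, ParameterError, reduce_mod_pi


class BoundaryError(ValueError):
    """ROI would cross a non-periodic domain boundary."""


@dataclass
class LowOrderRegion:
    """A connected set of grid nodes with S below threshold."""

    member_nodes: np.ndarray  # (m, 2) array of (j, i) indices
    centroid: tuple[float, float]  # physical (x, y)
    min_S: float

    @property
    def size(self) -> int:
        return int(len(self.member_nodes))


@dataclass
class ROI:
    """A square director patch centered on a candidate defect.

    ``theta_patch[j, i]`` is the director at physical offset
    ``(-span/2 + i*patch_spacing, -span/2 + j*patch_spacing)`` from ``center``
    (y increasing upward, row 0 at the bottom).
    """

    theta_patch: np.ndarray
    center: tuple[float, float]
    patch_spacing: float
    label: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.theta_patch = reduce_mod_pi(np.asarray(self.theta_patch, dtype=float))
        ny, nx = self.theta_patch.shape
        if ny != nx:
            raise ParameterError("ROI patch must be square")

    @property
    def side_points(self) -> int:
        return self.theta_patch.shape[0]

    @property
    def span(self) -> float:
        return self.patch_spacing * (self.side_points - 1)


def _connectivity_structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ParameterError("connectivity must be 4 or 8")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _merge_periodic(labels: np.ndarray, n_labels: int, connectivity: int) -> np.ndarray:
    """Merge component labels that touch across the periodic wrap."""
    uf = _UnionFind(n_labels + 1)
    ny, nx = labels.shape
    right, left = labels[:, -1], labels[:, 0]
    top, bottom = labels[-1, :], labels[0, :]
    pairs = [(right, left), (top, bottom)]
    if connectivity == 8:
        pairs += [
            (right, np.roll(left, -1)), (right, np.roll(left, 1)),
            (top, np.roll(bottom, -1)), (top, np.roll(bottom, 1)),
        ]
    for a, b in pairs:
        for la, lb in zip(a, b):
            if la and lb:
                uf.union(int(la), int(lb))
    remap = np.array([uf.find(l) for l in range(n_labels + 1)])
    return remap[labels]


def _circular_centroid(coords: np.ndarray, extent: float) -> float:
    """Center of mass of positions on a circle of circumference ``extent``."""
    ang = coords * (2 * np.pi / extent)
    c = np.exp(1j * ang).mean()
    if abs(c) < 1e-12:  # degenerate: fall back to plain mean
        return float(coords.mean())
    return float(np.mod(np.angle(c), 2 * np.pi) * extent / (2 * np.pi))


def find_low_order_regions(
    order: OrderField,
    s_th: float = 0.15,
    connectivity: int = 8,
) -> list[LowOrderRegion]:
    """Maximal connected components of nodes with S < s_th.

    Returns one region per component with the center of mass of its member
    node coordinates; the list may be empty. On periodic fields, components
    touching across the wrap are merged and centroids use a circular mean per
    axis, so regions straddling the boundary get correct centers.
    """
    if not (0 <= s_th < 1):
        raise ParameterError("s_th must lie in [0, 1)")
    mask = order.S < s_th
    structure = _connectivity_structure(connectivity)
    labels, n_labels = ndimage.label(mask, structure=structure)
    if n_labels == 0:
        return []
    if order.periodic:
        labels = _merge_periodic(labels, n_labels, connectivity)

    x0, y0 = order.origin
    s = order.spacing
    regions = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        jj, ii = np.nonzero(labels == lab)
        xs = x0 + s * ii
        ys = y0 + s * jj
        if order.periodic and order.box is not None:
            Lx, Ly = order.box
            cx = _circular_centroid(xs, Lx)
            cy = _circular_centroid(ys, Ly)
        else:
            cx, cy = float(xs.mean()), float(ys.mean())
        regions.append(
            LowOrderRegion(
                member_nodes=np.column_stack([jj, ii]),
                centroid=(cx, cy),
                min_S=float(order.S[jj, ii].min()),
            )
        )
    return regions


def extract_roi(
    grid: DirectorGrid,
    center: tuple[float, float],
    side_points: int = 9,
    roi_span: float | None = None,
    source_id: str = "",
) -> ROI:
    """Crop a square director patch centered on ``center``.

    The patch samples ``side_points`` x ``side_points`` directors at spacing
    ``roi_span / (side_points - 1)`` by nearest-grid-node lookup (the ROI grid
    is a subset of the fine grid, no re-interpolation). Periodic grids wrap;
    otherwise a patch crossing the boundary raises ``BoundaryError`` and the
    caller skips the candidate.

    ``roi_span`` defaults to one ROI step per 3 fine-grid steps, which under
    the default grid spacing of 0.25 cell diameters gives the target span of
    6 cell diameters; callers that know the frame should pass it explicitly.
    """
    if side_points < 3 or side_points % 2 == 0:
        raise ParameterError("side_points must be odd and >= 3")
    if roi_span is None:
        roi_span = (side_points - 1) * 3 * grid.spacing
    if roi_span <= 0:
        raise ParameterError("roi_span must be positive")

    cx, cy = center
    offsets = np.linspace(-roi_span / 2.0, roi_span / 2.0, side_points)
    xs = cx + offsets
    ys = cy + offsets
    ny, nx = grid.theta.shape
    i_idx = np.round((xs - grid.origin[0]) / grid.spacing).astype(int)
    j_idx = np.round((ys - grid.origin[1]) / grid.spacing).astype(int)
    if grid.periodic:
        i_idx %= nx
        j_idx %= ny
    else:
        if (i_idx < 0).any() or (i_idx >= nx).any() or (j_idx < 0).any() or (
            j_idx >= ny
        ).any():
            raise BoundaryError(
                f"ROI at ({cx:.3g}, {cy:.3g}) with span {roi_span:.3g} exits the domain"
            )
    patch = grid.theta[np.ix_(j_idx, i_idx)]
    return ROI(
        theta_patch=patch,
        center=(float(cx), float(cy)),
        patch_spacing=float(roi_span / (side_points - 1)),
        source_id=source_id,
    )
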