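"""Defect polarity and ensemble-averaged fields around detected defects.

A +1/2 defect has a single symmetry axis (the comet axis). Its orientation is
obtained from spatial derivatives of the nematic tensor,

    p = (dQxx/dx + dQxy/dy,  dQxy/dx - dQxx/dy),   psi = atan2(py, px),

evaluated by centered finite differences and averaged over a small disk of
nodes around the core. For the ideal field theta = phi/2 + theta_0 this gives
psi = 2*theta_0; rigidly rotating the field by alpha rotates psi by alpha.

Averaging fields around defects in the defect-aligned frame (rotate each
window by -psi so all polarities point along +x, resample on a common grid,
average element-wise) reveals mean-field structure — e.g. the flow pattern
around +1/2 defects — from far fewer defects than unaligned statistics would
need. A normalized single-point correlation compares two averaged fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import griddata

from .fields import CellFrame, DirectorGrid, ParameterError
from .records import DefectRecord


class PolarityUndefinedError(ValueError):
    """The polarity vector vanished (e.g. uniform field or -1/2 core)."""


@dataclass
class VectorField:
    """A vector field sampled on a regular grid (same layout as DirectorGrid)."""

    vx: np.ndarray
    vy: np.ndarray
    origin: tuple[float, float]
    spacing: float
    periodic: bool = False
    box: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        if self.vx.shape != self.vy.shape or self.vx.ndim != 2:
            raise ParameterError("vx, vy must be identically shaped 2D arrays")


@dataclass
class AverageField:
    """Element-wise mean vector field in the defect-aligned frame."""

    vx: np.ndarray
    vy: np.ndarray
    spacing: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ParameterError("ensemble size must be >= 1")


def interpolate_cell_velocities(
    frame: CellFrame,
    grid: DirectorGrid,
) -> VectorField:
    """Per-cell velocities interpolated to the director grid.

    Uses the same scheme as the director interpolation: linear with
    nearest-neighbour fill (ghost replication for periodic frames).
    """
    if frame.vx is None or frame.vy is None:
        raise ParameterError("frame has no velocities")
    px, py = frame.x, frame.y
    vals = np.column_stack([frame.vx, frame.vy])
    if frame.periodic:
        Lx, Ly = frame.box
        margin = max(6 * grid.spacing, 2 * frame.cell_diameter)
        ax, ay, av = [px], [py], [vals]
        for dx in (-Lx, 0.0, Lx):
            for dy in (-Ly, 0.0, Ly):
                if dx == 0.0 and dy == 0.0:
                    continue
                gx, gy = px + dx, py + dy
                keep = ((gx > -margin) & (gx < Lx + margin)
                        & (gy > -margin) & (gy < Ly + margin))
                ax.append(gx[keep])
                ay.append(gy[keep])
                av.append(vals[keep])
        px, py = np.concatenate(ax), np.concatenate(ay)
        vals = np.concatenate(av)
    X, Y = grid.node_coords()
    interp = griddata(np.column_stack([px, py]), vals, (X, Y), method="linear")
    nan = np.isnan(interp[..., 0])
    if nan.any():
        interp[nan] = griddata(
            np.column_stack([px, py]), vals, (X[nan], Y[nan]), method="nearest"
        )
    return VectorField(
        vx=interp[..., 0], vy=interp[..., 1],
        origin=grid.origin, spacing=grid.spacing,
        periodic=grid.periodic, box=grid.box,
    )


def defect_polarity(
    grid: DirectorGrid,
    core: tuple[float, float],
    radius_nodes: int = 1,
    tol: float = 1e-8,
) -> float:
    """Polarity angle psi of a +1/2 defect at ``core``.

    p = div Q evaluated from the director grid (Qxx = cos 2theta,
    Qxy = sin 2theta) by centered differences, averaged over the
    (2*radius_nodes+1)^2 node block around the core. Raises
    ``PolarityUndefinedError`` when |p| < tol (uniform fields, -1/2 cores).
    """
    qxx = np.cos(2.0 * grid.theta)
    qxy = np.sin(2.0 * grid.theta)
    s = grid.spacing
    if grid.periodic:
        def ddx(a):
            return (np.roll(a, -1, axis=1) - np.roll(a, 1, axis=1)) / (2 * s)

        def ddy(a):
            return (np.roll(a, -1, axis=0) - np.roll(a, 1, axis=0)) / (2 * s)
    else:
        def ddx(a):
            return np.gradient(a, s, axis=1)

        def ddy(a):
            return np.gradient(a, s, axis=0)

    px = ddx(qxx) + ddy(qxy)
    py = ddx(qxy) - ddy(qxx)
    j0, i0 = grid.nearest_index(*core)
    ny, nx = grid.theta.shape
    r = radius_nodes
    jj, ii = np.meshgrid(np.arange(j0 - r, j0 + r + 1),
                         np.arange(i0 - r, i0 + r + 1), indexing="ij")
    if grid.periodic:
        jj %= ny
        ii %= nx
    else:
        jj = np.clip(jj, 0, ny - 1)
        ii = np.clip(ii, 0, nx - 1)
    mx = float(px[jj, ii].mean())
    my = float(py[jj, ii].mean())
    if np.hypot(mx, my) < tol:
        raise PolarityUndefinedError(
            f"polarity undefined at ({core[0]:.3g}, {core[1]:.3g}): |p| < {tol}"
        )
    return float(np.mod(np.arctan2(my, mx), 2.0 * np.pi))


def _sample_bilinear(field: VectorField, x: np.ndarray, y: np.ndarray):
    """Bilinear sample of (vx, vy) at world coordinates (grid-wrap if periodic)."""
    ci = (x - field.origin[0]) / field.spacing
    cj = (y - field.origin[1]) / field.spacing
    mode = "grid-wrap" if field.periodic else "nearest"
    coords = np.stack([cj.ravel(), ci.ravel()])
    vx = ndimage.map_coordinates(field.vx, coords, order=1, mode=mode)
    vy = ndimage.map_coordinates(field.vy, coords, order=1, mode=mode)
    return vx.reshape(x.shape), vy.reshape(x.shape)


def average_field_around_defects(
    defects: list[DefectRecord],
    fields: list[VectorField] | VectorField,
    half_width: float,
    side_points: int = 17,
    n_max: int | None = None,
) -> AverageField:
    """Oriented ensemble average of a vector field around +1/2 defects.

    For each defect the window of physical half-width ``half_width`` is
    rotated by its polarity psi (so the sampling grid follows the defect) and
    the sampled vectors are rotated by -psi, aligning every polarity with +x;
    the aligned windows are then averaged element-wise over the first
    ``min(n, n_max)`` defects.

    ``fields`` is either one field shared by all defects or a list parallel
    to ``defects``. Windows crossing a non-periodic boundary are skipped with
    a warning.
    """
    if not defects:
        raise ParameterError("empty defect list")
    single = isinstance(fields, VectorField)
    if not single and len(fields) != len(defects):
        raise ParameterError("need one field per defect (or a single shared field)")
    use = defects if n_max is None else defects[:n_max]

    ax = np.linspace(-half_width, half_width, side_points)
    XI, ETA = np.meshgrid(ax, ax)
    acc_x = np.zeros_like(XI)
    acc_y = np.zeros_like(XI)
    n_used = 0
    import warnings

    for k, d in enumerate(use):
        if d.charge != "+1/2" or d.psi is None:
            raise ParameterError("oriented averaging needs +1/2 defects with psi")
        field = fields if single else fields[k]
        c, s = np.cos(d.psi), np.sin(d.psi)
        wx = d.x + c * XI - s * ETA
        wy = d.y + s * XI + c * ETA
        if not field.periodic:
            ny, nx = field.vx.shape
            x_max = field.origin[0] + field.spacing * (nx - 1)
            y_max = field.origin[1] + field.spacing * (ny - 1)
            if (wx.min() < field.origin[0] or wx.max() > x_max
                    or wy.min() < field.origin[1] or wy.max() > y_max):
                warnings.warn("window crosses non-periodic boundary; defect skipped",
                              stacklevel=2)
                continue
        svx, svy = _sample_bilinear(field, wx, wy)
        acc_x += c * svx + s * svy     # rotate vectors by -psi
        acc_y += -s * svx + c * svy
        n_used += 1
    if n_used == 0:
        raise ParameterError("no usable defects (all windows skipped)")
    return AverageField(
        vx=acc_x / n_used, vy=acc_y / n_used,
        spacing=float(ax[1] - ax[0]), n=n_used,
    )


def average_director_around_defects(
    defects: list[DefectRecord],
    grids: list[DirectorGrid] | DirectorGrid,
    half_width: float,
    side_points: int = 17,
    n_max: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Oriented ensemble average of the director field around +1/2 defects.

    Works on the nematic tensor components (cos 2theta, sin 2theta), which
    rotate by -2*psi in the aligned frame, then returns the mean director
    angles theta in [0, pi), the local order of the average (magnitude of the
    mean double-angle vector) and the ensemble size.
    """
    single = isinstance(grids, DirectorGrid)
    glist = [grids] * len(defects) if single else list(grids)
    qfields = []
    for g in glist:
        qfields.append(
            VectorField(
                vx=np.cos(2 * g.theta), vy=np.sin(2 * g.theta),
                origin=g.origin, spacing=g.spacing,
                periodic=g.periodic, box=g.box,
            )
        )
    if not defects:
        raise ParameterError("empty defect list")
    use = list(range(len(defects)))[: n_max if n_max is not None else len(defects)]
    ax = np.linspace(-half_width, half_width, side_points)
    XI, ETA = np.meshgrid(ax, ax)
    acc_c = np.zeros_like(XI)
    acc_s = np.zeros_like(XI)
    n_used = 0
    for k in use:
        d = defects[k]
        if d.charge != "+1/2" or d.psi is None:
            raise ParameterError("oriented averaging needs +1/2 defects with psi")
        f = qfields[k]
        c, s = np.cos(d.psi), np.sin(d.psi)
        wx = d.x + c * XI - s * ETA
        wy = d.y + s * XI + c * ETA
        qc, qs = _sample_bilinear(f, wx, wy)
        c2, s2 = np.cos(2 * d.psi), np.sin(2 * d.psi)
        acc_c += c2 * qc + s2 * qs     # rotate Q by -psi
        acc_s += -s2 * qc + c2 * qs
        n_used += 1
    theta = np.mod(0.5 * np.arctan2(acc_s / n_used, acc_c / n_used), np.pi)
    order = np.hypot(acc_c / n_used, acc_s / n_used)
    return theta, order, n_used


def field_correlation(a: AverageField, b: AverageField) -> float:
    """Normalized single-point correlation <A.B> / (rms|A| rms|B|) in [-1, 1]."""
    if a.vx.shape != b.vx.shape:
        raise ParameterError("averaged fields must share a grid shape")
    num = float(np.mean(a.vx * b.vx + a.vy * b.vy))
    ra = float(np.sqrt(np.mean(a.vx**2 + a.vy**2)))
    rb = float(np.sqrt(np.mean(b.vx**2 + b.vy**2)))
    if ra == 0.0 or rb == 0.0:
        raise ParameterError("correlation undefined for a zero field")
    return num / (ra * rb)
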