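"""Director-field construction from scattered cell orientations.

Cells segmented from a monolayer image come as centroids plus the orientation
of each cell's long axis, an angle defined only modulo pi (head-tail
symmetry). This module interpolates those scattered nematic orientations to a
fine regular grid, smooths them with a sliding window, and computes the scalar
nematic order parameter

    S = largest eigenvalue of Q,   Q_mn = <2 u_m u_n - delta_mn>,

with u = (cos theta, sin theta) and <.> a boxcar average over the window. In
2D the traceless symmetric Q has eigenvalues +-sqrt(Qxx^2 + Qxy^2), so S is
computed in closed form. All nematic averaging is done on the double-angle
components (cos 2theta, sin 2theta); averaging raw angles is wrong across the
pi wrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import griddata


class InvalidFrameError(ValueError):
    """Raised when a cell frame cannot support field construction."""


class ParameterError(ValueError):
    """Raised for invalid grid/window parameters."""


def reduce_mod_pi(theta: np.ndarray | float) -> np.ndarray | float:
    """Reduce director angles into [0, pi)."""
    return np.mod(theta, np.pi)


@dataclass
class CellFrame:
    """One snapshot of a confluent layer: centroids, orientations, velocities.

    Parameters
    ----------
    x, y : array of float
        Cell centroid coordinates (length units).
    theta : array of float
        Long-axis orientations in radians; reduced mod pi on construction.
    box : (Lx, Ly)
        Domain extents, origin at (0, 0), y increasing upward.
    periodic : bool
        Whether the domain wraps (torus). Periodic frames require all
        centroids inside [0, Lx) x [0, Ly).
    vx, vy : array of float, optional
        Per-cell velocities for defect-property averaging.
    """

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    box: tuple[float, float]
    periodic: bool = False
    vx: np.ndarray | None = None
    vy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.theta = reduce_mod_pi(np.asarray(self.theta, dtype=float))
        if self.x.shape != self.y.shape or self.x.shape != self.theta.shape:
            raise InvalidFrameError("x, y, theta must have identical shapes")
        if self.n_cells < 3:
            raise InvalidFrameError(
                f"need at least 3 cells for interpolation, got {self.n_cells}"
            )
        Lx, Ly = self.box
        if Lx <= 0 or Ly <= 0:
            raise InvalidFrameError("box extents must be positive")
        if self.periodic:
            if (self.x < 0).any() or (self.x >= Lx).any() or (self.y < 0).any() or (
                self.y >= Ly
            ).any():
                raise InvalidFrameError(
                    "periodic frames require centroids inside [0,Lx)x[0,Ly)"
                )
        for v in (self.vx, self.vy):
            if v is not None and np.asarray(v).shape != self.x.shape:
                raise InvalidFrameError("velocity arrays must match centroid shape")

    @property
    def n_cells(self) -> int:
        return int(self.x.size)

    @property
    def cell_diameter(self) -> float:
        """Typical cell size, estimated as sqrt(box area / n_cells)."""
        Lx, Ly = self.box
        return float(np.sqrt(Lx * Ly / self.n_cells))


@dataclass
class DirectorGrid:
    """Regular grid of director angles theta[j, i] at (x0 + i*s, y0 + j*s).

    Grids built from scattered cell data also carry the raw (interpolated,
    pre-smoothing) double-angle components ``raw_c2``/``raw_s2``; the order
    parameter is the magnitude of their window average, so that S measures
    the alignment of the underlying orientations, not of the smoothed field.
    Grids constructed directly from an analytic angle array leave them unset
    and theta itself is the raw field.
    """

    theta: np.ndarray
    origin: tuple[float, float]
    spacing: float
    periodic: bool = False
    box: tuple[float, float] | None = None
    raw_c2: np.ndarray | None = None
    raw_s2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta = reduce_mod_pi(np.asarray(self.theta, dtype=float))
        if self.theta.ndim != 2:
            raise ParameterError("theta must be a 2D array")
        if self.spacing <= 0:
            raise ParameterError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.theta.shape

    def node_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of all grid nodes, same shape as theta."""
        ny, nx = self.theta.shape
        x = self.origin[0] + self.spacing * np.arange(nx)
        y = self.origin[1] + self.spacing * np.arange(ny)
        return np.meshgrid(x, y)

    def nearest_index(self, x: float, y: float) -> tuple[int, int]:
        """(j, i) index of the node nearest to (x, y); wraps when periodic."""
        ny, nx = self.theta.shape
        i = int(round((x - self.origin[0]) / self.spacing))
        j = int(round((y - self.origin[1]) / self.spacing))
        if self.periodic:
            return j % ny, i % nx
        if not (0 <= i < nx and 0 <= j < ny):
            raise ParameterError(f"point ({x}, {y}) outside grid")
        return j, i


@dataclass
class OrderField:
    """Scalar nematic order parameter S on the same grid as its director field."""

    S: np.ndarray
    origin: tuple[float, float]
    spacing: float
    window: float
    periodic: bool = False
    box: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if ((self.S < -1e-9) | (self.S > 1 + 1e-9)).any():
            raise ParameterError("S must lie in [0, 1]")
        self.S = np.clip(self.S, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.S.shape


def nematic_order(thetas: np.ndarray) -> float:
    """Scalar order parameter of a set of orientations.

    S = sqrt(<cos 2theta>^2 + <sin 2theta>^2): 1 for perfect alignment, 0
    for a balanced orthogonal (or isotropic) mixture.
    """
    thetas = np.asarray(thetas, dtype=float)
    if thetas.size == 0:
        raise ParameterError("empty orientation set")
    return float(np.hypot(np.mean(np.cos(2 * thetas)), np.mean(np.sin(2 * thetas))))


def _window_size(window: float, spacing: float) -> int:
    """Boxcar size in grid nodes: odd, at least 1."""
    if window < spacing:
        raise ParameterError("window must be at least one grid spacing")
    half = int(np.floor(window / (2.0 * spacing)))
    return 2 * half + 1


def _grid_axes(frame: CellFrame, spacing: float):
    """Grid node positions covering the frame box.

    Periodic boxes get nodes at i*L/n (no duplicated wrap node); the spacing
    is adjusted to divide the box exactly so wrap-mode filtering is uniform.
    """
    Lx, Ly = frame.box
    if frame.periodic:
        nx = max(4, int(round(Lx / spacing)))
        ny = max(4, int(round(Ly / spacing)))
        sx, sy = Lx / nx, Ly / ny
        if abs(sx - sy) > 1e-9 * max(sx, sy):
            raise ParameterError(
                "periodic grids need a spacing commensurate with both box extents"
            )
        return np.arange(nx) * sx, np.arange(ny) * sy, sx
    nx = int(np.floor(Lx / spacing)) + 1
    ny = int(np.floor(Ly / spacing)) + 1
    return np.arange(nx) * spacing, np.arange(ny) * spacing, spacing


def build_director_grid(
    frame: CellFrame,
    spacing: float | None = None,
    window: float | None = None,
) -> DirectorGrid:
    """Interpolate scattered cell orientations to a fine smoothed grid.

    Interpolation is linear on the double-angle components with
    nearest-neighbour fill outside the convex hull (non-periodic) or ghost-cell
    replication (periodic); smoothing is a square boxcar of side ``window``.

    Parameters
    ----------
    spacing : float, optional
        Grid step; default 0.25 cell diameters ("fine grid").
    window : float, optional
        Side of the square sliding window; default 1.5 cell diameters.
    """
    d = frame.cell_diameter
    if spacing is None:
        spacing = 0.25 * d
    if window is None:
        window = 1.5 * d
    if spacing <= 0:
        raise ParameterError("spacing must be positive")
    if window < spacing:
        raise ParameterError("window must be >= spacing")

    xs, ys, spacing = _grid_axes(frame, spacing)
    X, Y = np.meshgrid(xs, ys)

    px, py, theta = frame.x, frame.y, frame.theta
    if frame.periodic:
        Lx, Ly = frame.box
        margin = max(window, 4 * spacing, 2 * d)
        sx, sy, st = [px], [py], [theta]
        for dx in (-Lx, 0.0, Lx):
            for dy in (-Ly, 0.0, Ly):
                if dx == 0.0 and dy == 0.0:
                    continue
                gx, gy = px + dx, py + dy
                keep = (
                    (gx > -margin) & (gx < Lx + margin)
                    & (gy > -margin) & (gy < Ly + margin)
                )
                sx.append(gx[keep])
                sy.append(gy[keep])
                st.append(theta[keep])
        px = np.concatenate(sx)
        py = np.concatenate(sy)
        theta = np.concatenate(st)

    pts = np.column_stack([px, py])
    vals = np.column_stack([np.cos(2 * theta), np.sin(2 * theta)])
    interp = griddata(pts, vals, (X, Y), method="linear")
    nan = np.isnan(interp[..., 0])
    if nan.any():
        fill = griddata(pts, vals, (X[nan], Y[nan]), method="nearest")
        interp[nan] = fill
    c2, s2 = interp[..., 0], interp[..., 1]

    size = _window_size(window, spacing)
    mode = "wrap" if frame.periodic else "nearest"
    c2s = ndimage.uniform_filter(c2, size=size, mode=mode)
    s2s = ndimage.uniform_filter(s2, size=size, mode=mode)

    theta_grid = 0.5 * np.arctan2(s2s, c2s)
    return DirectorGrid(
        theta=theta_grid,
        origin=(float(xs[0]), float(ys[0])),
        spacing=float(spacing),
        periodic=frame.periodic,
        box=frame.box,
        raw_c2=c2,
        raw_s2=s2,
    )


def order_parameter_field(grid: DirectorGrid, window: float) -> OrderField:
    """Scalar order parameter S at every grid node.

    Over the sliding window, Qxx = <cos 2theta>, Qxy = <sin 2theta> and
    S = sqrt(Qxx^2 + Qxy^2) — the largest eigenvalue of the 2D traceless
    symmetric nematic tensor, exactly and branch-free. The average is taken
    over the raw (pre-smoothing) orientations when the grid carries them, so
    that S reflects the alignment of the cells, not of the smoothed field;
    it is then the magnitude of the same windowed Q whose direction is the
    smoothed director.
    """
    size = _window_size(window, grid.spacing)
    mode = "wrap" if grid.periodic else "nearest"
    if grid.raw_c2 is not None and grid.raw_s2 is not None:
        base_c2, base_s2 = grid.raw_c2, grid.raw_s2
    else:
        base_c2 = np.cos(2 * grid.theta)
        base_s2 = np.sin(2 * grid.theta)
    c2 = ndimage.uniform_filter(base_c2, size=size, mode=mode)
    s2 = ndimage.uniform_filter(base_s2, size=size, mode=mode)
    S = np.clip(np.hypot(c2, s2), 0.0, 1.0)
    return OrderField(
        S=S,
        origin=grid.origin,
        spacing=grid.spacing,
        window=window,
        periodic=grid.periodic,
        box=grid.box,
    )
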