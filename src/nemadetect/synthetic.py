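"""Seeded synthetic tissue frames and labeled ROI datasets with known truth.

Real training data for the defect classifier comes from simulations of a
confluent layer (an active vertex model) that are expensive and whose labels
must be assigned by eye. This module replaces that source with an analytic
generator: cell centroids on a jittered triangular lattice, orientations
drawn from the ideal multi-defect director field

    theta(r) = sum_j k_j * phi_j(r) + theta_0   (mod pi),

with phi_j the polar angle around core j, plus angular noise applied in
double-angle space with von Mises concentration kappa (kappa = 0 is an
isotropic director, kappa -> infinity is noise-free). Planted cores, charges
and polarities are the exact ground truth, so every downstream component can
be scored without manual labels.

The generator makes no claim of vertex-model mechanics or hydrodynamic
fidelity: it plants recoverable patterns, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .detect import ROI
from .fields import CellFrame, reduce_mod_pi
from .records import CLASSES, DefectRecord, class_index


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


class SingularPointError(ValueError):
    """Field evaluated exactly at a defect core."""


@dataclass(frozen=True)
class Defect:
    """A planted defect: core position, charge (+-1/2) and phase offset."""

    x: float
    y: float
    charge: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if abs(abs(self.charge) - 0.5) > 1e-12:
            raise ConfigError("planted charges must be +1/2 or -1/2")

    @property
    def label(self) -> str:
        return CLASSES[0] if self.charge > 0 else CLASSES[2]

    @property
    def polarity(self) -> float:
        """Polarity of an isolated +1/2 core in the plane.

        For theta = phi/2 + theta_0 the divergence-of-Q polarity vector
        points along psi = 2*theta_0. With other cores present (or on a
        torus) the local phase shifts, so ``true_polarity`` computes the
        exact value from the generated field instead.
        """
        return float(np.mod(2.0 * self.phase, 2.0 * np.pi))


@dataclass
class SynthConfig:
    """Conditions for one synthetic frame.

    Defaults describe a moderately noisy monolayer of ~900 cells in a
    periodic 30x30 box (cell diameter 1), matching the regime in which the
    detection pipeline is meant to operate.
    """

    box: tuple[float, float] = (30.0, 30.0)
    n_cells: int = 900
    defects: list[Defect] = dc_field(default_factory=list)
    kappa: float | None = 3.0  # None = noise-free; 0 = isotropic
    jitter: float = 0.3  # fraction of the lattice constant
    v0: float = 1.0
    sigma_v: float = 0.0
    flow_length: float = 2.0
    periodic: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kappa is not None and self.kappa < 0:
            raise ConfigError("kappa must be >= 0")
        if self.n_cells < 3:
            raise ConfigError("need at least 3 cells")
        if self.periodic and self.defects:
            total = sum(d.charge for d in self.defects)
            if abs(total) > 1e-9:
                raise ConfigError(
                    "periodic frames require total topological charge 0"
                )
        d_cell = float(np.sqrt(self.box[0] * self.box[1] / self.n_cells))
        for a in range(len(self.defects)):
            for b in range(a + 1, len(self.defects)):
                da, db = self.defects[a], self.defects[b]
                dx, dy = da.x - db.x, da.y - db.y
                if self.periodic:
                    dx -= self.box[0] * np.round(dx / self.box[0])
                    dy -= self.box[1] * np.round(dy / self.box[1])
                if np.hypot(dx, dy) < 3.0 * d_cell:
                    raise ConfigError("defect cores closer than 3 cell diameters")


def _displacements(
    px: np.ndarray, py: np.ndarray, core: tuple[float, float],
    box: tuple[float, float] | None, periodic: bool,
) -> tuple[np.ndarray, np.ndarray]:
    dx = px - core[0]
    dy = py - core[1]
    if periodic and box is not None:
        dx = dx - box[0] * np.round(dx / box[0])
        dy = dy - box[1] * np.round(dy / box[1])
    return dx, dy


def _theta1(v: np.ndarray, q: float, n_terms: int = 12) -> np.ndarray:
    """Jacobi theta function theta_1(v, q) for complex v (series form)."""
    total = np.zeros(np.shape(v), dtype=complex)
    for n in range(n_terms):
        total = total + (-1.0) ** n * q ** ((n + 0.5) ** 2) * np.sin((2 * n + 1) * v)
    return 2.0 * total


def _torus_defect_angle(
    px: np.ndarray, py: np.ndarray, defects: list[Defect],
    box: tuple[float, float], theta0: float,
) -> np.ndarray:
    """Exactly periodic multi-defect director field on a torus.

    The double angle u = 2*theta is taken as the argument of a product of
    Jacobi theta_1 factors, one simple zero per core, so u winds by
    2*pi*(2k_j) around core j. The product is quasi-periodic: translating by
    Ly multiplies it by a constant phase exp(i*2*pi*sum_j 2k_j x_j / Lx); a
    uniform tilt gamma*y (chosen as the smallest value cancelling that phase
    modulo 2*pi) restores strict periodicity of the director mod pi. Total
    charge must vanish, which SynthConfig enforces for periodic frames.
    """
    Lx, Ly = box
    q = float(np.exp(-np.pi * Ly / Lx))
    u = np.zeros(np.broadcast(px, py).shape, dtype=float)
    phase_sum = float(theta0)
    wx_sum = 0.0
    for d in defects:
        w = int(round(2 * d.charge))
        z = (px - d.x) + 1j * (py - d.y)
        val = _theta1(np.pi * z / Lx, q)
        if np.any(val == 0.0):
            raise SingularPointError("field evaluated exactly at a defect core")
        u = u + w * np.angle(val)
        phase_sum += d.phase
        wx_sum += w * d.x
    shift = 2.0 * np.pi * wx_sum / Lx  # phase picked up per Ly translation
    m = np.round(shift / (2.0 * np.pi))
    gamma = (2.0 * np.pi * m - shift) / Ly
    u = u + gamma * py
    return reduce_mod_pi(0.5 * u + phase_sum)


def ideal_defect_angle(
    x: np.ndarray | float,
    y: np.ndarray | float,
    defects: list[Defect],
    theta0: float = 0.0,
    box: tuple[float, float] | None = None,
    periodic: bool = False,
) -> np.ndarray | float:
    """Director angle of the ideal superposed defect field, reduced mod pi.

    In the plane (periodic=False): theta = sum_j [k_j * phi_j + phase_j] +
    theta0 with phi_j the polar angle of the displacement from core j. On a
    torus (periodic=True with a box): an exactly periodic field with the same
    winding charges, built from Jacobi theta_1 factors (see
    ``_torus_defect_angle``). Evaluating exactly at a core raises
    ``SingularPointError``.
    """
    px = np.asarray(x, dtype=float)
    py = np.asarray(y, dtype=float)
    if periodic and box is not None and defects:
        out = _torus_defect_angle(px, py, defects, box, theta0)
        return float(out) if np.isscalar(x) and np.isscalar(y) else out
    theta = np.full(np.broadcast(px, py).shape, float(theta0))
    for d in defects:
        dx, dy = px - d.x, py - d.y
        r2 = dx * dx + dy * dy
        if np.any(r2 == 0.0):
            raise SingularPointError("field evaluated exactly at a defect core")
        theta = theta + d.charge * np.arctan2(dy, dx) + d.phase
    out = reduce_mod_pi(theta)
    return float(out) if np.isscalar(x) and np.isscalar(y) else out


def true_polarity(
    defect: Defect,
    defects: list[Defect],
    box: tuple[float, float] | None = None,
    periodic: bool = False,
    h: float = 0.15,
) -> float:
    """Exact polarity of a planted +1/2 core in the full generated field.

    Evaluates the ideal (noise-free) field on a small local grid around the
    core and extracts psi = atan2(p_y, p_x) from centered finite differences
    of the nematic tensor, p = (dQxx/dx + dQxy/dy, dQxy/dx - dQxx/dy).
    """
    if defect.charge <= 0:
        raise ConfigError("polarity is defined for +1/2 cores only")
    from .fields import DirectorGrid
    from .properties import defect_polarity

    n = 9
    ax = (np.arange(n) - n // 2) * h
    X, Y = np.meshgrid(defect.x + ax, defect.y + ax)
    # stay off the singular core node
    theta = ideal_defect_angle(
        X + 0.31 * h, Y + 0.17 * h, defects, box=box, periodic=periodic
    )
    grid = DirectorGrid(
        theta=theta, origin=(defect.x + ax[0], defect.y + ax[0]), spacing=h
    )
    return defect_polarity(grid, (defect.x, defect.y))


def _angular_noise(rng: np.random.Generator, n: int, kappa: float | None) -> np.ndarray:
    """Director noise: half of a von Mises draw on the double angle."""
    if kappa is None or np.isinf(kappa):
        return np.zeros(n)
    if kappa == 0.0:
        return rng.uniform(-np.pi, np.pi, n) / 2.0
    return rng.vonmises(0.0, kappa, n) / 2.0


def defect_velocity_template(
    x: np.ndarray | float,
    y: np.ndarray | float,
    core: tuple[float, float],
    psi: float,
    v0: float = 1.0,
    length: float = 2.0,
    box: tuple[float, float] | None = None,
    periodic: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Planted flow pattern of a +1/2 defect with polarity ``psi``.

    Divergence-free field from the streamfunction Psi = v0 * Y * exp(-r^2 /
    (2 L^2)) in the defect-aligned frame: a forward jet of speed v0 along the
    polarity axis at the core, flanked by two counter-rotating vortices at
    transverse distance L, all decaying over the scale L. It is a recoverable
    planted pattern with no hydrodynamic fidelity claimed.
    """
    if v0 < 0:
        raise ConfigError("v0 must be >= 0")
    dx, dy = _displacements(
        np.asarray(x, float), np.asarray(y, float), core, box, periodic
    )
    c, s = np.cos(psi), np.sin(psi)
    X = c * dx + s * dy
    Y = -s * dx + c * dy
    E = np.exp(-(X * X + Y * Y) / (2.0 * length * length))
    vX = v0 * E * (1.0 - Y * Y / (length * length))
    vY = v0 * E * X * Y / (length * length)
    vx = c * vX - s * vY
    vy = s * vX + c * vY
    return vx, vy


def _triangular_lattice(box: tuple[float, float], n_cells: int) -> np.ndarray:
    """~n_cells points on a triangular lattice covering the box."""
    Lx, Ly = box
    a = np.sqrt(2.0 * Lx * Ly / (np.sqrt(3.0) * n_cells))
    row_h = a * np.sqrt(3.0) / 2.0
    ncols = max(2, int(round(Lx / a)))
    nrows = max(2, int(round(Ly / row_h)))
    ax, ay = Lx / ncols, Ly / nrows
    pts = []
    for r in range(nrows):
        offset = 0.25 * ax if r % 2 == 0 else -0.25 * ax
        for c in range(ncols):
            pts.append(((c + 0.5) * ax + offset, (r + 0.5) * ay))
    return np.asarray(pts)


def generate_frame(cfg: SynthConfig) -> tuple[CellFrame, list[DefectRecord]]:
    """One synthetic frame plus its ground-truth defect records.

    Cell centers are a jittered triangular lattice at the configured density;
    orientations sample the ideal defect field plus angular noise; velocities
    (when cfg.v0 > 0 and +1/2 defects exist) superpose the per-defect flow
    templates plus isotropic Gaussian noise. Fully reproducible from cfg.seed.
    """
    rng = np.random.default_rng(cfg.seed)
    Lx, Ly = cfg.box
    pts = _triangular_lattice(cfg.box, cfg.n_cells)
    a = np.sqrt(2.0 * Lx * Ly / (np.sqrt(3.0) * cfg.n_cells))
    pts = pts + rng.uniform(-cfg.jitter * a, cfg.jitter * a, pts.shape)
    if cfg.periodic:
        pts[:, 0] %= Lx
        pts[:, 1] %= Ly
    else:
        pts[:, 0] = np.clip(pts[:, 0], 0.0, np.nextafter(Lx, 0.0))
        pts[:, 1] = np.clip(pts[:, 1], 0.0, np.nextafter(Ly, 0.0))

    # nudge any centroid that landed (to numerical precision) on a core
    for d in cfg.defects:
        dx, dy = _displacements(pts[:, 0], pts[:, 1], (d.x, d.y), cfg.box, cfg.periodic)
        hit = (dx == 0.0) & (dy == 0.0)
        pts[hit, 0] += 1e-6 * a

    if cfg.defects:
        theta = ideal_defect_angle(
            pts[:, 0], pts[:, 1], cfg.defects, box=cfg.box, periodic=cfg.periodic
        )
    else:
        theta = np.zeros(len(pts))
    theta = reduce_mod_pi(theta + _angular_noise(rng, len(pts), cfg.kappa))

    psis = {
        i: true_polarity(d, cfg.defects, cfg.box, cfg.periodic)
        for i, d in enumerate(cfg.defects)
        if d.charge > 0
    }

    vx = vy = None
    if cfg.v0 > 0 and psis:
        vx = np.zeros(len(pts))
        vy = np.zeros(len(pts))
        for i, d in enumerate(cfg.defects):
            if d.charge > 0:
                tx, ty = defect_velocity_template(
                    pts[:, 0], pts[:, 1], (d.x, d.y), psis[i],
                    v0=cfg.v0, length=cfg.flow_length,
                    box=cfg.box, periodic=cfg.periodic,
                )
                vx += tx
                vy += ty
        if cfg.sigma_v > 0:
            vx = vx + rng.normal(0.0, cfg.sigma_v, len(pts))
            vy = vy + rng.normal(0.0, cfg.sigma_v, len(pts))

    frame = CellFrame(
        x=pts[:, 0], y=pts[:, 1], theta=theta,
        box=cfg.box, periodic=cfg.periodic, vx=vx, vy=vy,
    )
    truth = [
        DefectRecord(
            x=d.x, y=d.y, charge=d.label,
            psi=psis.get(i),
            method="ground-truth",
        )
        for i, d in enumerate(cfg.defects)
    ]
    return frame, truth


@dataclass
class LabeledDataset:
    """Director patches with one-hot-able class labels.

    ``patches`` has shape (n, side, side); ``labels`` holds class indices in
    the canonical (+1/2, none, -1/2) order.
    """

    patches: np.ndarray
    labels: np.ndarray
    provenance: str = "synthetic-ground-truth"
    kappas: np.ndarray | None = None  # per-item noise concentration (inf = none)

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.patches.ndim != 3 or self.patches.shape[1] != self.patches.shape[2]:
            raise ConfigError("patches must be (n, side, side) and square")
        if len(self.labels) != len(self.patches):
            raise ConfigError("labels and patches must have equal length")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() > 2):
            raise ConfigError("labels must be class indices 0..2")
        if self.kappas is not None:
            self.kappas = np.asarray(self.kappas, dtype=float)
            if len(self.kappas) != len(self.patches):
                raise ConfigError("kappas must match patches length")

    def __len__(self) -> int:
        return int(len(self.patches))

    @property
    def side(self) -> int:
        return int(self.patches.shape[1])

    def one_hot(self) -> np.ndarray:
        return np.eye(3)[self.labels]

    def label_names(self) -> list[str]:
        return [CLASSES[i] for i in self.labels]

    def rois(self, patch_spacing: float = 0.75) -> list[ROI]:
        return [
            ROI(theta_patch=p, center=(0.0, 0.0), patch_spacing=patch_spacing,
                label=CLASSES[l])
            for p, l in zip(self.patches, self.labels)
        ]

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.patches[idx], self.labels[idx], self.provenance,
            None if self.kappas is None else self.kappas[idx],
        )


def _patch_coords(side: int, spacing: float) -> tuple[np.ndarray, np.ndarray]:
    half = spacing * (side - 1) / 2.0
    ax = np.linspace(-half, half, side)
    return np.meshgrid(ax, ax)


def _defect_patch(
    rng: np.random.Generator, side: int, spacing: float, charge: float,
    kappa: float | None,
) -> np.ndarray:
    """Ideal single-defect patch: random phase, core jittered off-node."""
    X, Y = _patch_coords(side, spacing)
    core = rng.uniform(-0.4, 0.4, 2) * spacing  # off-node so no singular sample
    phase = rng.uniform(0.0, np.pi)
    d = Defect(float(core[0]), float(core[1]), charge, phase)
    theta = ideal_defect_angle(X, Y, [d])
    return reduce_mod_pi(theta + _angular_noise(rng, X.size, kappa).reshape(X.shape))


def _no_defect_patch(
    rng: np.random.Generator, side: int, spacing: float, kappa: float | None,
) -> np.ndarray:
    """Hard negative: low-order patch with no enclosed core.

    Two recipes mixed 50/50 — a uniform base orientation with per-node noise
    (at low kappa this is a disordered region that is not a defect), and the
    far-field between a +-1/2 pair whose cores both lie safely outside the
    patch (winding 0 by charge neutrality).
    """
    X, Y = _patch_coords(side, spacing)
    span = spacing * (side - 1)
    if rng.random() < 0.5:
        theta = np.full(X.shape, rng.uniform(0.0, np.pi))
    else:
        r1 = span * rng.uniform(0.9, 1.5)
        r2 = span * rng.uniform(0.9, 1.5)
        a1 = rng.uniform(0.0, 2 * np.pi)
        a2 = a1 + np.pi + rng.uniform(-0.5, 0.5)
        pair = [
            Defect(r1 * np.cos(a1), r1 * np.sin(a1), +0.5, rng.uniform(0, np.pi)),
            Defect(r2 * np.cos(a2), r2 * np.sin(a2), -0.5),
        ]
        theta = ideal_defect_angle(X, Y, pair)
    return reduce_mod_pi(theta + _angular_noise(rng, X.size, kappa).reshape(X.shape))


def generate_labeled_rois(
    n_per_class: int,
    noise_levels: tuple[float | None, ...] = (None, 8.0, 3.0),
    side: int = 9,
    patch_spacing: float = 0.75,
    seed: int = 0,
) -> LabeledDataset:
    """Balanced labeled ROI dataset spread evenly across noise levels.

    Noise levels are von Mises concentrations in double-angle space
    (``None`` = noise-free). With the default patch spacing of 0.75 cell
    diameters a 9x9 patch spans 6 cell diameters, the size used for
    candidate ROIs. Byte-identical output for a fixed seed.
    """
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    patches, labels, kappas = [], [], []
    for ci, cls in enumerate(CLASSES):
        for item in range(n_per_class):
            kappa = noise_levels[item % len(noise_levels)]
            if cls == "none":
                p = _no_defect_patch(rng, side, patch_spacing, kappa)
            else:
                charge = 0.5 if cls == "+1/2" else -0.5
                p = _defect_patch(rng, side, patch_spacing, charge, kappa)
            patches.append(p)
            labels.append(ci)
            kappas.append(np.inf if kappa is None else float(kappa))
    order = rng.permutation(len(patches))
    return LabeledDataset(
        patches=np.asarray(patches)[order],
        labels=np.asarray(labels)[order],
        kappas=np.asarray(kappas)[order],
    )


def generate_labeled_rois_by_noise(
    n_per_class: int,
    noise_levels: tuple[float | None, ...],
    side: int = 9,
    patch_spacing: float = 0.75,
    seed: int = 0,
) -> dict[float | None, LabeledDataset]:
    """One balanced dataset per noise level (for noise-accuracy curves)."""
    out = {}
    for j, kappa in enumerate(noise_levels):
        out[kappa] = generate_labeled_rois(
            n_per_class, (kappa,), side=side, patch_spacing=patch_spacing,
            seed=seed + 7919 * (j + 1),
        )
    return out
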