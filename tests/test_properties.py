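"""Defect polarity and oriented ensemble averaging of fields."""

import numpy as np
import pytest

from nemadetect.fields import DirectorGrid, ParameterError
from nemadetect.properties import (
    AverageField,
    PolarityUndefinedError,
    VectorField,
    average_director_around_defects,
    average_field_around_defects,
    defect_polarity,
    field_correlation,
    interpolate_cell_velocities,
)
from nemadetect.records import DefectRecord
from nemadetect.synthetic import (
    Defect,
    SynthConfig,
    defect_velocity_template,
    generate_frame,
    ideal_defect_angle,
)
from nemadetect.fields import build_director_grid

from conftest import make_ideal_grid


def template_field(psi, core=(0.0, 0.0), extent=6.0, spacing=0.25, noise=0.0,
                   rng=None, v0=1.0):
    """VectorField holding the planted +1/2 flow template (+ optional noise)."""
    n = int(round(2 * extent / spacing)) + 1
    ax = np.linspace(-extent, extent, n)
    X, Y = np.meshgrid(core[0] + ax, core[1] + ax)
    vx, vy = defect_velocity_template(X, Y, core, psi, v0=v0)
    if noise > 0:
        vx = vx + rng.normal(0, noise, vx.shape)
        vy = vy + rng.normal(0, noise, vy.shape)
    return VectorField(vx=vx, vy=vy, origin=(core[0] + ax[0], core[1] + ax[0]),
                       spacing=float(ax[1] - ax[0]))


def clean_average(half_width=4.0, side_points=17):
    ax = np.linspace(-half_width, half_width, side_points)
    X, Y = np.meshgrid(ax, ax)
    vx, vy = defect_velocity_template(X, Y, (0.0, 0.0), 0.0)
    return AverageField(vx=vx, vy=vy, spacing=float(ax[1] - ax[0]), n=1)


class TestDefectPolarity:
    def test_zero_phase_ideal_field_points_along_x(self):
        grid = make_ideal_grid([Defect(0.0, 0.0, 0.5)])
        psi = defect_polarity(grid, (0.0, 0.0))
        assert np.abs(np.angle(np.exp(1j * psi))) < 1e-2

    def test_rigid_rotation_rotates_polarity(self):
        for phase in (0.2, 0.9, 2.5):
            grid = make_ideal_grid([Defect(0.0, 0.0, 0.5, phase)])
            psi = defect_polarity(grid, (0.0, 0.0))
            assert np.abs(np.angle(np.exp(1j * (psi - 2 * phase)))) < 1e-2

    def test_uniform_field_has_undefined_polarity(self):
        grid = DirectorGrid(theta=np.full((21, 21), 0.3), origin=(0, 0),
                            spacing=0.5)
        with pytest.raises(PolarityUndefinedError):
            defect_polarity(grid, (5.0, 5.0))


class TestOrientedAveraging:
    def test_identical_clean_templates_average_to_the_template(self):
        rng = np.random.default_rng(1)
        defects, fields = [], []
        for psi in rng.uniform(0, 2 * np.pi, 8):
            defects.append(DefectRecord(x=0.0, y=0.0, charge="+1/2",
                                        psi=float(psi)))
            fields.append(template_field(psi))
        avg = average_field_around_defects(defects, fields, half_width=4.0)
        ref = clean_average()
        assert field_correlation(avg, ref) > 0.999
        assert avg.n == 8

    def test_averaging_is_deterministic_and_permutation_invariant(self):
        rng = np.random.default_rng(2)
        defects, fields = [], []
        for psi in rng.uniform(0, 2 * np.pi, 6):
            defects.append(DefectRecord(x=0.0, y=0.0, charge="+1/2",
                                        psi=float(psi)))
            fields.append(template_field(psi, noise=0.3, rng=rng))
        a1 = average_field_around_defects(defects, fields, 4.0)
        a2 = average_field_around_defects(defects, fields, 4.0)
        assert np.array_equal(a1.vx, a2.vx)
        perm = [3, 1, 5, 0, 4, 2]
        a3 = average_field_around_defects(
            [defects[i] for i in perm], [fields[i] for i in perm], 4.0
        )
        assert np.allclose(a1.vx, a3.vx, atol=1e-12)

    def test_requires_polarized_positive_defects(self):
        with pytest.raises(ParameterError):
            average_field_around_defects([], template_field(0.0), 4.0)
        bad = DefectRecord(x=0, y=0, charge="-1/2")
        with pytest.raises(ParameterError):
            average_field_around_defects([bad], template_field(0.0), 4.0)

    def test_window_crossing_nonperiodic_boundary_is_skipped(self):
        f = template_field(0.0, extent=3.0)
        near_edge = DefectRecord(x=2.5, y=0.0, charge="+1/2", psi=0.0)
        ok = DefectRecord(x=0.0, y=0.0, charge="+1/2", psi=0.0)
        with pytest.warns(UserWarning):
            avg = average_field_around_defects([near_edge, ok], [f, f], 2.5)
        assert avg.n == 1

    def test_average_director_recovers_plus_half_pattern(self):
        rng = np.random.default_rng(3)
        defects, grids = [], []
        for phase in rng.uniform(0, np.pi, 6):
            grids.append(make_ideal_grid([Defect(0.0, 0.0, 0.5, phase)], n=81))
            defects.append(DefectRecord(x=0.0, y=0.0, charge="+1/2",
                                        psi=float((2 * phase) % (2 * np.pi))))
        theta, order, n = average_director_around_defects(defects, grids, 4.0)
        assert n == 6
        # the aligned average must match the zero-phase ideal +1/2 field
        ax = np.linspace(-4.0, 4.0, theta.shape[0])
        X, Y = np.meshgrid(ax, ax)
        expect = ideal_defect_angle(X + 1e-9, Y + 1e-9, [Defect(0, 0, 0.5)])
        far = np.hypot(X, Y) > 1.0
        mism = np.abs(np.angle(np.exp(2j * (theta - expect)))) / 2
        assert np.quantile(mism[far], 0.95) < 0.1
        assert order[far].min() > 0.8


class TestFieldCorrelation:
    def test_self_correlation_is_one(self):
        a = clean_average()
        assert field_correlation(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_antisymmetry(self):
        a = clean_average()
        b = AverageField(vx=-a.vx, vy=-a.vy, spacing=a.spacing, n=1)
        assert field_correlation(a, b) == pytest.approx(-1.0, abs=1e-12)

    def test_pointwise_quarter_rotation_is_orthogonal(self):
        a = clean_average()
        b = AverageField(vx=-a.vy, vy=a.vx, spacing=a.spacing, n=1)
        assert field_correlation(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_zero_field_rejected(self):
        a = clean_average()
        z = AverageField(vx=np.zeros_like(a.vx), vy=np.zeros_like(a.vy),
                         spacing=a.spacing, n=1)
        with pytest.raises(ParameterError):
            field_correlation(a, z)

    def test_shape_mismatch_rejected(self):
        a = clean_average(side_points=17)
        b = clean_average(side_points=15)
        with pytest.raises(ParameterError):
            field_correlation(a, b)


class TestVelocityInterpolation:
    def test_planted_flow_recovered_on_grid(self):
        cfg = SynthConfig(
            defects=[Defect(9, 15, 0.5, 0.3), Defect(21, 15, -0.5)],
            kappa=None, seed=5, v0=1.0,
        )
        frame, truth = generate_frame(cfg)
        grid = build_director_grid(frame)
        vf = interpolate_cell_velocities(frame, grid)
        X, Y = grid.node_coords()
        ex, ey = defect_velocity_template(
            X, Y, (9.0, 15.0), truth[0].psi, box=cfg.box, periodic=True
        )
        err = np.hypot(vf.vx - ex, vf.vy - ey)
        assert np.median(err) < 0.1

    def test_missing_velocities_rejected(self):
        frame, _ = generate_frame(SynthConfig(defects=[], seed=1))
        grid = build_director_grid(frame)
        with pytest.raises(ParameterError):
            interpolate_cell_velocities(frame, grid)
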