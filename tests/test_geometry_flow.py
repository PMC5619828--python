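"""Wall geometries, no-slip boundaries, pressure-driven flow."""

import numpy as np
import pytest

from mesocell.geometry_flow import (
    effective_opening_size,
    Slab,
    Pipette,
    TriangularPillarArray,
    DeviceGeometry,
    build_walls,
    drive_flow,
)
from mesocell.dpd_core.particles import ParticleSystem, ThermoState, FLUID, WALL
from mesocell.dpd_core.interactions import default_interactions
from mesocell.dpd_core.integrator import Simulation
from mesocell.units import UnitSystem


class TestEffectiveOpening:
    @pytest.mark.parametrize(
        "gap,expected", [(10.0, 9.1), (12.0, 9.93), (15.0, 11.1)]
    )
    def test_printed_values(self, gap, expected):
        assert effective_opening_size(gap, 25.8) == pytest.approx(expected, abs=0.05)

    def test_unit_circle(self):
        assert effective_opening_size(np.pi, 1.0) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            effective_opening_size(0.0, 25.8)
        with pytest.raises(ValueError):
            effective_opening_size(10.0, -1.0)


class TestSDFs:
    def test_slab_signs(self):
        s = Slab(axis=2, lo=1.0, hi=9.0)
        pts = np.array([[0, 0, 5.0], [0, 0, 0.5], [0, 0, 9.5]])
        d = s.sdf(pts)
        assert d[0] < 0 and d[1] > 0 and d[2] > 0

    def test_pipette_bore_open(self):
        p = Pipette(radius=3.0, mouth=5.0, wall_length=8.0, center=(10.0, 10.0))
        pts = np.array(
            [[7.0, 10.0, 10.0],   # inside bore -> fluid
             [7.0, 16.0, 10.0],   # inside plate -> solid
             [2.0, 10.0, 10.0]]   # upstream of mouth -> fluid
        )
        d = p.sdf(pts)
        assert d[0] < 0 and d[1] > 0 and d[2] < 0

    def test_pillar_array_gap_width(self):
        arr = TriangularPillarArray(gap=12.0, side=20.0)
        xs = np.linspace(0.0, arr.period, 4001)
        h = arr.side * np.sqrt(3.0) / 2.0
        # widest pillar section is the base row (upper y edge)
        ys = np.linspace(20.0 - 2.0 * h / 3.0, 20.0 + h / 3.0 - 1e-6, 801)
        widths = []
        for y in ys:
            pts = np.column_stack(
                [xs, np.full_like(xs, y), np.full_like(xs, 5.0)]
            )
            frac = (arr.sdf(pts) < 0).mean()
            widths.append(frac * arr.period)
        assert min(widths) == pytest.approx(12.0, abs=0.1)

    def test_device_periodic_box(self):
        dev = DeviceGeometry(gap=12.0)
        assert dev.box[2] == pytest.approx(25.8 + 3.0)
        assert list(dev.periodic) == [True, True, False]
        assert dev.pillars.effective_opening() == pytest.approx(9.93, abs=0.05)

    def test_gap_validation(self):
        with pytest.raises(ValueError):
            TriangularPillarArray(gap=-1.0)


class TestWalls:
    def test_wall_band(self):
        s = Slab(axis=2, lo=1.0, hi=9.0)
        box = np.array([5.0, 5.0, 10.0])
        pos = build_walls(s, box, fluid_density=3.0, cutoff=1.0)
        d = s.sdf(pos)
        assert pos.shape[0] > 0
        assert np.all((d > 0.0) & (d <= 1.0))

    def test_containment_after_steps(self):
        """No fluid particle at sdf > 0 after any step (bounce-back)."""
        geom = Slab(axis=2, lo=1.0, hi=9.0)
        rng = np.random.default_rng(0)
        box = np.array([6.0, 6.0, 10.0])
        n = 400
        pts = rng.uniform([0, 0, 1.2], [6, 6, 8.8], (n, 3))
        wall_pos = build_walls(geom, box, 3.0, rng=rng)
        system = ParticleSystem(
            positions=np.vstack([pts, wall_pos]),
            velocities=np.zeros((n + wall_pos.shape[0], 3)),
            types=np.concatenate([np.full(n, FLUID), np.full(wall_pos.shape[0], WALL)]),
            box=box,
            periodic=np.array([True, True, False]),
        )
        sim = Simulation(system, default_interactions(), ThermoState(seed=1), geometry=geom)
        for _ in range(10):
            sim.step(50)
            d = geom.sdf(system.positions[system.types == FLUID])
            assert np.all(d <= 1e-9)

    def test_no_slip_without_driving(self):
        geom = Slab(axis=2, lo=1.0, hi=9.0)
        rng = np.random.default_rng(2)
        box = np.array([6.0, 6.0, 10.0])
        n = int(3 * 6 * 6 * 8)
        pts = rng.uniform([0, 0, 1.05], [6, 6, 8.95], (n, 3))
        wall_pos = build_walls(geom, box, 3.0, rng=rng)
        system = ParticleSystem(
            positions=np.vstack([pts, wall_pos]),
            velocities=np.zeros((n + wall_pos.shape[0], 3)),
            types=np.concatenate([np.full(n, FLUID), np.full(wall_pos.shape[0], WALL)]),
            box=box,
            periodic=np.array([True, True, False]),
        )
        sim = Simulation(system, default_interactions(), ThermoState(seed=2), geometry=geom)
        sim.step(1500)
        means = []
        for _ in range(10):
            sim.step(50)
            fluid = system.types == FLUID
            near = fluid & (
                (system.positions[:, 2] < 2.0) | (system.positions[:, 2] > 8.0)
            )
            means.append(system.velocities[near, :2].mean(axis=0))
        assert np.abs(np.mean(means, axis=0)).max() < 0.05


class TestDriveFlow:
    def test_zero_gradient_zero_force(self):
        s = _tiny_system()
        f = drive_flow(s, 0.0)
        assert np.allclose(f, 0.0)

    def test_unit_mapping(self):
        s = _tiny_system()
        u = UnitSystem()
        f = drive_flow(s, 0.67, axis=1, density=3.0, units=u)
        expected = 0.67 / u.pressure_si / 3.0
        assert f[1] == pytest.approx(expected)
        assert f[0] == f[2] == 0.0

    def test_poiseuille_profile(self):
        """Driven channel flow matches the continuum parabola (oracle)."""
        geom = Slab(axis=2, lo=1.0, hi=9.0)
        rng = np.random.default_rng(3)
        box = np.array([6.0, 6.0, 10.0])
        n = int(3 * 6 * 6 * 8)
        pts = rng.uniform([0, 0, 1.05], [6, 6, 8.95], (n, 3))
        wall_pos = build_walls(geom, box, 3.0, rng=rng)
        system = ParticleSystem(
            positions=np.vstack([pts, wall_pos]),
            velocities=np.zeros((n + wall_pos.shape[0], 3)),
            types=np.concatenate([np.full(n, FLUID), np.full(wall_pos.shape[0], WALL)]),
            box=box,
            periodic=np.array([True, True, False]),
        )
        sim = Simulation(
            system,
            default_interactions(),
            ThermoState(seed=3),
            geometry=geom,
            body_force=np.array([0.0, 0.15, 0.0]),
        )
        sim.step(4000)
        nbins = 16
        prof = np.zeros(nbins)
        count = np.zeros(nbins)
        for _ in range(50):
            sim.step(100)
            fluid = system.types == FLUID
            z = system.positions[fluid, 2]
            vy = system.velocities[fluid, 1]
            idx = np.clip(((z - 1.0) / 8.0 * nbins).astype(int), 0, nbins - 1)
            np.add.at(prof, idx, vy)
            np.add.at(count, idx, 1)
        prof /= np.maximum(count, 1)
        zc = 1.0 + (np.arange(nbins) + 0.5) * 8.0 / nbins
        # continuum oracle: u(z) = umax * 4 (z-1)(9-z)/w^2
        coeffs = np.polyfit(zc, prof, 2)
        fit = np.polyval(coeffs, zc)
        ss_res = np.sum((prof - fit) ** 2)
        ss_tot = np.sum((prof - prof.mean()) ** 2)
        assert 1.0 - ss_res / ss_tot > 0.95        # parabolic shape
        assert coeffs[0] < 0                        # concave
        z_max = -coeffs[1] / (2.0 * coeffs[0])
        assert z_max == pytest.approx(5.0, abs=0.5)  # max at the center
        # near-wall velocity far below the center velocity (no slip)
        assert prof[0] < 0.35 * prof[nbins // 2]

    def test_linearity_in_gradient(self):
        """Doubling the body force doubles the mean flow speed (low Re)."""
        speeds = []
        for scale, seed in ((1.0, 4), (2.0, 5)):
            geom = Slab(axis=2, lo=1.0, hi=9.0)
            rng = np.random.default_rng(seed)
            box = np.array([6.0, 6.0, 10.0])
            n = int(3 * 6 * 6 * 8)
            pts = rng.uniform([0, 0, 1.05], [6, 6, 8.95], (n, 3))
            wall_pos = build_walls(geom, box, 3.0, rng=rng)
            system = ParticleSystem(
                positions=np.vstack([pts, wall_pos]),
                velocities=np.zeros((n + wall_pos.shape[0], 3)),
                types=np.concatenate(
                    [np.full(n, FLUID), np.full(wall_pos.shape[0], WALL)]
                ),
                box=box,
                periodic=np.array([True, True, False]),
            )
            sim = Simulation(
                system, default_interactions(), ThermoState(seed=seed),
                geometry=geom, body_force=np.array([0.0, 0.08 * scale, 0.0]),
            )
            sim.step(6000)  # startup transient ~ rho w^2 / (pi^2 mu)
            vals = []
            for _ in range(12):
                sim.step(500)
                vals.append(system.velocities[system.types == FLUID, 1].mean())
            speeds.append(np.mean(vals))
        assert speeds[1] / speeds[0] == pytest.approx(2.0, rel=0.25)


def _tiny_system():
    return ParticleSystem(
        positions=np.zeros((1, 3)),
        velocities=np.zeros((1, 3)),
        types=np.full(1, FLUID),
        box=np.full(3, 10.0),
        periodic=np.array([True, True, True]),
    )
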