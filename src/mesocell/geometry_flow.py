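"""Solid-wall geometries as signed distance functions, no-slip boundaries,
and pressure-driven flow.

Sign convention: ``sdf(points) < 0`` in the fluid, ``> 0`` inside the solid.
No-slip walls combine bounce-back reflection (handled by the integrator)
with layers of frozen DPD particles filling the solid region.

The obstacle-array device follows the printed geometry: triangular pillars
in rows, gap ``g`` between facing pillar edges within a row, rows spaced
60 um apart, device depth 25.8 um, adjacent rows staggered by half a
period.  Pillar side length and orientation (equilateral, apex upstream)
are configurable assumptions; the paper prints only gap, depth, spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mesocell.dpd_core.particles import ParticleSystem, WALL
from mesocell.units import UnitSystem, DEFAULT_UNITS


def effective_opening_size(gap: float, depth: float) -> float:
    """Radius of the circle whose area equals the gap-by-depth opening."""
    if gap <= 0 or depth <= 0:
        raise ValueError("gap and depth must be positive")
    return float(np.sqrt(gap * depth / np.pi))


# ---------------------------------------------------------------------------
# SDF primitives and CSG
# ---------------------------------------------------------------------------

class SDF:
    def sdf(self, points: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __or__(self, other: "SDF") -> "SDF":
        return Union(self, other)


@dataclass
class Union(SDF):
    a: SDF
    b: SDF

    def sdf(self, points: np.ndarray) -> np.ndarray:
        return np.maximum(self.a.sdf(points), self.b.sdf(points))


@dataclass
class Slab(SDF):
    """Solid outside the open interval (lo, hi) along one axis."""

    axis: int
    lo: float
    hi: float

    def sdf(self, points: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(points)[:, self.axis]
        return np.maximum(self.lo - x, x - self.hi)


@dataclass
class Pipette(SDF):
    """Axisymmetric pipette: a flat face plate with a circular bore.

    Oriented along +x; the mouth plane sits at ``x = mouth``; the solid is
    the plate x in [mouth, mouth+wall_length] minus the bore of radius
    ``radius`` around the (y0, z0) axis.  The bore edge is rounded with
    ``rounding``.
    """

    radius: float
    mouth: float = 0.0
    wall_length: float = 8.0
    center: tuple[float, float] = (0.0, 0.0)
    rounding: float = 0.25

    def sdf(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        x = p[:, 0]
        rho = np.hypot(p[:, 1] - self.center[0], p[:, 2] - self.center[1])
        # solid = plate slab (x in [mouth, mouth+wall_length]) minus the bore
        in_slab = np.minimum(x - self.mouth, self.mouth + self.wall_length - x)
        d = np.minimum(in_slab, rho - self.radius)
        # round off the mouth lip: quarter-circle fillet centered one
        # rounding radius inside the sharp corner (mouth, bore radius)
        if self.rounding > 0:
            cx = self.mouth + self.rounding
            crho = self.radius + self.rounding
            near_lip = (x < cx) & (rho < crho)
            dist = np.sqrt((x - cx) ** 2 + (rho - crho) ** 2)
            d = np.where(near_lip, self.rounding - dist, d)
        return d


def _polygon_sdf_2d(px: np.ndarray, py: np.ndarray, verts: np.ndarray) -> np.ndarray:
    """Exact signed distance to a 2-D polygon, positive inside."""
    n = verts.shape[0]
    d = np.full(px.shape, np.inf)
    sign = np.ones(px.shape)
    j = n - 1
    inside = np.zeros(px.shape, dtype=bool)
    for i in range(n):
        vx0, vy0 = verts[j]
        vx1, vy1 = verts[i]
        ex, ey = vx1 - vx0, vy1 - vy0
        wx, wy = px - vx0, py - vy0
        t = np.clip((wx * ex + wy * ey) / (ex * ex + ey * ey), 0.0, 1.0)
        dx, dy = wx - t * ex, wy - t * ey
        d = np.minimum(d, np.hypot(dx, dy))
        cond = ((vy0 <= py) & (py < vy1)) | ((vy1 <= py) & (py < vy0))
        xi = vx0 + (py - vy0) / np.where(vy1 != vy0, vy1 - vy0, 1.0) * ex
        inside ^= cond & (px < xi)
        j = i
    return np.where(inside, d, -d)


@dataclass
class TriangularPillarArray(SDF):
    """Rows of equilateral triangular pillars (apex upstream, flow along +y).

    Lateral (x) period = side + gap; adjacent rows are offset by half a
    period.  Depth (z) confinement is added separately with a Slab.
    """

    gap: float
    side: float = 20.0
    row_spacing: float = 60.0
    n_rows: int = 1
    first_row_y: float = 20.0
    depth: float = 25.8
    pressure_gradient_pa_um: float = 0.67

    def __post_init__(self) -> None:
        if self.gap <= 0:
            raise ValueError("gap must be positive")
        h = self.side * np.sqrt(3.0) / 2.0
        # apex pointing in -y (upstream), base downstream
        self._verts = np.array(
            [(0.0, -2.0 * h / 3.0), (self.side / 2.0, h / 3.0), (-self.side / 2.0, h / 3.0)]
        )

    @property
    def period(self) -> float:
        return self.side + self.gap

    def sdf(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(points)
        x, y = p[:, 0], p[:, 1]
        d = np.full(x.shape, -np.inf)
        for row in range(self.n_rows):
            yc = self.first_row_y + row * self.row_spacing
            xoff = 0.5 * self.period if row % 2 else 0.0
            xl = np.mod(x - xoff + 0.5 * self.period, self.period) - 0.5 * self.period
            d = np.maximum(d, _polygon_sdf_2d(xl, y - yc, self._verts))
        return d

    def effective_opening(self) -> float:
        return effective_opening_size(self.gap, self.depth)


@dataclass
class DeviceGeometry(SDF):
    """One lateral period of the obstacle-array device: pillars plus depth walls."""

    gap: float
    depth: float = 25.8
    row_spacing: float = 60.0
    side: float = 20.0
    n_rows: int = 1
    first_row_y: float = 20.0
    pressure_gradient_pa_um: float = 0.67
    wall_pad: float = 1.5

    def __post_init__(self) -> None:
        self.pillars = TriangularPillarArray(
            gap=self.gap,
            side=self.side,
            row_spacing=self.row_spacing,
            n_rows=self.n_rows,
            first_row_y=self.first_row_y,
            depth=self.depth,
        )
        self.depth_walls = Slab(axis=2, lo=self.wall_pad, hi=self.wall_pad + self.depth)

    @property
    def box(self) -> np.ndarray:
        ly = self.first_row_y + (self.n_rows - 1) * self.row_spacing + self.first_row_y
        return np.array([self.pillars.period, ly, self.depth + 2 * self.wall_pad])

    @property
    def periodic(self) -> np.ndarray:
        return np.array([True, True, False])

    def sdf(self, points: np.ndarray) -> np.ndarray:
        return np.maximum(self.pillars.sdf(points), self.depth_walls.sdf(points))


@dataclass
class PipetteGeometry(SDF):
    """Pipette wall plus a containment box for solvent-free aspiration."""

    radius: float = 3.0
    mouth: float = 0.0
    wall_length: float = 8.0
    rounding: float = 0.25
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("pipette radius must be positive")
        self.pipette = Pipette(
            radius=self.radius,
            mouth=self.mouth,
            wall_length=self.wall_length,
            center=self.center,
            rounding=self.rounding,
        )

    def sdf(self, points: np.ndarray) -> np.ndarray:
        return self.pipette.sdf(points)


# ---------------------------------------------------------------------------
# wall particles and driving
# ---------------------------------------------------------------------------

def build_walls(
    geometry: SDF,
    box: np.ndarray,
    fluid_density: float = 3.0,
    cutoff: float = 1.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Frozen-particle positions filling the solid region to depth >= cutoff.

    Random points at the fluid number density are kept where
    0 < sdf <= cutoff (deeper layers cannot interact with the fluid).
    """
    rng = rng or np.random.default_rng(0)
    box = np.asarray(box, dtype=float)
    n_target = int(np.ceil(fluid_density * box.prod()))
    pts = rng.uniform(0.0, box, size=(n_target, 3))
    d = geometry.sdf(pts)
    keep = (d > 0.0) & (d <= cutoff)
    return pts[keep]


def drive_flow(
    system: ParticleSystem,
    pressure_gradient_pa_um: float,
    axis: int = 1,
    density: float = 3.0,
    units: UnitSystem = DEFAULT_UNITS,
) -> np.ndarray:
    """Uniform body force per particle equivalent to the pressure gradient.

    f = grad(P) / n for fluid and cell particles; wall particles get zero.
    Returns the (3,) force vector (use with Simulation.body_force).
    """
    grad_sim = units.pressure_gradient_to_sim(pressure_gradient_pa_um)
    f = np.zeros(3)
    f[axis] = grad_sim / density
    return f
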