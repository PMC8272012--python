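"""Synthetic 2D speed-of-sound breast phantoms.

Phantoms emulate coronal breast slices immersed in water inside a ring
array: a water background at 1484 m/s, a smooth closed outer boundary, a
slow fat-mimicking annulus, a textured glandular interior, plus embedded
circular inclusions and point scatterers. They serve as ground truth for
forward simulation, network training, and inversion benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

WATER_SOS = 1484.0  # m/s, room-temperature water bath
SOS_HARD_MIN = 300.0
SOS_HARD_MAX = 3000.0
TISSUE_SOS_MIN = 1300.0
TISSUE_SOS_MAX = 1800.0


@dataclass
class VelocityModel:
    """2D speed-of-sound grid with physical placement.

    Attributes
    ----------
    grid : (ny, nx) float array of SoS values in m/s.
    spacing : grid cell size in metres (square cells).
    origin : physical (x, y) of grid index (0, 0), metres.
    water_sos : background water value, m/s.
    """

    grid: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    water_sos: float = WATER_SOS

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 2:
            raise ValueError("grid must be 2D")
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("grid contains non-finite values")
        if self.grid.min() < SOS_HARD_MIN or self.grid.max() > SOS_HARD_MAX:
            raise ValueError(
                f"SoS outside [{SOS_HARD_MIN}, {SOS_HARD_MAX}] m/s: "
                f"[{self.grid.min():.1f}, {self.grid.max():.1f}]"
            )
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) physical extent in metres."""
        ny, nx = self.grid.shape
        x0, y0 = self.origin
        return (x0, x0 + (nx - 1) * self.spacing, y0, y0 + (ny - 1) * self.spacing)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical x and y coordinates of grid columns / rows."""
        ny, nx = self.grid.shape
        x0, y0 = self.origin
        return (x0 + self.spacing * np.arange(nx), y0 + self.spacing * np.arange(ny))

    def copy(self) -> "VelocityModel":
        return replace(self, grid=self.grid.copy())


def homogeneous_model(
    shape: tuple[int, int], spacing: float, sos: float = WATER_SOS,
    origin: tuple[float, float] | None = None,
) -> VelocityModel:
    """Uniform model; default origin centres the grid on (0, 0)."""
    ny, nx = shape
    if origin is None:
        origin = (-(nx - 1) * spacing / 2.0, -(ny - 1) * spacing / 2.0)
    return VelocityModel(np.full(shape, float(sos)), spacing, origin, water_sos=sos)


@dataclass
class PhantomSpec:
    """Parameters of the parametric breast phantom generator.

    All speeds in m/s, lengths in metres. ``inclusions`` is a list of
    ``((cx, cy), radius, sos)`` circles. ``scatterer_density`` is point
    scatterers per square metre of interior area.
    """

    outer_radius: float = 0.07
    fat_layer_thickness: float = 0.01
    fat_sos: float = 1440.0
    glandular_sos_mean: float = 1550.0
    glandular_sos_texture_amplitude: float = 40.0
    texture_correlation_length: float = 5e-3
    inclusions: Sequence[tuple[tuple[float, float], float, float]] = field(
        default_factory=lambda: (((0.015, 0.01), 0.008, 1650.0),
                                 ((-0.02, -0.015), 0.006, 1620.0))
    )
    scatterer_density: float = 5e3
    scatterer_amplitude: float = 60.0
    center: tuple[float, float] = (0.0, 0.0)
    boundary_wobble: float = 0.06  # fractional radial modulation of the outline
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.fat_layer_thickness < self.outer_radius):
            raise ValueError("fat layer must be thinner than the outer radius")
        if self.outer_radius > 0.1:
            raise ValueError("outer_radius must fit inside the ~0.1 m ring radius")
        for name, v in (("fat_sos", self.fat_sos),
                        ("glandular_sos_mean", self.glandular_sos_mean)):
            if not (TISSUE_SOS_MIN <= v <= TISSUE_SOS_MAX):
                raise ValueError(f"{name}={v} outside [{TISSUE_SOS_MIN}, {TISSUE_SOS_MAX}]")
        for (c, r, s) in self.inclusions:
            if not (TISSUE_SOS_MIN <= s <= TISSUE_SOS_MAX):
                raise ValueError(f"inclusion SoS {s} outside tissue range")
            if np.hypot(*c) + r > self.outer_radius:
                raise ValueError("inclusion extends beyond the outer boundary")


def _correlated_field(shape, spacing, corr_length, rng) -> np.ndarray:
    """Zero-mean, unit-RMS Gaussian random field, low-passed to corr_length."""
    white = rng.standard_normal(shape)
    sigma_cells = max(corr_length / spacing, 1e-6)
    f = gaussian_filter(white, sigma=sigma_cells, mode="wrap")
    rms = np.sqrt(np.mean(f**2))
    return f / rms if rms > 0 else f


def make_breast_phantom(
    spec: PhantomSpec,
    grid_shape: tuple[int, int],
    spacing: float,
    origin: tuple[float, float] | None = None,
) -> VelocityModel:
    """Render a PhantomSpec onto a grid.

    The phantom outline is a circle of ``outer_radius`` with smooth radial
    wobble; a fat annulus of ``fat_layer_thickness`` lines the boundary and
    the interior is ``glandular_sos_mean`` plus band-limited Gaussian
    texture, inclusions, and point scatterers. Deterministic for fixed
    ``spec.seed``.
    """
    spec.validate()
    ny, nx = grid_shape
    if origin is None:
        origin = (-(nx - 1) * spacing / 2.0, -(ny - 1) * spacing / 2.0)
    model = VelocityModel(np.full(grid_shape, WATER_SOS), spacing, origin)
    xs, ys = model.coords()
    X, Y = np.meshgrid(xs, ys)
    cx, cy = spec.center
    dx, dy = X - cx, Y - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    rng = np.random.default_rng(spec.seed)
    # smooth closed outline: low-order Fourier modulation of the radius
    n_modes = 4
    amp = rng.standard_normal(n_modes) * spec.boundary_wobble / np.sqrt(n_modes)
    phase = rng.uniform(0, 2 * np.pi, n_modes)
    modulation = np.ones_like(theta)
    for k in range(n_modes):
        modulation += amp[k] * np.cos((k + 2) * theta + phase[k])
    boundary_r = spec.outer_radius * modulation

    max_r = spec.outer_radius * (1 + spec.boundary_wobble * 2)
    half_x = (nx - 1) * spacing / 2.0
    half_y = (ny - 1) * spacing / 2.0
    if abs(cx) + max_r > half_x or abs(cy) + max_r > half_y:
        raise ValueError(
            f"phantom (radius ≤ {max_r * 1e3:.1f} mm at centre {spec.center}) "
            f"exceeds grid half-extent ({half_x * 1e3:.1f} × {half_y * 1e3:.1f} mm)"
        )

    inside = r <= boundary_r
    fat = inside & (r > boundary_r - spec.fat_layer_thickness)
    interior = inside & ~fat

    grid = model.grid
    grid[fat] = spec.fat_sos
    tex = np.zeros(grid_shape)
    if spec.glandular_sos_texture_amplitude > 0:
        tex = spec.glandular_sos_texture_amplitude * _correlated_field(
            grid_shape, spacing, spec.texture_correlation_length, rng
        )
    else:
        rng.standard_normal(grid_shape)  # keep RNG stream aligned across specs
    grid[interior] = spec.glandular_sos_mean + tex[interior]

    for (icx, icy), rad, sos in spec.inclusions:
        mask = (X - (cx + icx)) ** 2 + (Y - (cy + icy)) ** 2 <= rad**2
        grid[mask & interior] = sos

    # point scatterers: single-cell SoS perturbations in the interior
    area = np.count_nonzero(interior) * spacing**2
    n_scat = rng.poisson(spec.scatterer_density * area)
    if n_scat > 0:
        iy, ix = np.nonzero(interior)
        pick = rng.integers(0, len(iy), size=n_scat)
        signs = rng.choice([-1.0, 1.0], size=n_scat)
        grid[iy[pick], ix[pick]] += signs * spec.scatterer_amplitude

    np.clip(grid, TISSUE_SOS_MIN, TISSUE_SOS_MAX, out=grid, where=inside)
    grid[~inside] = WATER_SOS
    return model


def phantom_rms(
    model_a: VelocityModel, model_b: VelocityModel, mask: np.ndarray | None = None
) -> float:
    """Root-mean-square SoS difference (m/s) over ``mask`` (default: all cells)."""
    if model_a.grid.shape != model_b.grid.shape:
        raise ValueError(
            f"grid shape mismatch: {model_a.grid.shape} vs {model_b.grid.shape}"
        )
    diff = model_a.grid - model_b.grid
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != diff.shape:
            raise ValueError("mask shape mismatch")
        if not mask.any():
            raise ValueError("empty mask")
        diff = diff[mask]
    return float(np.sqrt(np.mean(diff**2)))


def interior_mask(model: VelocityModel, radius: float, center=(0.0, 0.0)) -> np.ndarray:
    """Boolean mask of cells within ``radius`` of ``center``."""
    xs, ys = model.coords()
    X, Y = np.meshgrid(xs, ys)
    return (X - center[0]) ** 2 + (Y - center[1]) ** 2 <= radius**2
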