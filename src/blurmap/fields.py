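"""Spatially varying diffusivity fields.

A :class:`DiffusivityField` maps a 2-D position (nm) to a local diffusion
coefficient D (µm²/s).  Fields are used both to drive Brownian-dynamics
simulations with position-dependent step lengths and as the ground truth
against which reconstructed D maps are scored.

Supported layouts
-----------------
``uniform``
    One D everywhere.
``square_inclusion`` / ``circular_inclusion``
    A single inclusion of contrasting D in a uniform background.
``pattern``
    An arbitrary list of square/circular inclusions (later entries win),
    e.g. the two-level test pattern with ~1 µm square and circular domains
    of D = 4 µm²/s in a D = 2 µm²/s background.
``labeled_grid``
    A raster of per-cell D values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["Inclusion", "DiffusivityField"]


@dataclass(frozen=True)
class Inclusion:
    """A square or circular region of constant D inside a field.

    ``size`` is the edge length of a square or the diameter of a circle,
    in nm.  ``center`` is (x, y) in nm.
    """

    kind: str  # "square" | "circle"
    center: tuple[float, float]
    size: float
    D: float

    def __post_init__(self) -> None:
        if self.kind not in ("square", "circle"):
            raise ValueError(f"unknown inclusion kind {self.kind!r}")
        if self.size <= 0:
            raise ValueError("inclusion size must be positive")
        if self.D < 0:
            raise ValueError("D must be non-negative")

    def contains(self, xy: np.ndarray) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        dx = xy[..., 0] - self.center[0]
        dy = xy[..., 1] - self.center[1]
        half = self.size / 2.0
        if self.kind == "square":
            return (np.abs(dx) <= half) & (np.abs(dy) <= half)
        return dx * dx + dy * dy <= half * half


@dataclass(frozen=True)
class DiffusivityField:
    """Map from position (nm) to local diffusion coefficient (µm²/s)."""

    layout: str
    D_background: float
    domain_bounds: tuple[float, float, float, float]  # (x0, y0, x1, y1) nm
    inclusions: tuple[Inclusion, ...] = ()
    grid_values: np.ndarray | None = None  # labeled_grid only, (ny, nx)
    grid_cell: float | None = None  # nm per cell, labeled_grid only

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.domain_bounds
        if not (x1 > x0 and y1 > y0):
            raise ValueError("domain_bounds must describe a non-empty rectangle")
        if self.D_background < 0:
            raise ValueError("D must be non-negative everywhere")
        if self.layout == "labeled_grid":
            if self.grid_values is None or self.grid_cell is None:
                raise ValueError("labeled_grid requires grid_values and grid_cell")
            if np.any(np.asarray(self.grid_values) < 0):
                raise ValueError("D must be non-negative everywhere")

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def uniform(cls, D: float, domain_bounds=(0.0, 0.0, 10_000.0, 10_000.0)):
        return cls("uniform", D, tuple(domain_bounds))

    @classmethod
    def square_inclusion(cls, D_background, D_inclusion, center, size, domain_bounds):
        inc = Inclusion("square", tuple(center), size, D_inclusion)
        return cls("square_inclusion", D_background, tuple(domain_bounds), (inc,))

    @classmethod
    def circular_inclusion(cls, D_background, D_inclusion, center, diameter, domain_bounds):
        inc = Inclusion("circle", tuple(center), diameter, D_inclusion)
        return cls("circular_inclusion", D_background, tuple(domain_bounds), (inc,))

    @classmethod
    def pattern(cls, D_background, inclusions: Sequence[Inclusion], domain_bounds):
        return cls("pattern", D_background, tuple(domain_bounds), tuple(inclusions))

    @classmethod
    def labeled_grid(cls, values: np.ndarray, cell_nm: float, origin=(0.0, 0.0)):
        values = np.asarray(values, dtype=float)
        ny, nx = values.shape
        x0, y0 = origin
        bounds = (x0, y0, x0 + nx * cell_nm, y0 + ny * cell_nm)
        return cls("labeled_grid", float(values.min()), bounds,
                   grid_values=values, grid_cell=float(cell_nm))

    @classmethod
    def two_level_test_pattern(cls, D_background=2.0, D_inclusion=4.0,
                               feature_size=960.0,
                               domain_bounds=(0.0, 0.0, 3840.0, 1920.0)):
        """Square + circle inclusion pattern used for mapping benchmarks.

        Defaults: ~1 µm square and circular domains at D = 4 µm²/s in a
        D = 2 µm²/s background, sized so a 120 nm mapping grid tiles the
        domain exactly.
        """
        x0, y0, x1, y1 = domain_bounds
        cy = (y0 + y1) / 2.0
        square = Inclusion("square", (x0 + (x1 - x0) * 0.27, cy), feature_size, D_inclusion)
        circle = Inclusion("circle", (x0 + (x1 - x0) * 0.73, cy), feature_size, D_inclusion)
        return cls.pattern(D_background, [square, circle], domain_bounds)

    # ------------------------------------------------------------------ #

    @property
    def D_inclusion(self) -> float | None:
        return self.inclusions[0].D if self.inclusions else None

    def contains(self, xy) -> np.ndarray:
        xy = np.asarray(xy, dtype=float)
        x0, y0, x1, y1 = self.domain_bounds
        return ((xy[..., 0] >= x0) & (xy[..., 0] <= x1)
                & (xy[..., 1] >= y0) & (xy[..., 1] <= y1))

    def D_at(self, xy) -> np.ndarray:
        """Local D (µm²/s) at positions ``xy`` (..., 2) in nm."""
        xy = np.asarray(xy, dtype=float)
        if self.layout == "labeled_grid":
            x0, y0, _, _ = self.domain_bounds
            ny, nx = self.grid_values.shape
            ix = np.clip(((xy[..., 0] - x0) // self.grid_cell).astype(int), 0, nx - 1)
            iy = np.clip(((xy[..., 1] - y0) // self.grid_cell).astype(int), 0, ny - 1)
            return self.grid_values[iy, ix]
        D = np.full(xy.shape[:-1], self.D_background, dtype=float)
        for inc in self.inclusions:  # later inclusions win
            D = np.where(inc.contains(xy), inc.D, D)
        return D

    def sample_positions(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` positions uniformly over the domain, (n, 2) nm."""
        x0, y0, x1, y1 = self.domain_bounds
        out = np.empty((n, 2))
        out[:, 0] = rng.uniform(x0, x1, n)
        out[:, 1] = rng.uniform(y0, y1, n)
        return out
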