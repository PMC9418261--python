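"""Lattice field containers shared by all pipeline stages.

All fields live on a single uniform square lattice of ``n x n`` nodes.
Index convention: ``values[i, j]`` is the node at row ``i`` (y) and column
``j`` (x); physical coordinates are ``x = j*h``, ``y = i*h`` with ``h`` the
grid spacing in metres.  Fields are node-centered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScalarField", "VectorField"]


@dataclass
class ScalarField:
    """A scalar quantity sampled on the lattice (TAF, fibronectin, IFP, ...)."""

    values: np.ndarray
    grid_spacing: float  # m
    units: str = ""
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ScalarField values must be a 2D array")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ScalarField":
        return ScalarField(self.values.copy(), self.grid_spacing, self.units, self.name)

    def check_finite(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"field {self.name!r} contains non-finite values")

    @classmethod
    def full(cls, n: int, h: float, fill: float = 0.0, units: str = "", name: str = "") -> "ScalarField":
        return cls(np.full((n, n), fill, dtype=float), h, units, name)


@dataclass
class VectorField:
    """A 2D vector quantity on the lattice (interstitial fluid velocity)."""

    vx: np.ndarray
    vy: np.ndarray
    grid_spacing: float  # m
    units: str = "m/s"
    name: str = ""

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        if self.vx.shape != self.vy.shape or self.vx.ndim != 2:
            raise ValueError("vx and vy must be 2D arrays of equal shape")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.vx.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def copy(self) -> "VectorField":
        return VectorField(self.vx.copy(), self.vy.copy(), self.grid_spacing, self.units, self.name)
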