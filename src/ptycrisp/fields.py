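"""Container types for ptychographic reconstruction.

The containers are deliberately thin: all numerical work happens on plain
complex ``numpy`` arrays, and these classes only bundle the arrays with the
metadata (pixel pitch, noise model, seeds) that travels with them through
simulation, reconstruction and file I/O.

Conventions used throughout the package:

* Scan positions are given in **object pixels** as ``(y, x)`` pairs and denote
  the top-left corner of the probe window on the object canvas.
* A position splits into an integer part (window placement) and a subpixel
  part in ``[-0.5, 0.5)`` (band-limited probe shift); see
  :func:`ptycrisp.forward.split_shift`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ObjectField", "ProbeField", "ScanPlan", "DiffractionSet"]


def _check_finite(a: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite entries")


@dataclass
class ObjectField:
    """Complex object transmission function O on the full canvas.

    ``values`` is a dimensionless complex transmission map (|O| <= 1 for a
    passive specimen, though this is not enforced on reconstructions);
    ``pixel_pitch`` is the physical length per pixel, in the same units for
    object and probe.
    """

    values: np.ndarray
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("object must be a 2-D array")
        _check_finite(self.values, "object")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ProbeField:
    """Complex illumination probe P on the probe window (smaller than O)."""

    values: np.ndarray
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.ndim != 2:
            raise ValueError("probe must be a 2-D array")
        _check_finite(self.values, "probe")
        if not np.any(self.values):
            raise ValueError("probe must not be identically zero")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def energy(self) -> float:
        """Total field energy ||P||_F^2."""
        return float(np.sum(np.abs(self.values) ** 2))


@dataclass
class ScanPlan:
    """Ordered real-valued scan positions r_n (top-left, object pixels)."""

    positions: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array of (y, x)")
        if len(self.positions) < 1:
            raise ValueError("scan needs at least one position")
        _check_finite(self.positions, "positions")

    def __len__(self) -> int:
        return len(self.positions)

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer and subpixel parts of every position.

        ``s_int + s_sub == r`` exactly, with each subpixel component in
        ``[-0.5, 0.5)``.
        """
        from .forward import split_shift

        ints = np.empty_like(self.positions, dtype=np.int64)
        subs = np.empty_like(self.positions)
        for n, r in enumerate(self.positions):
            ints[n], subs[n] = split_shift(r)
        return ints, subs

    def validate_geometry(self, canvas_shape: tuple[int, int],
                          window: tuple[int, int]) -> None:
        """Raise if any probe window would fall outside the object canvas."""
        ints, _ = self.split()
        hi = np.asarray(canvas_shape) - np.asarray(window)
        if np.any(ints < 0) or np.any(ints > hi):
            raise ValueError("a probe window falls outside the object canvas")


@dataclass
class DiffractionSet:
    """N nonnegative diffraction intensity patterns matched to the probe window."""

    intensities: np.ndarray
    noise_model: str = "clean"  # "clean" | "poisson"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be an (N, H, W) stack")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        if self.noise_model not in ("clean", "poisson"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")

    def __len__(self) -> int:
        return len(self.intensities)

    @property
    def pattern_shape(self) -> tuple[int, int]:
        return self.intensities.shape[1:]
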