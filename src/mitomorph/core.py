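"""Core containers shared by every stage of the pipeline.

All images live on a regular 3D grid in (z, y, x) index order with a
physical voxel spacing in micrometres per axis.  Voxel centres sit at
``index * spacing``.  Every processing stage appends a provenance record,
so the exact chain of operations applied to a stack can be asserted and
archived with the outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

Spacing = tuple[float, float, float]


class ParameterError(ValueError):
    """A parameter violates an operation's preconditions."""


class GeometryError(ValueError):
    """A geometric object falls outside its allowed domain."""


class ContractError(RuntimeError):
    """Inputs violate a contract between pipeline stages."""


def _validate_spacing(spacing: Spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ParameterError(f"voxel spacing must be 3 positive values, got {spacing}")
    return spacing


@dataclass
class VolumetricImage:
    """A 3D scalar intensity grid with physical voxel spacing in µm."""

    data: np.ndarray
    spacing: Spacing
    provenance: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3D stack, got ndim={self.data.ndim}")
        if not np.all(np.isfinite(self.data)):
            raise ParameterError("intensities must be finite")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> np.ndarray:
        """Physical extent of the grid per axis in µm."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    def is_isotropic(self, rtol: float = 1e-3) -> bool:
        s = np.asarray(self.spacing)
        return bool(np.all(np.abs(s - s[0]) <= rtol * s[0]))

    def derive(self, data: np.ndarray, step: str,
               spacing: Spacing | None = None, **params: Any) -> "VolumetricImage":
        """New image carrying this image's provenance plus one record."""
        record = {"step": step, **params}
        return VolumetricImage(
            data=data,
            spacing=self.spacing if spacing is None else spacing,
            provenance=[*self.provenance, record],
        )

    def steps(self) -> list[str]:
        return [rec["step"] for rec in self.provenance]


@dataclass
class BinaryMask:
    """A boolean voxel grid sharing the geometry of its source image."""

    data: np.ndarray
    spacing: Spacing
    provenance: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise GeometryError(f"expected a 3D mask, got ndim={self.data.ndim}")
        self.spacing = _validate_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def volume(self) -> float:
        """Foreground volume in µm³ (voxel count × voxel volume)."""
        return float(self.data.sum()) * self.voxel_volume

    def is_isotropic(self, rtol: float = 1e-3) -> bool:
        s = np.asarray(self.spacing)
        return bool(np.all(np.abs(s - s[0]) <= rtol * s[0]))
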