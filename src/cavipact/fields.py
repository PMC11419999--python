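"""Scalar fields on physical grids, with TIFF + JSON-sidecar persistence.

Every image-like quantity in the pipeline (label maps, fluence, absorption,
initial pressure, reconstructions, filtered images) is a :class:`FieldMap`:
an array on a uniform grid with a physical pitch in millimetres and an
explicit origin.  Conventions: x increases rightward (columns), y increases
upward, row 0 is the top of the array; all geometry is stored in mm.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["FieldMap", "write_field", "read_field"]

#: recognised physical quantities a FieldMap can hold
QUANTITIES = ("labels", "fluence", "absorption", "initial_pressure", "image")


@dataclasses.dataclass
class FieldMap:
    """A 2-D (or 3-D) scalar field on a uniform physical grid.

    Parameters
    ----------
    values:
        Array of shape (rows, cols) or (rows, cols, planes).
    pitch:
        Grid spacing in mm (isotropic).
    origin:
        Physical (x, y) coordinates in mm of the centre of pixel
        ``values[0, 0]`` (top-left).  For 3-D fields the third axis is
        centred on z = 0.
    quantity:
        One of :data:`QUANTITIES`.
    meta:
        Free-form provenance (seed, photon count, config hash, ...).
    """

    values: np.ndarray
    pitch: float
    origin: tuple[float, float]
    quantity: str = "image"
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.pitch <= 0:
            raise ValueError(f"pitch must be positive, got {self.pitch}")
        if self.quantity not in QUANTITIES:
            raise ValueError(
                f"unknown quantity {self.quantity!r}; expected one of {QUANTITIES}"
            )
        if self.quantity != "labels" and not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    # ---- geometry -------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def x_coords(self) -> np.ndarray:
        """Physical x coordinate (mm) of each column centre."""
        return self.origin[0] + self.pitch * np.arange(self.shape[1])

    def y_coords(self) -> np.ndarray:
        """Physical y coordinate (mm) of each row centre (row 0 at top)."""
        return self.origin[1] - self.pitch * np.arange(self.shape[0])

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of (x, y) pixel-centre coordinates in mm."""
        return np.meshgrid(self.x_coords(), self.y_coords())

    def same_grid(self, other: "FieldMap") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.pitch, other.pitch)
            and np.allclose(self.origin, other.origin)
        )

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Fractional (row, col) indices of physical points (mm)."""
        col = (np.asarray(x) - self.origin[0]) / self.pitch
        row = (self.origin[1] - np.asarray(y)) / self.pitch
        return row, col

    def normalized(self) -> "FieldMap":
        """Min-max normalisation to [0, 1] (constant fields map to 0)."""
        v = self.values.astype(np.float64)
        lo, hi = float(v.min()), float(v.max())
        out = np.zeros_like(v) if hi == lo else (v - lo) / (hi - lo)
        return dataclasses.replace(self, values=out)


def centered_origin(shape: tuple[int, int], pitch: float) -> tuple[float, float]:
    """Origin placing the physical (0, 0) at the grid centre."""
    rows, cols = shape[:2]
    return (-pitch * (cols - 1) / 2.0, pitch * (rows - 1) / 2.0)


def write_field(field: FieldMap, path: str | Path) -> Path:
    """Write a FieldMap as float32 (or uint8 labels) TIFF plus JSON sidecar."""
    path = Path(path)
    dtype = np.uint8 if field.quantity == "labels" else np.float32
    tifffile.imwrite(path, field.values.astype(dtype))
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "pitch_mm": field.pitch,
                "origin_mm": list(field.origin),
                "quantity": field.quantity,
                "meta": field.meta,
            },
            indent=2,
            default=str,
        )
    )
    return path


def read_field(path: str | Path) -> FieldMap:
    path = Path(path)
    values = tifffile.imread(path)
    info = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return FieldMap(
        values=values,
        pitch=info["pitch_mm"],
        origin=tuple(info["origin_mm"]),
        quantity=info["quantity"],
        meta=info.get("meta", {}),
    )
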