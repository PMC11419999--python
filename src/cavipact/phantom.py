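"""Cavity-structure phantoms: media property tables and tube arrangements.

The phantom is a 5 cm cube of agarose substrate holding 1 mm-diameter sealed
tubes of blood, air or water, immersed in a water bath.  In the 2-D imaging
plane each tube is a disk.  Twelve named layouts are provided:

* ``s1``-``s3`` — single-medium controls (air, blood, water);
* ``s4``-``s6`` — three tubes in a horizontal row (blood-air-water,
  air-blood-water, air-water-blood);
* ``S1``-``S3`` — 3x3 single-medium matrix controls;
* ``S4``-``S6`` — 3x3 Latin squares whose first row matches the
  corresponding lowercase layout and whose remaining rows are cyclic
  shifts, so every medium appears exactly once per row and column.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import yaml

from .fields import FieldMap, centered_origin

__all__ = [
    "MediumProperties",
    "PhantomModel",
    "LABELS",
    "LABEL_NAMES",
    "UNIFORM_MEDIA",
    "MC_MEDIA",
    "MEASURED_MU_A_800NM",
    "ARRANGEMENTS",
    "build_arrangement",
    "rasterize",
    "voxelize",
    "blood_only_model",
    "is_latin_square",
    "save_phantom",
    "load_phantom",
]


@dataclasses.dataclass(frozen=True)
class MediumProperties:
    """Optical and acoustic properties of one medium.

    mu_a and mu_s are in 1/cm, g is the scattering anisotropy in [-1, 1],
    n the refractive index, sound_speed in m/s, density in kg/m^3.
    """

    name: str
    mu_a: float
    mu_s: float
    g: float
    n: float
    sound_speed: float
    density: float

    def __post_init__(self) -> None:
        if self.name not in LABELS:
            raise ValueError(f"unknown medium name {self.name!r}")
        if not -1.0 <= self.g <= 1.0:
            raise ValueError("anisotropy g must lie in [-1, 1]")
        if self.n < 1.0:
            raise ValueError("refractive index must be >= 1")
        if self.sound_speed <= 0 or self.density <= 0:
            raise ValueError("acoustic properties must be positive")


#: integer labels used in rasterised maps
LABELS = {"background": 0, "substrate": 1, "blood": 2, "air": 3, "water": 4}
LABEL_NAMES = {v: k for k, v in LABELS.items()}

# Acoustic values: the air tube is (340 m/s, 1.2 kg/m^3); every other region
# (substrate, blood, water, and the surrounding water bath) is water-like
# (1500 m/s, 1000 kg/m^3).
_AIR_AC = dict(sound_speed=340.0, density=1.2)
_WATER_AC = dict(sound_speed=1500.0, density=1000.0)

#: Uniform-light property table: only blood absorbs (mu_a = 3 /cm); the
#: substrate, air and water tubes are treated as non-absorbing.  Scattering
#: is irrelevant under uniform illumination and set to zero.
UNIFORM_MEDIA = {
    "background": MediumProperties("background", 0.0, 0.0, 0.0, 1.0, **_WATER_AC),
    "substrate": MediumProperties("substrate", 0.0, 0.0, 0.0, 1.0, **_WATER_AC),
    "blood": MediumProperties("blood", 3.0, 0.0, 0.0, 1.0, **_WATER_AC),
    "air": MediumProperties("air", 0.0, 0.0, 0.0, 1.0, **_AIR_AC),
    "water": MediumProperties("water", 0.0, 0.0, 0.0, 1.0, **_WATER_AC),
}

#: Monte-Carlo optical property table at 800 nm.  The agarose substrate
#: carries its measured 800 nm absorption (0.056 /cm) plus the weak
#: scattering of a plain 1% agarose gel (mu_s' ~ 0.2 /cm) and a
#: water-gel refractive index; this lets focused beams imprint visible
#: light paths on the absorption map, as seen in practice.
MC_MEDIA = {
    "background": MediumProperties("background", 0.0001, 0.1, 1.0, 1.0, **_WATER_AC),
    "substrate": MediumProperties("substrate", 0.056, 1.0, 0.8, 1.34, **_WATER_AC),
    "blood": MediumProperties("blood", 2.38, 522.0, 0.9, 1.4, **_WATER_AC),
    "air": MediumProperties("air", 0.001, 347.0, 0.001, 1.0, **_AIR_AC),
    "water": MediumProperties("water", 0.06, 1.0, 0.99, 1.3, **_WATER_AC),
}

#: Spectrophotometer absorption readings at 800 nm (1/cm), kept for
#: reference; the simulation uses the rounded UNIFORM_MEDIA values.
MEASURED_MU_A_800NM = {
    "substrate": 0.056362,
    "air": 0.015132,
    "blood": 2.994754,
    "water": 0.002734,
}


@dataclasses.dataclass
class PhantomModel:
    """Geometric description of one phantom in the imaging plane.

    inclusions is a list of (center_xy mm, radius mm, medium label).
    substrate_extent is (xmin, xmax, ymin, ymax) in mm.
    """

    substrate_extent: tuple[float, float, float, float]
    inclusions: list[tuple[tuple[float, float], float, str]]
    arrangement_id: str = "custom"
    spacing: float | None = None
    tube_length: float = 50.0  # mm, extrusion along the tube axis (z)

    def __post_init__(self) -> None:
        xmin, xmax, ymin, ymax = self.substrate_extent
        if not (xmin < xmax and ymin < ymax):
            raise ValueError("degenerate substrate extent")
        for (cx, cy), r, medium in self.inclusions:
            if medium not in LABELS:
                raise ValueError(f"unknown medium {medium!r}")
            if r <= 0:
                raise ValueError("inclusion radius must be positive")
            if not (xmin + r <= cx <= xmax - r and ymin + r <= cy <= ymax - r):
                raise ValueError(
                    f"inclusion at ({cx}, {cy}) r={r} extends outside the substrate"
                )
        for i, ((ax, ay), ar, _) in enumerate(self.inclusions):
            for (bx, by), br, _ in self.inclusions[i + 1 :]:
                if np.hypot(ax - bx, ay - by) < ar + br:
                    raise ValueError("inclusions overlap")

    def positions_of(self, medium: str) -> list[tuple[float, float]]:
        return [c for c, _, m in self.inclusions if m == medium]


# Layout table: row-major medium grids.  Lowercase = one row in the imaging
# plane; uppercase = 3x3 matrix.  S4-S6 first rows match s4-s6 and the
# remaining rows are right cyclic shifts of the row above.
def _cyclic(row: tuple[str, ...]) -> list[tuple[str, ...]]:
    out = [row]
    for _ in range(2):
        r = out[-1]
        out.append((r[-1],) + r[:-1])
    return out


ARRANGEMENTS: dict[str, list[tuple[str, ...]]] = {
    "s1": [("air",)],
    "s2": [("blood",)],
    "s3": [("water",)],
    "s4": [("blood", "air", "water")],
    "s5": [("air", "blood", "water")],
    "s6": [("air", "water", "blood")],
    "S1": [("air",) * 3] * 3,
    "S2": [("blood",) * 3] * 3,
    "S3": [("water",) * 3] * 3,
    "S4": _cyclic(("blood", "air", "water")),
    "S5": _cyclic(("air", "blood", "water")),
    "S6": _cyclic(("air", "water", "blood")),
}


def build_arrangement(
    arrangement_id: str,
    tube_radius: float = 0.5,
    spacing: float = 10.0,
    substrate_half: float = 25.0,
) -> PhantomModel:
    """Build the phantom for one named layout.

    Parameters
    ----------
    arrangement_id:
        One of s1-s6 / S1-S6.
    tube_radius:
        Tube radius in mm (default 0.5, i.e. the 1 mm simulated diameter;
        use 0.45 for the 0.9 mm physical tubes).
    spacing:
        Centre-to-centre tube spacing in mm.  The inter-tube spacing is not
        prescribed by the study geometry, so it is configurable and echoed
        in the model.
    """
    if arrangement_id not in ARRANGEMENTS:
        raise ValueError(
            f"unknown arrangement {arrangement_id!r}; valid labels are "
            + ", ".join(sorted(ARRANGEMENTS))
        )
    if spacing <= 2 * tube_radius:
        raise ValueError("spacing must exceed the tube diameter")
    rows = ARRANGEMENTS[arrangement_id]
    n_rows, n_cols = len(rows), len(rows[0])
    inclusions = []
    for i, row in enumerate(rows):
        y = spacing * ((n_rows - 1) / 2.0 - i)  # row 0 at top
        for j, medium in enumerate(row):
            x = spacing * (j - (n_cols - 1) / 2.0)
            inclusions.append(((x, y), tube_radius, medium))
    half = substrate_half
    return PhantomModel(
        substrate_extent=(-half, half, -half, half),
        inclusions=inclusions,
        arrangement_id=arrangement_id,
        spacing=spacing,
    )


def blood_only_model(model: PhantomModel) -> PhantomModel:
    """The paired artifact-free phantom: same geometry, blood tubes only."""
    return PhantomModel(
        substrate_extent=model.substrate_extent,
        inclusions=[inc for inc in model.inclusions if inc[2] == "blood"],
        arrangement_id=model.arrangement_id + "-blood-only",
        spacing=model.spacing,
        tube_length=model.tube_length,
    )


def is_latin_square(model: PhantomModel) -> bool:
    """Check that a 3x3 arrangement places each medium once per row/column."""
    rows = ARRANGEMENTS.get(model.arrangement_id)
    if rows is None or len(rows) != 3:
        return False
    media = set(rows[0])
    if len(media) != 3:
        return False
    for i in range(3):
        if set(rows[i]) != media:
            return False
        if {rows[r][i] for r in range(3)} != media:
            return False
    return True


def rasterize(
    model: PhantomModel,
    grid_shape: tuple[int, int] = (121, 121),
    pitch: float = 1.0,
) -> FieldMap:
    """Discretise a phantom onto a pixel grid by strict centre-in-region.

    Each pixel takes the label of the medium containing its centre; pixels
    outside the substrate are background.  Deterministic and idempotent.
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    origin = centered_origin(grid_shape, pitch)
    xs = origin[0] + pitch * np.arange(grid_shape[1])
    ys = origin[1] - pitch * np.arange(grid_shape[0])
    xmin, xmax, ymin, ymax = model.substrate_extent
    if xs[0] > xmin or xs[-1] < xmax or ys[-1] > ymin or ys[0] < ymax:
        raise ValueError("grid does not cover the substrate extent")
    X, Y = np.meshgrid(xs, ys)
    labels = np.zeros(grid_shape, dtype=np.uint8)
    in_sub = (X >= xmin) & (X <= xmax) & (Y >= ymin) & (Y <= ymax)
    labels[in_sub] = LABELS["substrate"]
    for (cx, cy), r, medium in model.inclusions:
        inside = (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
        labels[inside] = LABELS[medium]
        # a tube narrower than one cell still marks its centre cell
        row, col = np.unravel_index(
            np.argmin((X - cx) ** 2 + (Y - cy) ** 2), grid_shape
        )
        labels[row, col] = LABELS[medium]
    return FieldMap(labels, pitch, origin, quantity="labels",
                    meta={"arrangement_id": model.arrangement_id,
                          "spacing_mm": model.spacing})


def voxelize(
    model: PhantomModel,
    grid_shape: tuple[int, int, int] = (120, 120, 120),
    pitch: float = 1.0,
) -> FieldMap:
    """3-D label volume: the 2-D plane map extruded along the tube axis (z).

    Tubes span ``tube_length`` centred on z = 0; the substrate cube spans
    its full extent in z as well.  Outside the cube is background.
    """
    plane = rasterize(model, grid_shape[:2], pitch)
    nz = grid_shape[2]
    z = pitch * (np.arange(nz) - (nz - 1) / 2.0)
    vol = np.zeros(grid_shape, dtype=np.uint8)
    half_len = model.tube_length / 2.0
    xmin, xmax, ymin, ymax = model.substrate_extent
    sub_half = (ymax - ymin) / 2.0
    in_cube = np.abs(z) <= sub_half
    in_tube = np.abs(z) <= half_len
    sub_plane = np.where(plane.values != LABELS["background"],
                         LABELS["substrate"], LABELS["background"]).astype(np.uint8)
    for k in range(nz):
        if in_tube[k] and in_cube[k]:
            vol[:, :, k] = plane.values
        elif in_cube[k]:
            vol[:, :, k] = sub_plane
    return FieldMap(vol, pitch, plane.origin, quantity="labels",
                    meta=dict(plane.meta))


# ---- YAML persistence ---------------------------------------------------


def save_phantom(model: PhantomModel, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "arrangement_id": model.arrangement_id,
        "spacing_mm": model.spacing,
        "substrate_extent_mm": list(model.substrate_extent),
        "tube_length_mm": model.tube_length,
        "inclusions": [
            {"center_mm": list(c), "radius_mm": r, "medium": m}
            for c, r, m in model.inclusions
        ],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_phantom(path: str | Path) -> PhantomModel:
    doc = yaml.safe_load(Path(path).read_text())
    return PhantomModel(
        substrate_extent=tuple(doc["substrate_extent_mm"]),
        inclusions=[
            (tuple(i["center_mm"]), i["radius_mm"], i["medium"])
            for i in doc["inclusions"]
        ],
        arrangement_id=doc.get("arrangement_id", "custom"),
        spacing=doc.get("spacing_mm"),
        tube_length=doc.get("tube_length_mm", 50.0),
    )
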