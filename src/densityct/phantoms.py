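"""Digital 2D phantoms: labelled material grids plus analysis ROIs.

Three families mirror the physical phantoms commonly used for density
calibration and dose QA:

* a water-equivalent calibration cylinder with tissue-substitute inserts
  (Gammex-467 style),
* the same cylinder layout with titanium and stainless-steel plugs
  (CIRS CBCT electron-density style),
* a rectangular solid-water slab stack with plaster, cork and air
  cavities (IMRT slab style),

plus a qualitative elliptical body phantom.  Phantoms are transverse 2D
slices; the 2 cm spherical averaging ROIs of the physical protocol
become 2 cm circles.  Rasterization samples pixel centers (optionally
4x supersampled) and is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .physics import ConfigurationError, Material, material_library

__all__ = [
    "PhantomImage",
    "RoiSpec",
    "make_calibration_phantom",
    "make_cbct_metal_phantom",
    "make_slab_phantom",
    "make_body_phantom",
    "DEFAULT_INSERTS",
    "CBCT_INSERTS",
]


@dataclass(frozen=True)
class RoiSpec:
    """Circular analysis region; center in mm relative to the grid center."""

    name: str
    center: tuple[float, float]
    diameter: float = 20.0

    def __post_init__(self):
        if self.diameter <= 0:
            raise ConfigurationError(f"ROI {self.name}: diameter must be positive")


@dataclass
class PhantomImage:
    """Label grid with a material map; pixel (0,0) is the top-left corner.

    Physical x runs along columns, y along rows; the coordinate origin is
    the grid center, matching the scanner isocenter.
    """

    label_grid: np.ndarray  # 2D int
    pixel_size: float  # mm
    material_map: dict[int, Material]

    def __post_init__(self):
        if self.label_grid.ndim != 2:
            raise ConfigurationError("label grid must be 2D")
        if self.pixel_size <= 0:
            raise ConfigurationError("pixel size must be positive")
        missing = set(np.unique(self.label_grid)) - set(self.material_map)
        if missing:
            raise ConfigurationError(f"labels without material: {sorted(missing)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.label_grid.shape

    def coordinates(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel-center physical coordinates (x, y) in mm."""
        ny, nx = self.label_grid.shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_size
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.pixel_size
        return np.meshgrid(x, y)

    def material_of(self, name: str) -> Material:
        for mat in self.material_map.values():
            if mat.name == name:
                return mat
        raise KeyError(name)

    def red_map(self) -> np.ndarray:
        """Ground-truth RED image (the oracle for reconstruction tests)."""
        reds = {lbl: m.red for lbl, m in self.material_map.items()}
        out = np.zeros(self.label_grid.shape)
        for lbl, r in reds.items():
            out[self.label_grid == lbl] = r
        return out

    def save(self, prefix) -> None:
        """Write the label grid as CSV of ints plus a JSON material sidecar."""
        np.savetxt(f"{prefix}_labels.csv", self.label_grid, fmt="%d", delimiter=",")
        side = {
            "pixel_size_mm": self.pixel_size,
            "materials": {str(k): m.to_dict() for k, m in self.material_map.items()},
        }
        with open(f"{prefix}.json", "w") as fh:
            json.dump(side, fh, indent=1)

    @classmethod
    def load(cls, prefix) -> "PhantomImage":
        grid = np.loadtxt(f"{prefix}_labels.csv", delimiter=",", dtype=int)
        with open(f"{prefix}.json") as fh:
            side = json.load(fh)
        mats = {int(k): Material.from_dict(d) for k, d in side["materials"].items()}
        return cls(grid, float(side["pixel_size_mm"]), mats)


def _circle_mask(xx, yy, cx, cy, radius, supersample=1):
    if supersample <= 1:
        return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    # Area-weighted membership via sub-pixel sampling, thresholded at 50%.
    px = xx[0, 1] - xx[0, 0]
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    frac = np.zeros(xx.shape)
    for ox in offs:
        for oy in offs:
            frac += (xx + ox * px - cx) ** 2 + (yy + oy * px - cy) ** 2 <= radius**2
    return frac >= (supersample**2) / 2.0


# Default calibration-insert ring: (material, RED spans 0.2 - 1.7).
DEFAULT_INSERTS = (
    "lung_inhale", "lung_exhale", "adipose", "breast", "muscle",
    "liver", "bone_200", "bone_800", "bone_1250", "water",
)

# CBCT-style phantom: tissue ring plus metal plugs.
CBCT_INSERTS = DEFAULT_INSERTS[:9] + ("titanium", "steel")


def _ring_positions(n, ring_radius, start_deg=90.0):
    ang = np.deg2rad(start_deg) - 2 * np.pi * np.arange(n) / n
    return [(ring_radius * np.cos(a), ring_radius * np.sin(a)) for a in ang]


def _insert_cylinder(inserts, *, size, pixel_size, body_radius, ring_radius,
                     insert_diameter, metal_diameter, supersample, library):
    """Shared builder for the calibration and CBCT cylinders."""
    if not inserts:
        raise ConfigurationError("insert list must not be empty")
    lib = library or material_library()
    names = list(inserts)
    metals = {"titanium", "steel", "brass"}
    positions = _ring_positions(len(names), ring_radius)
    diam = [metal_diameter if n in metals else insert_diameter for n in names]
    # reject overlapping inserts
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            d = np.hypot(positions[i][0] - positions[j][0],
                         positions[i][1] - positions[j][1])
            if d < (diam[i] + diam[j]) / 2.0:
                raise ConfigurationError(
                    f"inserts {names[i]} and {names[j]} overlap"
                )

    mats = [lib["air"], lib["water"]]
    for n in names:
        mats.append(lib[n])
    grid = np.zeros((size, size), dtype=int)
    phantom = PhantomImage(grid, pixel_size, dict(enumerate(mats)))
    xx, yy = phantom.coordinates()
    grid[_circle_mask(xx, yy, 0, 0, body_radius, supersample)] = 1
    rois = []
    for k, (name, (cx, cy), d) in enumerate(zip(names, positions, diam)):
        if np.hypot(cx, cy) + d / 2.0 > body_radius:
            raise ConfigurationError(f"insert {name} extends outside the body")
        grid[_circle_mask(xx, yy, cx, cy, d / 2.0, supersample)] = 2 + k
        roi_d = min(20.0, d - 2 * pixel_size)
        rois.append(RoiSpec(name, (cx, cy), roi_d))
    return phantom, rois


def _scaled(value, size, pixel_size, fraction):
    """Default geometry scales with the field of view (256 mm reference)."""
    return value if value is not None else fraction * size * pixel_size


def make_calibration_phantom(inserts=DEFAULT_INSERTS, *, size=256, pixel_size=1.0,
                             body_radius=None, ring_radius=None,
                             insert_diameter=None, supersample=1, library=None):
    """Water cylinder with a ring of tissue-substitute inserts.

    Returns the phantom and one 2 cm ROI per insert, centered on it
    (ROIs shrink to fit smaller inserts on coarse grids).  Geometry
    defaults scale with the field of view: a 100 mm body with 28 mm
    inserts on a 62 mm ring at the default 256 mm.
    """
    fov = (size, pixel_size)
    return _insert_cylinder(
        inserts, size=size, pixel_size=pixel_size,
        body_radius=_scaled(body_radius, *fov, 100 / 256),
        ring_radius=_scaled(ring_radius, *fov, 62 / 256),
        insert_diameter=_scaled(insert_diameter, *fov, 28 / 256),
        metal_diameter=_scaled(None, *fov, 12 / 256),
        supersample=supersample, library=library)


def make_cbct_metal_phantom(inserts=CBCT_INSERTS, *, include_metals=True,
                            size=256, pixel_size=1.0, body_radius=None,
                            ring_radius=None, insert_diameter=None,
                            metal_diameter=None, supersample=1, library=None):
    """Insert cylinder with titanium and stainless-steel plugs.

    With ``include_metals=False`` the metal plugs are dropped and the
    layout reduces to the calibration configuration.
    """
    names = list(inserts)
    if not include_metals:
        names = [n for n in names if n not in ("titanium", "steel", "brass")]
    fov = (size, pixel_size)
    return _insert_cylinder(
        names, size=size, pixel_size=pixel_size,
        body_radius=_scaled(body_radius, *fov, 100 / 256),
        ring_radius=_scaled(ring_radius, *fov, 62 / 256),
        insert_diameter=_scaled(insert_diameter, *fov, 28 / 256),
        metal_diameter=_scaled(metal_diameter, *fov, 12 / 256),
        supersample=supersample, library=library)


def make_slab_phantom(*, size=256, pixel_size=1.0, slab_width=None,
                      slab_height=None, cavity_size=None,
                      cavity_depth=0.0, supersample=1, library=None):
    """Solid-water slab stack with two plaster blocks, cork and an air cavity.

    The four cavities sit side by side at depth ``cavity_depth`` mm below
    the slab midline (beam entry is the top edge).  ROIs cover each cavity
    and a solid-water reference region.
    """
    lib = library or material_library()
    fov = (size, pixel_size)
    slab_width = _scaled(slab_width, *fov, 220 / 256)
    slab_height = _scaled(slab_height, *fov, 180 / 256)
    if cavity_size is None:
        cavity_size = (_scaled(None, *fov, 30 / 256),) * 2
    order = ["plaster", "cork", "air", "plaster"]
    mats = [lib["air"], lib["solid_water"], lib["plaster"], lib["cork"], lib["air"]]
    label_of = {"plaster": 2, "cork": 3, "air": 4}
    grid = np.zeros((size, size), dtype=int)
    phantom = PhantomImage(grid, pixel_size, dict(enumerate(mats)))
    xx, yy = phantom.coordinates()
    in_slab = (np.abs(xx) <= slab_width / 2.0) & (np.abs(yy) <= slab_height / 2.0)
    grid[in_slab] = 1
    w, h = cavity_size
    pitch = slab_width / (len(order) + 0.5)
    rois = []
    for k, name in enumerate(order):
        cx = (k - (len(order) - 1) / 2.0) * pitch
        cy = cavity_depth
        blk = (np.abs(xx - cx) <= w / 2.0) & (np.abs(yy - cy) <= h / 2.0)
        if not (np.abs(cx) + w / 2.0 <= slab_width / 2.0
                and np.abs(cy) + h / 2.0 <= slab_height / 2.0):
            raise ConfigurationError(f"cavity {name} extends outside the slab")
        grid[blk] = label_of[name]
        roi_d = min(20.0, min(w, h) - 2 * pixel_size)
        suffix = ("_left", "_right")[k > len(order) // 2] \
            if order.count(name) > 1 else ""
        rois.append(RoiSpec(f"{name}{suffix}", (cx, cy), roi_d))
    rois.append(RoiSpec("solid_water", (0.0, -slab_height / 2.0 + 0.15 * slab_height),
                        min(20.0, 0.2 * slab_height)))
    return phantom, rois


def make_body_phantom(*, size=256, pixel_size=1.5, supersample=1, library=None):
    """Elliptical body with lung, bone and an air pocket.

    Qualitative stand-in for anthropomorphic geometry; not matched to any
    physical phantom and used only for demonstration plans.
    """
    lib = library or material_library()
    mats = [lib["air"], lib["muscle"], lib["lung_inhale"],
            lib["bone_800"], lib["air"]]
    grid = np.zeros((size, size), dtype=int)
    phantom = PhantomImage(grid, pixel_size, dict(enumerate(mats)))
    xx, yy = phantom.coordinates()
    a, b = size * pixel_size * 0.42, size * pixel_size * 0.30
    body = (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
    grid[body] = 1
    for sx in (-1, 1):
        lung = ((xx - sx * a * 0.45) / (a * 0.30)) ** 2 + (yy / (b * 0.55)) ** 2 <= 1.0
        grid[lung & body] = 2
    spine = _circle_mask(xx, yy, 0, b * 0.55, 0.09 * a, supersample)
    grid[spine & body] = 3
    pocket = _circle_mask(xx, yy, 0, -b * 0.45, 0.06 * a, supersample)
    grid[pocket & body] = 4
    rois = [RoiSpec("spine", (0.0, b * 0.55), min(20.0, 0.16 * a)),
            RoiSpec("air_pocket", (0.0, -b * 0.45), min(20.0, 0.10 * a)),
            RoiSpec("lung_left", (-a * 0.45, 0.0), 20.0)]
    return phantom, rois
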