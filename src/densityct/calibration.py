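"""Conventional HU reconstruction and CT-number-to-RED calibration.

The HU chain water-corrects the polyenergetic sinogram (per-ray lookup of
the water-equivalent thickness built from simulated water slabs for the
same spectrum), reconstructs, and scales to Hounsfield units at the
spectrum's effective energy, so water reads ~0 HU and air ~-1000 HU at
every tube voltage while bone-like materials stay voltage dependent.

Calibration curves map image values to RED through ordered control
points obtained from insert ROI statistics.  Conversion interpolates
piecewise-linearly; beyond the last control point (nominally RED 1.7,
where tissue-substitute curves end) the behaviour is a policy choice:
'clamp' holds the last RED — the conservative clinical setting — while
'extrapolate' continues the last straight-line segment, which is what a
TPS does when metals are read through a tissue curve and is required to
reproduce voltage-dependent metal readings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .physics import ConfigurationError, Spectrum, WATER, linear_attenuation
from .phantoms import PhantomImage, RoiSpec
from .projector import (Geometry, ReconImage, Sinogram, default_geometry,
                        fbp, forward_project)

__all__ = [
    "CalibrationCurve",
    "RoiStats",
    "hu_reconstruct",
    "water_correction_table",
    "roi_stats",
    "build_curve",
    "image_to_red",
    "red_profile",
    "dd_reference_curve",
    "HU_FLOOR",
    "HU_CAP",
]

RED_MAX_DEFAULT = 1.7
HU_FLOOR = -1024.0
HU_CAP = 3071.0  # 12-bit CT integer range


@dataclass(frozen=True)
class RoiStats:
    name: str
    mean: float
    sd: float
    n_pixels: int

    def __post_init__(self):
        if self.sd < 0 or self.n_pixels <= 0:
            raise ConfigurationError("invalid ROI statistics")


@dataclass(frozen=True)
class CalibrationCurve:
    """Ordered (image value -> RED) control points.

    ``kvp`` is the tube voltage the curve belongs to, or "DD" for the
    voltage-independent direct-density curve.  ``slope``/``intercept``
    hold the least-squares line of RED against image value.
    """

    points: tuple[tuple[float, float], ...]
    kvp: str = "DD"
    red_max: float = RED_MAX_DEFAULT
    above_range: str = "clamp"  # or "extrapolate"
    slope: float = float("nan")
    intercept: float = float("nan")

    def __post_init__(self):
        xs = np.array([p[0] for p in self.points])
        rs = np.array([p[1] for p in self.points])
        if len(self.points) < 2:
            raise ConfigurationError("curve needs at least two control points")
        if not np.all(np.diff(xs) > 0):
            raise ConfigurationError("image values must be strictly increasing")
        if (rs < 0).any() or not np.all(np.diff(rs) >= 0):
            raise ConfigurationError("REDs must be non-negative and non-decreasing")
        if self.above_range not in ("clamp", "extrapolate"):
            raise ConfigurationError("above_range must be 'clamp' or 'extrapolate'")

    def to_csv(self, path) -> None:
        arr = np.asarray(self.points)
        np.savetxt(path, arr, delimiter=",", header="image_value,red", comments="")

    @classmethod
    def from_csv(cls, path, kvp="DD", **kw) -> "CalibrationCurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(tuple(map(tuple, arr)), kvp=kvp, **kw)


def water_correction_table(spectrum: Spectrum, *, max_cm: float = 50.0,
                           n: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """(water thickness cm, polyenergetic log attenuation) lookup pairs."""
    mu_w = np.asarray(linear_attenuation(WATER, spectrum.energies))
    d = np.linspace(0.0, max_cm, n)
    s = -np.log(np.exp(-np.outer(d, mu_w)) @ spectrum.weights)
    return d, s


def hu_reconstruct(phantom: PhantomImage, spectrum: Spectrum,
                   geometry: Geometry | None = None, *,
                   apodization: str = "hann", photons: float | None = None,
                   seed: int | None = None,
                   path_lengths: np.ndarray | None = None,
                   s_mu: Sinogram | None = None) -> ReconImage:
    """Water-corrected FBP scaled to Hounsfield units.

    Each measured log attenuation is replaced by mu_w(E_eff) times the
    water-equivalent thickness that would have produced it, which removes
    cupping for water-like objects; HU = 1000 (mu - mu_w)/mu_w at the
    effective energy, clipped to the 12-bit CT range.
    """
    geometry = geometry or default_geometry(phantom)
    if s_mu is None:
        s_mu = forward_project(phantom, spectrum, geometry, photons=photons,
                               seed=seed, path_lengths=path_lengths)
    d, s = water_correction_table(spectrum)
    d_weq = np.interp(s_mu.values, s, d)
    mu_w_eff = float(linear_attenuation(WATER, spectrum.mean_energy))
    corrected = Sinogram(d_weq * mu_w_eff, geometry, kind="mu")
    img = fbp(corrected, apodization=apodization,
              output_size=max(phantom.shape), pixel_size=phantom.pixel_size)
    hu = 1000.0 * (img.values - mu_w_eff) / mu_w_eff
    hu = np.clip(hu, HU_FLOOR, HU_CAP)
    return ReconImage(hu, img.pixel_size, "hu")


def roi_stats(image: ReconImage, roi: RoiSpec) -> RoiStats:
    """Mean/SD over pixels whose centers fall inside the ROI disk."""
    xx, yy = image.coordinates()
    cx, cy = roi.center
    mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= (roi.diameter / 2.0) ** 2
    if not mask.any():
        raise ConfigurationError(f"ROI {roi.name} covers no pixel centers")
    vals = image.values[mask]
    return RoiStats(roi.name, float(vals.mean()), float(vals.std()), int(vals.size))


def _pava(values: np.ndarray) -> np.ndarray:
    """Non-decreasing projection (pool adjacent violators, equal weights)."""
    level = list(values.astype(float))
    count = [1] * len(level)
    i = 0
    while i < len(level) - 1:
        if level[i] > level[i + 1] + 1e-15:
            merged = (level[i] * count[i] + level[i + 1] * count[i + 1]) \
                / (count[i] + count[i + 1])
            level[i: i + 2] = [merged]
            count[i: i + 2] = [count[i] + count[i + 1]]
            i = max(i - 1, 0)
        else:
            i += 1
    return np.repeat(level, count)


def build_curve(stats: list[tuple[RoiStats, float]], kvp="DD", *,
                red_max: float = RED_MAX_DEFAULT,
                above_range: str = "clamp") -> CalibrationCurve:
    """Calibration curve from (ROI statistics, true RED) pairs.

    Control points are sorted by image value; the least-squares line of
    RED against image value is reported alongside.  Inserts whose
    reading order disagrees with their REDs (nearly equal tissues read
    through noise) are pooled to the isotonic projection, as a monotone
    conversion table requires.
    """
    if len(stats) < 2:
        raise ConfigurationError("need at least two inserts")
    pts = sorted((s.mean, red) for s, red in stats)
    xs = np.array([p[0] for p in pts])
    if np.any(np.diff(xs) == 0):
        raise ConfigurationError("duplicate image values among inserts")
    rs = np.array([p[1] for p in pts])
    slope, intercept = np.polyfit(xs, rs, 1)
    pts = tuple(zip(xs.tolist(), _pava(rs).tolist()))
    return CalibrationCurve(pts, kvp=str(kvp),
                            red_max=red_max, above_range=above_range,
                            slope=float(slope), intercept=float(intercept))


def dd_reference_curve(*, above_range: str = "clamp") -> CalibrationCurve:
    """The published direct-density straight line RED = 0.001 v + 0.994.

    Control points span image values from air (-994) to the RED-1.7
    point (706); the fitted slope/intercept are exact by construction.
    """
    xs = (-994.0, 6.0, 706.0)
    pts = tuple((x, 0.001 * x + 0.994) for x in xs)
    return CalibrationCurve(pts, kvp="DD", above_range=above_range,
                            slope=0.001, intercept=0.994)


def _convert(values: np.ndarray, curve: CalibrationCurve) -> np.ndarray:
    xs = np.array([p[0] for p in curve.points])
    rs = np.array([p[1] for p in curve.points])
    out = np.interp(values, xs, rs)
    lo_slope = (rs[1] - rs[0]) / (xs[1] - xs[0])
    below = values < xs[0]
    out = np.where(below, rs[0] + (values - xs[0]) * lo_slope, out)
    if curve.above_range == "extrapolate":
        hi_slope = (rs[-1] - rs[-2]) / (xs[-1] - xs[-2])
        above = values > xs[-1]
        out = np.where(above, rs[-1] + (values - xs[-1]) * hi_slope, out)
    else:
        out = np.minimum(out, curve.red_max)
    return np.maximum(out, 0.0)


def image_to_red(image: ReconImage, curve: CalibrationCurve) -> ReconImage:
    """Convert an image-value image to RED through a calibration curve.

    Piecewise-linear between control points; below the lowest point the
    first segment extrapolates but the result is floored at 0; above the
    highest point the curve's above-range policy applies (clamp at
    ``red_max`` by default).  Monotone non-decreasing by construction.
    """
    return ReconImage(_convert(image.values, curve), image.pixel_size, "red")


def red_profile(image: ReconImage, start: tuple[float, float],
                end: tuple[float, float], *, step: float = 0.5) -> np.ndarray:
    """Bilinear line profile: columns (position mm, value), 0.5 mm steps."""
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    length = float(np.hypot(*(end - start)))
    n = max(int(np.floor(length / step)) + 1, 2)
    pos = np.linspace(0.0, length, n)
    pts = start[None, :] + (pos / length)[:, None] * (end - start)[None, :]
    ny, nx = image.values.shape
    cols = pts[:, 0] / image.pixel_size + (nx - 1) / 2.0
    rows = pts[:, 1] / image.pixel_size + (ny - 1) / 2.0
    vals = map_coordinates(image.values, [rows, cols], order=1, mode="nearest")
    return np.column_stack([pos, vals])
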