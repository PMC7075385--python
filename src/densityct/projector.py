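"""Virtual parallel-beam scanner: exact ray tracing, polyenergetic forward
projection with optional Poisson noise, and filtered back projection.

Ray tracing is Siddon-style: every ray is intersected with the pixel-grid
lines, so chord lengths through labelled regions are exact and analytic
chord tests hold to rasterization accuracy.  The same tracer backs both
the polyenergetic projector (per-material path lengths) and the linear
re-projector used on reconstructed images.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .physics import ConfigurationError, Spectrum, linear_attenuation
from .phantoms import PhantomImage

__all__ = [
    "Geometry",
    "Sinogram",
    "ReconImage",
    "default_geometry",
    "material_path_lengths",
    "forward_project",
    "forward_project_image",
    "fbp",
]


@dataclass(frozen=True)
class Geometry:
    """Parallel-beam acquisition geometry."""

    n_angles: int = 180
    angular_range: float = 180.0  # degrees
    n_detectors: int = 367
    detector_pitch: float = 1.0  # mm

    def __post_init__(self):
        if self.n_angles < 1 or self.n_detectors < 1:
            raise ConfigurationError("geometry needs positive counts")
        if self.detector_pitch <= 0:
            raise ConfigurationError("detector pitch must be positive")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_angles) * self.angular_range / self.n_angles

    @property
    def detector_offsets(self) -> np.ndarray:
        """Detector-center offsets from the rotation axis, mm."""
        return (np.arange(self.n_detectors) - (self.n_detectors - 1) / 2.0) \
            * self.detector_pitch


def default_geometry(phantom: PhantomImage, n_angles: int = 180) -> Geometry:
    """Geometry whose detector row spans the phantom diagonal."""
    n = max(phantom.shape)
    span = int(np.ceil(n * np.sqrt(2))) + 4
    span += 1 - span % 2  # odd, so one detector sits on the axis
    return Geometry(n_angles=n_angles, n_detectors=span,
                    detector_pitch=phantom.pixel_size)


@dataclass
class Sinogram:
    """Projection-domain data: (angle, detector) line integrals.

    ``kind`` tags the physical meaning: 'mu' for polyenergetic
    log-attenuation, 'linear' for line integrals of image values
    (value x cm), 'bone' and 'red' for the decomposition products.
    """

    values: np.ndarray
    geometry: Geometry
    kind: str = "mu"

    def __post_init__(self):
        if self.values.shape != (self.geometry.n_angles, self.geometry.n_detectors):
            raise ConfigurationError("sinogram shape does not match geometry")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("sinogram contains non-finite values")

    def save(self, prefix, **meta) -> None:
        np.savetxt(f"{prefix}.csv", self.values, delimiter=",")
        side = {"kind": self.kind, "n_angles": self.geometry.n_angles,
                "angular_range": self.geometry.angular_range,
                "n_detectors": self.geometry.n_detectors,
                "detector_pitch": self.geometry.detector_pitch, **meta}
        with open(f"{prefix}.json", "w") as fh:
            json.dump(side, fh, indent=1)


@dataclass
class ReconImage:
    """Reconstructed 2D image with physical pixel size and value semantics.

    semantics: 'attenuation' (1/cm), 'image-value', 'hu', 'red' or
    'bone-mask'.
    """

    values: np.ndarray
    pixel_size: float
    semantics: str = "attenuation"

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("image contains non-finite values")

    @property
    def shape(self):
        return self.values.shape

    def coordinates(self):
        ny, nx = self.values.shape
        x = (np.arange(nx) - (nx - 1) / 2.0) * self.pixel_size
        y = (np.arange(ny) - (ny - 1) / 2.0) * self.pixel_size
        return np.meshgrid(x, y)

    def save(self, prefix, **meta) -> None:
        np.savetxt(f"{prefix}.csv", self.values, delimiter=",")
        with open(f"{prefix}.json", "w") as fh:
            json.dump({"pixel_size_mm": self.pixel_size,
                       "semantics": self.semantics, **meta}, fh, indent=1)


# ---------------------------------------------------------------------------
# Ray tracing
# ---------------------------------------------------------------------------

def _angle_segments(shape, pixel_mm, geometry, theta_deg):
    """Exact ray/pixel intersections for all detectors at one view angle.

    Returns flat arrays (detector index, row, col, segment length in cm)
    for every ray segment inside the grid.  Rays are parametrized as
    ``P(s) = t*v + s*u`` with detector axis v = (cos t, sin t) and ray
    direction u = (-sin t, cos t).
    """
    ny, nx = shape
    th = np.deg2rad(theta_deg)

    def _snap(c):
        # exact zeros at the cardinal angles, so edge-aligned rays break
        # pixel ties identically at 0 and 90 degrees
        return 0.0 if abs(c) < 1e-12 else float(c)

    vx, vy = _snap(np.cos(th)), _snap(np.sin(th))
    ux, uy = -vy, vx
    t = geometry.detector_offsets[:, None]

    x_edges = (np.arange(nx + 1) - nx / 2.0) * pixel_mm
    y_edges = (np.arange(ny + 1) - ny / 2.0) * pixel_mm

    big = 1e12
    sx = ((x_edges[None, :] - t * vx) / ux) if abs(ux) > 1e-12 \
        else np.full((t.size, nx + 1), big)
    sy = ((y_edges[None, :] - t * vy) / uy) if abs(uy) > 1e-12 \
        else np.full((t.size, ny + 1), big)
    s = np.sort(np.concatenate([sx, sy], axis=1), axis=1)

    s0, s1 = s[:, :-1], s[:, 1:]
    length_mm = s1 - s0
    smid = 0.5 * (s0 + s1)
    xm = t * vx + smid * ux
    ym = t * vy + smid * uy
    col = np.floor((xm - x_edges[0]) / pixel_mm).astype(np.int64)
    row = np.floor((ym - y_edges[0]) / pixel_mm).astype(np.int64)
    ok = (length_mm > 1e-12) & (col >= 0) & (col < nx) & (row >= 0) & (row < ny) \
        & (np.abs(smid) < big / 2)
    det = np.broadcast_to(np.arange(t.size)[:, None], ok.shape)
    return det[ok], row[ok], col[ok], length_mm[ok] / 10.0


def material_path_lengths(phantom: PhantomImage, geometry: Geometry) -> np.ndarray:
    """Per-ray chord length through every material label, cm.

    Returns an array of shape (n_labels, n_angles, n_detectors).  This is
    the expensive geometric step; it depends only on the label grid and
    geometry, so callers reuse it across tube voltages.
    """
    labels = phantom.label_grid
    n_lab = int(labels.max()) + 1
    out = np.zeros((n_lab, geometry.n_angles, geometry.n_detectors))
    flat = labels.ravel()
    nx = labels.shape[1]
    for a, th in enumerate(geometry.angles_deg):
        det, row, col, seg = _angle_segments(
            labels.shape, phantom.pixel_size, geometry, th)
        lab = flat[row * nx + col]
        acc = np.bincount(lab * geometry.n_detectors + det, weights=seg,
                          minlength=n_lab * geometry.n_detectors)
        out[:, a, :] = acc.reshape(n_lab, geometry.n_detectors)
    return out


def forward_project(phantom: PhantomImage, spectrum: Spectrum,
                    geometry: Geometry | None = None, *,
                    photons: float | None = None, seed: int | None = None,
                    path_lengths: np.ndarray | None = None) -> Sinogram:
    """Polyenergetic log-attenuation sinogram of a labelled phantom.

    Per ray the transmitted fraction is T = sum_E w(E) exp(-sum_m
    mu_m(E) L_m) and the sinogram value is -ln T.  With ``photons`` set,
    T is resampled as Poisson(N*T)/N with the given seed before the log
    (counts floored at 1 to keep the log finite on starved rays).
    """
    geometry = geometry or default_geometry(phantom)
    if path_lengths is None:
        path_lengths = material_path_lengths(phantom, geometry)
    mu = np.stack([linear_attenuation(phantom.material_map[lbl], spectrum.energies)
                   for lbl in range(path_lengths.shape[0])])  # (n_lab, n_E)
    flat_l = path_lengths.reshape(path_lengths.shape[0], -1)
    # optical depth per (energy, ray)
    tau = mu.T @ flat_l
    transmission = spectrum.weights @ np.exp(-tau)
    if photons is not None:
        if photons <= 0:
            raise ConfigurationError("photon count must be positive")
        rng = np.random.default_rng(seed)
        counts = np.maximum(rng.poisson(photons * transmission), 1)
        transmission = counts / photons
    values = -np.log(transmission).reshape(geometry.n_angles, geometry.n_detectors)
    return Sinogram(values, geometry, kind="mu")


def forward_project_image(image: ReconImage, geometry: Geometry) -> Sinogram:
    """Line integrals of image values (value x cm), e.g. bone re-projection."""
    vals = image.values
    flat = vals.ravel()
    nx = vals.shape[1]
    out = np.zeros((geometry.n_angles, geometry.n_detectors))
    for a, th in enumerate(geometry.angles_deg):
        det, row, col, seg = _angle_segments(
            vals.shape, image.pixel_size, geometry, th)
        out[a] = np.bincount(det, weights=seg * flat[row * nx + col],
                             minlength=geometry.n_detectors)
    return Sinogram(out, geometry, kind="linear")


# ---------------------------------------------------------------------------
# Filtered back projection
# ---------------------------------------------------------------------------

_WINDOWS = ("ramp", "hann", "cosine", "shepp-logan")


def _ramp_filter(n_pad: int, pitch_cm: float, apodization: str) -> np.ndarray:
    # Ram-Lak filter built from its spatial-domain kernel; sampling |freq|
    # directly would zero the DC bin and bias flat regions low.
    n = np.concatenate([np.arange(0, n_pad // 2 + 1), np.arange(n_pad // 2 - 1, 0, -1)])
    kernel = np.zeros(n_pad)
    kernel[0] = 0.25
    odd = n % 2 == 1
    kernel[odd] = -1.0 / (np.pi * n[odd]) ** 2
    filt = np.real(np.fft.fft(kernel)) / pitch_cm
    freq = np.fft.fftfreq(n_pad, d=pitch_cm)
    f_nyq = 0.5 / pitch_cm
    ratio = np.clip(np.abs(freq) / f_nyq, 0, 1)
    if apodization == "hann":
        filt *= 0.5 * (1 + np.cos(np.pi * ratio))
    elif apodization == "cosine":
        filt *= np.cos(np.pi * ratio / 2)
    elif apodization == "shepp-logan":
        filt *= np.sinc(ratio / 2)
    elif apodization != "ramp":
        raise ConfigurationError(f"unknown apodization {apodization!r}; "
                                 f"choose from {_WINDOWS}")
    return filt


def fbp(sinogram: Sinogram, *, apodization: str = "hann",
        output_size: int | None = None,
        pixel_size: float | None = None) -> ReconImage:
    """Ramp-filtered back projection with linear interpolation.

    Output values are in (sinogram value)/cm; for a kind='mu' sinogram
    that is an effective linear attenuation image, for kind='red' a RED
    image.  The angular range must cover at least 180 degrees.
    """
    geo = sinogram.geometry
    if geo.angular_range < 180.0 - 1e-9:
        raise ConfigurationError("FBP needs an angular range of at least 180 deg")
    pitch_cm = geo.detector_pitch / 10.0
    n_det = geo.n_detectors
    n_pad = int(2 ** np.ceil(np.log2(2 * n_det)))
    filt = _ramp_filter(n_pad, pitch_cm, apodization)
    padded = np.zeros((geo.n_angles, n_pad))
    padded[:, :n_det] = sinogram.values
    filtered = np.real(np.fft.ifft(np.fft.fft(padded, axis=1) * filt, axis=1))
    filtered = filtered[:, :n_det]

    size = output_size or int(np.floor(n_det / np.sqrt(2)))
    px = pixel_size if pixel_size is not None else geo.detector_pitch
    xs = (np.arange(size) - (size - 1) / 2.0) * px
    xx, yy = np.meshgrid(xs, xs)
    recon = np.zeros((size, size))
    offsets = geo.detector_offsets
    for th_deg, q in zip(geo.angles_deg, filtered):
        th = np.deg2rad(th_deg)
        t = xx * np.cos(th) + yy * np.sin(th)
        recon += np.interp(t, offsets, q, left=0.0, right=0.0)
    recon *= np.pi / geo.n_angles * (geo.angular_range / 180.0)
    semantics = {"mu": "attenuation", "red": "red"}.get(sinogram.kind, "image-value")
    return ReconImage(recon, px, semantics)
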