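"""Scripted end-to-end studies on the virtual scanner.

Each experiment reproduces one figure- or table-shaped result family at
desk scale:

* ``run_calibration_family`` — image-value-vs-RED calibration curves for
  the HU chain (one per tube voltage) and the direct-density chain,
  with per-insert voltage-spread metrics;
* ``run_red_tables`` — insert-by-reconstruction mean-RED tables for the
  slab and the metal-plug phantoms;
* ``run_slab_dose`` — single-field dose on every reconstruction of the
  slab phantom, with difference maps, passing rates and profiles;
* ``run_metal_profile`` — RED line profiles through the metal plugs.

Results are returned as pandas DataFrames and optionally written as CSV
with a JSON sidecar carrying the configuration and its hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import calibration as cal
from . import doseval as dv
from .ddrecon import run_direct_density
from .phantoms import (make_calibration_phantom, make_cbct_metal_phantom,
                       make_slab_phantom)
from .physics import make_spectrum
from .projector import default_geometry, material_path_lengths
from .physics import ConfigurationError

__all__ = [
    "ExperimentConfig",
    "CalibrationFamily",
    "run_calibration_family",
    "run_red_tables",
    "run_slab_dose",
    "run_metal_profile",
]

STANDARD_KVPS = (80, 100, 120, 140)
REFERENCE_KVP = 120


@dataclass(frozen=True)
class ExperimentConfig:
    """Shared experiment settings; noise-free by default."""

    kvps: tuple[int, ...] = STANDARD_KVPS
    size: int = 256
    n_angles: int = 180
    photons: float | None = None  # None = noise-free
    seed: int = 0
    field_width: float = 120.0  # mm, slab-dose beam
    outdir: str | None = None

    def __post_init__(self):
        if not set(self.kvps) <= set(STANDARD_KVPS):
            raise ConfigurationError(f"kvps must be within {STANDARD_KVPS}")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write(df: pd.DataFrame, cfg: ExperimentConfig, name: str) -> None:
    if cfg.outdir is None:
        return
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / f"{name}.csv", index=False)
    side = {"config": asdict(cfg), "config_hash": cfg.hash(), "seed": cfg.seed}
    (out / f"{name}.json").write_text(json.dumps(side, indent=1))


def _scan_all(phantom, rois, cfg: ExperimentConfig):
    """Run HU and DD chains at every voltage, reusing the traced chords."""
    geometry = default_geometry(phantom, n_angles=cfg.n_angles)
    chords = material_path_lengths(phantom, geometry)
    noise = {} if cfg.photons is None else {
        "photons": cfg.photons, "seed": cfg.seed}
    hu_images, dd_results = {}, {}
    for kvp in cfg.kvps:
        spectrum = make_spectrum(kvp)
        hu_images[kvp] = cal.hu_reconstruct(
            phantom, spectrum, geometry, path_lengths=chords, **noise)
        dd_results[kvp] = run_direct_density(
            phantom, spectrum, geometry, path_lengths=chords, **noise)
    return hu_images, dd_results


@dataclass
class CalibrationFamily:
    """Calibration-study output: curves per chain plus raw insert values."""

    table: pd.DataFrame  # insert x (true RED, image values per chain/kvp)
    spreads: pd.DataFrame  # per-insert voltage-spread metrics
    hu_curves: dict[int, cal.CalibrationCurve]
    dd_curve: cal.CalibrationCurve
    dd_curves: dict[int, cal.CalibrationCurve]


def run_calibration_family(cfg: ExperimentConfig = ExperimentConfig(),
                           phantom=None, rois=None) -> CalibrationFamily:
    """Insert image values and calibration curves for both chains.

    The DD calibration curve is fitted on the reference-voltage points,
    following the convention of regressing the 120 kVp data; curves for
    the other voltages are also built so their spread can be reported.
    """
    if phantom is None:
        phantom, rois = make_calibration_phantom(size=cfg.size)
    hu_images, dd_results = _scan_all(phantom, rois, cfg)

    true_red = {r.name: phantom.material_of(r.name).red for r in rois}
    rows = []
    for roi in rois:
        row = {"insert": roi.name, "true_red": true_red[roi.name]}
        for kvp in cfg.kvps:
            row[f"hu_{kvp}"] = cal.roi_stats(hu_images[kvp], roi).mean
            row[f"dd_{kvp}"] = cal.roi_stats(dd_results[kvp].image, roi).mean
        rows.append(row)
    table = pd.DataFrame(rows)

    hu_curves = {
        kvp: cal.build_curve(
            [(cal.roi_stats(hu_images[kvp], r), true_red[r.name]) for r in rois],
            kvp=kvp)
        for kvp in cfg.kvps}
    dd_curves = {
        kvp: cal.build_curve(
            [(cal.roi_stats(dd_results[kvp].image, r), true_red[r.name])
             for r in rois], kvp="DD")
        for kvp in cfg.kvps}
    ref = REFERENCE_KVP if REFERENCE_KVP in cfg.kvps else cfg.kvps[0]
    dd_curve = dd_curves[ref]

    hu_cols = table[[f"hu_{k}" for k in cfg.kvps]].to_numpy()
    dd_cols = table[[f"dd_{k}" for k in cfg.kvps]].to_numpy()
    dd_red = dd_cols / 1000.0 + 0.994
    spreads = pd.DataFrame({
        "insert": table["insert"],
        "true_red": table["true_red"],
        # normalized on the HU+1000 scale, which is proportional to
        # attenuation, so the water row is not a 0/0 artifact
        "hu_rel_spread_pct": 100.0 * (hu_cols.max(1) - hu_cols.min(1))
        / (hu_cols.mean(1) + 1000.0),
        "dd_red_spread": dd_red.max(1) - dd_red.min(1),
    })
    _write(table, cfg, "calibration_values")
    _write(spreads, cfg, "calibration_spreads")
    if cfg.outdir is not None:
        out = Path(cfg.outdir)
        for kvp, curve in hu_curves.items():
            curve.to_csv(out / f"curve_hu_{kvp}.csv")
        dd_curve.to_csv(out / "curve_dd.csv")
    return CalibrationFamily(table, spreads, hu_curves, dd_curve, dd_curves)


def _red_table(phantom, rois, cfg, hu_curve, dd_curve) -> pd.DataFrame:
    """Insert x reconstruction mean-RED table (reference, HU_120, DD_kvp)."""
    hu_images, dd_results = _scan_all(phantom, rois, cfg)
    ref_kvp = REFERENCE_KVP if REFERENCE_KVP in cfg.kvps else cfg.kvps[0]
    hu_red = cal.image_to_red(hu_images[ref_kvp], hu_curve)
    rows = []
    for roi in rois:
        try:
            mat = phantom.material_of(roi.name)
        except KeyError:
            mat = phantom.material_of(roi.name.rsplit("_", 1)[0])
        row = {"insert": roi.name, "reference": mat.red}
        s = cal.roi_stats(hu_red, roi)
        row[f"hu_{ref_kvp}_mean"], row[f"hu_{ref_kvp}_sd"] = s.mean, s.sd
        for kvp in cfg.kvps:
            red_img = cal.image_to_red(dd_results[kvp].image, dd_curve)
            s = cal.roi_stats(red_img, roi)
            row[f"dd_{kvp}_mean"], row[f"dd_{kvp}_sd"] = s.mean, s.sd
        rows.append(row)
    return pd.DataFrame(rows)


def run_red_tables(cfg: ExperimentConfig = ExperimentConfig(),
                   family: CalibrationFamily | None = None):
    """Mean-RED tables for the slab and the metal-plug phantoms.

    Metal plugs are read through the tissue calibration curves with the
    above-range policy set to 'extrapolate': a tissue curve ends at RED
    1.7, and continuing its straight line is what exposes the voltage
    dependence of metal readings (a hard clamp would pin every metal at
    1.7).
    """
    if family is None:
        family = run_calibration_family(cfg)
    ref_kvp = REFERENCE_KVP if REFERENCE_KVP in cfg.kvps else cfg.kvps[0]
    hu_curve = family.hu_curves[ref_kvp]
    dd_curve = family.dd_curve

    slab, slab_rois = make_slab_phantom(size=cfg.size)
    slab_table = _red_table(slab, slab_rois, cfg, hu_curve, dd_curve)

    metal, metal_rois = make_cbct_metal_phantom(size=cfg.size)
    hu_x = cal.CalibrationCurve(hu_curve.points, kvp=hu_curve.kvp,
                                above_range="extrapolate",
                                slope=hu_curve.slope, intercept=hu_curve.intercept)
    dd_x = cal.CalibrationCurve(dd_curve.points, kvp="DD",
                                above_range="extrapolate",
                                slope=dd_curve.slope, intercept=dd_curve.intercept)
    metal_table = _red_table(metal, metal_rois, cfg, hu_x, dd_x)

    _write(slab_table, cfg, "red_table_slab")
    _write(metal_table, cfg, "red_table_metal")
    return slab_table, metal_table


@dataclass
class SlabDoseResult:
    passing: pd.DataFrame  # per-kvp passing rates and ROI mean deltas
    depth_profiles: pd.DataFrame
    lateral_profiles: pd.DataFrame
    doses: dict
    ref_dose: dv.DoseGrid
    rois: dict


def run_slab_dose(cfg: ExperimentConfig = ExperimentConfig(),
                  family: CalibrationFamily | None = None) -> SlabDoseResult:
    """Single broad beam on every reconstruction of the slab phantom.

    The reference dose is computed on the HU-chain RED map at the
    reference voltage; each DD-chain RED map is compared against it with
    the 0.5%/5% dose-difference criterion, ROI mean-dose deltas, and
    depth/lateral profiles through the cavities.
    """
    if family is None:
        family = run_calibration_family(cfg)
    ref_kvp = REFERENCE_KVP if REFERENCE_KVP in cfg.kvps else cfg.kvps[0]
    slab, slab_rois = make_slab_phantom(size=cfg.size)
    hu_images, dd_results = _scan_all(slab, slab_rois, cfg)
    beam = dv.BeamSpec(entry="top", field_width=cfg.field_width)

    def dose_of(red_img):
        return dv.compute_dose(dv.resample_to_dose_grid(red_img), beam)

    ref_red = cal.image_to_red(hu_images[ref_kvp], family.hu_curves[ref_kvp])
    ref_dose = dose_of(ref_red)

    spacing = ref_dose.spacing
    n = ref_dose.values.shape[0]
    xx_idx = lambda mm: mm / spacing + (n - 1) / 2.0  # noqa: E731

    roi_masks = {}
    yy, xx = np.meshgrid(*[np.arange(n)] * 2, indexing="ij")
    for roi in slab_rois:
        cx, cy = roi.center
        r = roi.diameter / 2.0 / spacing
        roi_masks[roi.name] = (xx - xx_idx(cx)) ** 2 + (yy - xx_idx(cy)) ** 2 <= r**2

    half = n * spacing / 2.0
    depth_lines = {name: ((cx, -half), (cx, half - spacing))
                   for name, cx in (("plaster", slab_rois[0].center[0]),
                                    ("air", slab_rois[2].center[0]),
                                    ("water", 0.0))}
    lat_depth = slab_rois[0].center[1]

    doses, rows = {}, []
    dprof = {"position_mm": dv.dose_profile(ref_dose, *depth_lines["plaster"])[:, 0]}
    lprof = {"position_mm": dv.dose_profile(
        ref_dose, (-half, lat_depth), (half - spacing, lat_depth))[:, 0]}
    for name, line in depth_lines.items():
        dprof[f"ref_{name}"] = dv.dose_profile(ref_dose, *line)[:, 1]
    lprof["ref"] = dv.dose_profile(ref_dose, (-half, lat_depth),
                                   (half - spacing, lat_depth))[:, 1]
    for kvp in cfg.kvps:
        red_img = cal.image_to_red(dd_results[kvp].image, family.dd_curve)
        dose = dose_of(red_img)
        doses[kvp] = dose
        diff = dv.dose_difference(dose, ref_dose)
        row = {"kvp": kvp,
               "passing_rate_pct": dv.passing_rate(diff, ref_dose)}
        for rname, mask in roi_masks.items():
            row[f"delta_mean_{rname}_pct"] = dv.mean_dose_delta(dose, ref_dose, mask)
        rows.append(row)
        for name, line in depth_lines.items():
            dprof[f"dd{kvp}_{name}"] = dv.dose_profile(dose, *line)[:, 1]
        lprof[f"dd{kvp}"] = dv.dose_profile(dose, (-half, lat_depth),
                                            (half - spacing, lat_depth))[:, 1]

    passing = pd.DataFrame(rows)
    depth_profiles = pd.DataFrame(dprof)
    lateral_profiles = pd.DataFrame(lprof)
    _write(passing, cfg, "slab_dose_passing")
    _write(depth_profiles, cfg, "slab_depth_profiles")
    _write(lateral_profiles, cfg, "slab_lateral_profiles")
    return SlabDoseResult(passing, depth_profiles, lateral_profiles,
                          doses, ref_dose, roi_masks)


def run_metal_profile(cfg: ExperimentConfig = ExperimentConfig(),
                      family: CalibrationFamily | None = None) -> pd.DataFrame:
    """RED line through the steel plug for every reconstruction."""
    if family is None:
        family = run_calibration_family(cfg)
    ref_kvp = REFERENCE_KVP if REFERENCE_KVP in cfg.kvps else cfg.kvps[0]
    phantom, rois = make_cbct_metal_phantom(size=cfg.size)
    hu_images, dd_results = _scan_all(phantom, rois, cfg)
    steel = next(r for r in rois if r.name == "steel")
    cx, cy = steel.center
    start, end = (cx - 60.0, cy), (cx + 60.0, cy)

    hu_curve = family.hu_curves[ref_kvp]
    hu_x = cal.CalibrationCurve(hu_curve.points, kvp=hu_curve.kvp,
                                above_range="extrapolate",
                                slope=hu_curve.slope, intercept=hu_curve.intercept)
    dd_x = cal.CalibrationCurve(family.dd_curve.points, kvp="DD",
                                above_range="extrapolate",
                                slope=family.dd_curve.slope,
                                intercept=family.dd_curve.intercept)
    ref_prof = cal.red_profile(cal.image_to_red(hu_images[ref_kvp], hu_x),
                               start, end)
    out = {"position_mm": ref_prof[:, 0], f"hu_{ref_kvp}": ref_prof[:, 1]}
    for kvp in cfg.kvps:
        red_img = cal.image_to_red(dd_results[kvp].image, dd_x)
        out[f"dd_{kvp}"] = cal.red_profile(red_img, start, end)[:, 1]
    df = pd.DataFrame(out)
    _write(df, cfg, "metal_profile")
    return df
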