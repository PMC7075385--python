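# Methods

This note documents the physics and numerics behind `densityct`: what
is modelled, which constants matter, where the design was genuinely
open, and what the desk-scale results do and do not demonstrate.

## Attenuation model

Materials are elemental mixtures (17 elements, H–Zn) with a mass
density. Mass attenuation per element is an analytic three-term model
on 10–150 keV:

* incoherent scattering: Z × the Klein–Nishina cross section per
  electron (exact closed form);
* photoelectric absorption: a power law c·Z^p/E^q per atom;
* coherent scattering: a second power law.

The four power-law constants were least-squares fitted to standard
(NIST) water and aluminium mass-attenuation values; the fit reproduces
the embedded water anchors at 40/60/80/100 keV to better than 1 % and
extrapolates to Ca/Ti/Fe within roughly ±15 %. Absolute accuracy at
high Z is not critical: the simulator and the reconstruction model
share the same tables, so the study is self-consistent, and only the
qualitative Z-dependence (photoelectric ≫ Compton at low energy)
drives beam hardening. Tables are evaluated on a 1 keV grid and
interpolated log–log. Mixtures follow the mass-fraction mixture rule.

## Tube spectra

Kramers bremsstrahlung (photon fluence ∝ kvp/E − 1) filtered by a
configurable aluminium thickness, weighted by E for an
energy-integrating detector, normalized on 1 keV bins from 10 keV to
the tube voltage. Optional tungsten K lines can be enabled. The
default filtration is **10 mm Al-equivalent**: a CT scanner's total
central-ray filtration (inherent port plus bow-tie center) is far
heavier than the 2–3 mm of a radiographic tube, and an unrealistically
soft beam exaggerates the low-kVp photoelectric distortion of
carbon-rich tissues. Mean energies are then ≈51/59/67/75 keV at
80/100/120/140 kVp. No scatter, heel effect, or spatially varying
bow-tie is modelled.

## Material library

Tissue substitutes use ICRU-style compositions with the density chosen
to hit the manufacturer-style reference RED (lung 0.20/0.50, adipose
0.95, breast 0.98, muscle 1.04, liver 1.05, titanium 3.74, stainless
steel 6.92, brass 7.0). Graded bone inserts (RED 1.12/1.46/1.70) are
built as **volumetric water/cortical-bone mixtures**: electron-density
phantom inserts are engineered to mimic the attenuation-vs-RED relation
of real skeletal tissue, i.e. to lie on the water/bone two-material
manifold, and the volume mixture reproduces that by construction. Cast
plaster (gypsum) and cork are hand-set to RED 1.37 and 0.26; gypsum's
high effective Z puts it deliberately *off* the tissue manifold, which
is what makes it an interesting bone surrogate. Dry air fills cavities
and the background.

## Virtual scanner

Parallel-beam geometry, 180 views over 180°, detector pitch equal to
the 1 mm pixel size, detector row spanning the grid diagonal. Rays are
intersected exactly with the pixel grid (Siddon-style), so chord tests
against analytic lengths hold to rasterization accuracy; per-material
chord maps are cached and reused across tube voltages. The forward
model is T = Σ w(E)·exp(−Σ_m μ_m(E) L_m) per ray, S_μ = −ln T.
Optional noise resamples T as Poisson(N·T)/N with a seeded generator
(default budget 2×10⁵ photons per ray, scaled with mAs by the caller;
counts are floored at one photon to keep the log finite).

FBP uses a Ram-Lak filter constructed from its spatial-domain kernel
(frequency sampling would zero the DC bin and bias flat regions by
≈1 %), an apodization window standing in for vendor kernels (Hann by
default), and linear interpolation in the back projection.
A round trip on a smooth 256² image has RMSE ≈ 0.04 % of range, well
inside the 2 % budget; the suite also cross-checks against
scikit-image's `iradon` on a disk.

## Direct-density chain

The implementation follows the published flow (initial image →
threshold → bone re-projection → water decomposition → RED sinogram →
FBP → affine image-value map) with four documented realization choices
where the publication is silent:

1. **The initial image is water-corrected.** Any clinical "single
   energy CT image" is; without the correction, cupping of several
   percent pushes soft tissue and bone across the fixed threshold
   I_S (+150 HU-equivalent by default, 100 HU soft ramp).
2. **The bone image stores the value-weighted excess over the water
   baseline.** A graded-bone voxel is a water/bone mixture; only the
   attenuation beyond the water level it displaces is bone signal.
   Weighting raw values double-counts the water share of every bone
   voxel into d_B (−0.09 RED on the 1.46 insert, −0.3 on the 1.12
   insert). With a hard threshold and zero baseline the operation
   reduces to the idempotent masked-value form.
3. **μ_bone_ref is a secant, not a tangent.** The bone sinogram is in
   water-corrected image units, so the conversion to centimetres uses
   the water-equivalent excess that one cm of reference bone actually
   produces behind a representative water path (3 cm bone behind
   15 cm water, the mean chord of the default 20 cm body). A
   monoenergetic or thin-path ratio overestimates the conversion
   because the in-body spectrum is harder than the incident one.
4. **The decomposition is bounded by CT-number consistency.**
   Reconstructed images carry the standard 12-bit range (−1024 to
   +3071 HU-equivalent). Per ray, d_W may not imply more attenuation
   than the capped initial image admits (2 % slack + 1 mm margin for
   reconstruction error). Ordinary rays never touch the bound; metal
   rays saturate at it instead of absorbing their unexplained
   photoelectric excess as metres of fictitious water. This is what
   keeps metal degradation bounded: without it steel reconstructs to
   RED 15–25 *decreasing* with kVp, with it to ≈2.8–3.3 *increasing*
   with kVp and always far below the true 6.92 — the behavior physical
   scanners exhibit. The same cap makes the conventional chain read
   titanium and steel identically (both clipped at +3071 HU).

The water solve is a vectorized bracketed bisection on the strictly
monotone polyenergetic model, tolerance 10⁻⁶ cm (≈40 iterations,
guaranteed convergence); d_W clamps at 0 where the bone component
alone explains the ray. One decomposition pass is performed; iterating
the bone estimate is left as an extension. The affine map
(RED − 0.994) × 1000 is applied after FBP — FBP is linear, so only the
offset's placement matters, and post-FBP keeps sinogram units physical.

## Conventional chain and calibration

The HU chain water-corrects S_μ by inverting a simulated 0–50 cm water
slab lookup for the same spectrum, reconstructs, and scales to HU at
the spectrum's mean energy, clipped to the 12-bit range. Water lands at
0 ± 1 HU and air at −1000 at every voltage while bone values spread by
20–30 % between 80 and 140 kVp — the usual reason per-kVp curves exist.

Calibration curves are ordered (image value, RED) control points from
2 cm-ROI means, converted piecewise-linearly. Readings whose order
disagrees with their REDs (nearly equal tissues) are pooled
isotonically, as a monotone conversion table requires. Below the lowest
point the first segment extrapolates but floors at RED 0. Above the
highest point (nominally RED 1.7, where tissue curves end) the policy
is explicit: `clamp` — the conservative clinical setting and the
default, used for dose calculation — or `extrapolate`, which continues
the last straight-line segment and is what exposes the voltage
dependence of metal readings in the reported tables. The reference
direct-density line RED = 0.001·v + 0.994 is available as a built-in
curve; fitting the synthetic calibration inserts reproduces its slope
to better than 1 % at every voltage.

## Dose model and comparison statistics

The dose engine is a declared toy: an axis-aligned broad beam with
D = output × PDD(z) × lateral profile, PDD(z) = N(e^(−az) − e^(−bz))
with a = 0.005/mm, b = 0.26/mm for "6 MV" (build-up ≈ 15 mm), an erf
penumbra of σ = 3 mm, and z the RED-weighted radiological depth. It is
not a clinical algorithm and claims no AAA-equivalence; it exists so
RED errors propagate into dose with the correct sign and rough
magnitude. Doses live on a 1.25 mm grid (RED resampled bilinearly).

Comparisons follow QA practice: per-pixel difference as % of the
reference maximum (global normalization — the publication's region
definition "above 5 % of the maximum dose" implies a global reference,
and local normalization is noted as the open alternative), passing
rate of a 0.5 % criterion in that region (an empty region is an error,
never a silent 100 %), cumulative DVHs binned at 0.1 % of the maximum,
and ROI mean-dose deltas.

## Study conditions and problem sizes

Experiments run noise-free on 256² grids at 1 mm pixels with 180
views — the scale at which the full calibration family takes ~30 s on
one CPU. Phantom geometry scales with the field of view (100 mm body,
28 mm inserts, 12 mm metal plugs at the reference size; ROIs shrink to
fit smaller inserts on coarse grids). Noisy runs are seeded and
bit-reproducible and produce insert SDs of the same order as measured
tables, but their magnitudes are qualitative only.

## What the synthetic study does and does not show

It demonstrates the *mechanism*: voltage-independent RED recovery
(per-insert spread ≤ 0.03 across 80–140 kVp), the straight-line
image-value calibration, bounded voltage-dependent metal
underestimation, and the sign structure of the dose differences behind
dense and light inhomogeneities (the difference persists beyond
plaster and resolves beyond an air cavity). It does not reproduce
detector-specific effects: no scatter, no electronic noise floor, no
vendor sinogram conditioning. One measured behavior is specifically a
noise-floor artifact and does not occur here: a physical HU chain
assigns air a small positive RED (≈0.04) while the density chain
assigns less, so measured dose in air regions is overestimated on the
density images; the noise-free twin's reference chain assigns air
exactly 0, the density chain can only be ≥ 0, and the sign cannot
emerge. The corresponding check is retained and fails honestly.

Carbon-rich adipose is the least water/bone-like tissue and shows the
largest voltage residual (≈0.03 spread); that residual shrinks with
harder beams, which is why the filtration default matters and is
documented above.
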