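# Methods

This note documents the models, numerical choices and limitations behind
sliceflex, in the order data flows through the package.

## Framework model

The framework targets one workflow: load a 2D multislice dataset, walk
it slice by slice, interact, compute, visualize, export. Three layers
implement it:

- **Image layer** (`image_model`): one `ImageRecord` per 2D image, in
  the source dtype, with a flat tag map (EchoTime in ms, SliceLocation
  in mm, MagneticFieldStrength in T, PatientName, AcquisitionTime,
  InstanceNumber). DICOM rescale slope/intercept are applied on read, so
  values are in output units; when they are present the array is
  float64, otherwise the stored dtype is preserved. Raster images
  (bmp/png/jpg/gif/tiff) are accepted with an empty tag map;
  multi-channel input is reduced by the unweighted channel mean (a
  deliberate, documented choice — there is no principled luminance
  weighting for medical screenshots). `scale2` maps min→lo, max→hi; a
  constant image maps to all `lo` (deterministic, no division by zero).
- **Compute plugin layer** (`plugin`): one compute object per slice,
  holding channel→image lists (echo-sorted) and an opaque, JSON-safe
  application payload. The controller talks to plugins only through the
  mandatory hook set (`init_app`, `get_img2display`, `post_plot`,
  `draw_graph`, `get_textbox_lines`, `custom_save`, the three image
  mouse handlers, `key_press`, `key_release`); a plugin missing a hook
  is rejected when registered, not when first used. Historical
  camelCase names map to these hooks one-to-one: mInit_oCompApp →
  `init_app`, mGetImg2Display → `get_img2display`, mPostPlot →
  `post_plot`, mDrawGraph → `draw_graph`, mGetTextBoxLines →
  `get_textbox_lines`, mCustomSaveData → `custom_save`,
  mImgAxisButtonDown/Motion/Up (also known as mImageDisplayButtonUp) →
  `image_button_down/motion/up`, mKeyPress/mKeyRelease →
  `key_press`/`key_release`, mMergeContours → `merge_contours`,
  mFitIntensities → `fit_intensities`, mGetPDFF → `get_pdff`,
  mGetMagImages → `compute_magnitudes`, mDrawContour → `draw_contour`.
- **Controller layer** (`controller`): discovery, loading, event
  dispatch, UI update, persistence. The UI is a headless `UIState`
  value; no widgets are rendered. Rendering hosts can be layered on top
  without touching any logic here.

### Loading

Each channel's files are found by a directory glob plus a filename glob
(both from the application config, positionally paired with the channel
name), lexicographically sorted. Files are grouped into slices by
SliceLocation rounded to 10⁻³ mm — DICOM encodes the tag as a decimal
string, so values that agree to a micrometre are the same slice; ties
within a slice/channel are ordered by EchoTime, then InstanceNumber.
Channels must cover identical slice sets with identical echo counts;
anything else is a consistency error rather than a silent partial load.

### Events and UI update

All ten event types are dispatched through one function; after every
event the update routine runs in the fixed order image → graph → text →
table. The table runs last so that any change a hook made to the session
is already visible when it is rendered; cell (r, c) is the value of the
configured entry call c evaluated against slice r (`name` = property
lookup, `name(k)` = method call with 1-based k, matching the radiological
convention of 1-based ROI numbering). Event pixel coordinates are
0-based (row, col). Unfitted results render as blank cells via a
`None` sentinel.

Menu callbacks are plain method identifiers resolved on the current
slice's plugin object. The historical design stored interpreter-evaluated
callback strings in the config; evaluating code from a config file is a
needless hazard, so identifiers are looked up instead, and the
framework's Load Data / Save Data entries are always present.

### Session persistence and migration

A session is saved as a zip container
(`{patient}_{acquisitionTime}_{currentTime}_{application}_data.session`)
holding `manifest.json` plus one raw little-endian binary file per image
with dtype/shape recorded in the manifest. Contents are plain
self-describing records — deliberately detached from any class
definition, so old containers remain loadable as the code evolves. On
load, every class in the plugin's version chain whose stored version is
older than the code has its migration function applied to each slice
payload, most specific class first, proceeding to the superclass.
Migrations are pure functions `(payload, old_version) → payload`.
Containers newer than the running code are refused outright; guessing
forward semantics risks silent data loss. Zip member timestamps are
fixed so identical sessions are byte-identical. Auto-save is exposed as
a hook the host calls from its own timer (interval from
frameworkConfig); the framework owns no clock, which keeps it testable.

## The Fatquant signal model

Input per slice: real and imaginary images at n ≥ 3 echo times, plus
MagneticFieldStrength from the header. Magnitude images are
sqrt(re² + im²) per echo. The mean magnitude over a ROI is fitted to the
single-peak magnitude model

    S(TE) = sqrt(W² + F² + 2·W·F·cos(2π·Δf·TE)) · e^(−R2*·TE)
    Δf = 3.4 ppm × 42.577 MHz/T × B0   (computed, never hard-coded)

This is a designed choice, not a reconstruction of any particular
scanner product: it is the simplest standard water–fat model, and the
module is written so a multi-peak fat spectrum could replace the cosine
term without touching the surrounding machinery.

Fitting: `scipy.optimize.least_squares` with bounds W ≥ 0, F ≥ 0,
R2* ∈ [0, 1000] s⁻¹, tolerances 10⁻¹² (tight enough that an exactly
constant signal reaches a machine-level residual, which the degenerate
R² rule below relies on). The magnitude model is exactly symmetric under
W↔F, i.e. PDFF p and 100−p are indistinguishable, so the fit
multi-starts at initial fat fractions 10/50/90% (amplitude from the
largest intensity, R2* from the log-slope of the envelope), evaluates
both branches of every solution, and among residual-tied candidates
reports the lower fat fraction — the physiologically dominant branch for
liver work, and the convention a reader should keep in mind above
PDFF 50%. R² = 1 − SSres/SStot; when SStot = 0 (constant data), R² is 1
if SSres ≤ 10⁻¹²·n, else 0.

ROIs: strokes are recorded between button-down and button-up, clipped to
the image bounds, auto-closed, and rasterized by the even-odd
(crossing-number) rule on pixel centers. Merging is mask union, hence
commutative and idempotent; strokes with fewer than 3 vertices are stray
clicks and are ignored with a warning. Echo times are converted from
DICOM milliseconds to seconds at load; all fits run in seconds.

Export: CSV by default (`.xlsx` via the same operation when the filename
asks for it), one row per slice (first column slice position in mm), one
PDFF column per ROI, written only if **every** fitted ROI's R² clears
the threshold (default 0.95 — the gate is intentionally all-or-nothing,
with a warning naming each offending slice/ROI/R², so a partially
trusted session is never silently exported as if complete). Threshold 0
always exports.

## The phantom generator

The generator emulates a multi-echo Dixon acquisition with known ground
truth, not anatomy. Per pixel it holds (W, F, R2*) maps — a uniform
background overpainted by rectangular or polygonal regions in painter's
order — and evaluates the complex signal
`(W + F·e^(i·2π·Δf·TE))·e^(−R2*·TE)` plus circular complex Gaussian
noise (per-component σ; SNR is defined as (W+F)/σ of the brightest
region). Real parts go to `*_RE_*.dcm`, imaginary to `*_IM_*.dcm`, in
`Dixon*` directories — the layout the default application config
discovers. Pixels are stored as signed 16-bit integers with per-file
rescale slope/intercept spanning the signal range (round-trip error
< 0.1% of the signal); slope/intercept are quantized to their own DICOM
decimal-string representation before use, so the decoded arrays the
generator reports are exactly what a reader recovers. UIDs and all
embedded dates derive from the seed and a fixed nominal acquisition time
(2024-01-01 12:00:00), making the output tree byte-identical for a given
seed.

The standard fixture is 4 slices of 64×64 pixels, three 16×16 regions at
PDFF 10/25/40% (W+F = 100 signal units, R2* 40/50/60 s⁻¹) over a
fat-free background (W = 60, R2* = 25 s⁻¹), 6 echoes at 1.2–9.7 ms,
1.5 T, with a noiseless and an SNR-50 (σ = 2) variant. These sizes keep
every end-to-end check comfortably in seconds while exercising all
moving parts.

What the phantom does **not** emulate — and therefore what passing tests
do not show about clinical data: B0 field inhomogeneity, multi-peak fat
spectra, T1 bias, Rician-dominated low-SNR regimes, coil sensitivity,
motion, and anatomy-shaped ROI ambiguity. Recovery numbers on the
phantom are a correctness check of the pipeline, not a clinical accuracy
claim.

## Configuration

Two JSON documents drive everything. `frameworkConfig.json`: auto-save
interval, UI element visibility, selected callbacks (validated against
the recognized event list), key shortcuts. `applicationConfig.json`:
application name, compute-class identifier (a leading `@` is accepted
and stripped), channel names with positionally paired directory/filename
glob patterns, table headers with entry calls, menu entries, ROI hotkeys
(their count defines the ROI count per slice). Legacy keys
`imgSearchDir`/`imgSearchName` are accepted as aliases for the pattern
lists; unknown keys round-trip untouched so configs written by newer
code still load. Documented JSON-schema files ship in
`src/sliceflex/schemas/`.

## Known limitations

- 2D multislice only; no volumes, no multi-frame DICOM, no compressed
  transfer syntaxes.
- Single-peak magnitude fitting cannot separate PDFF p from 100−p; the
  low branch is reported by convention.
- The R² export gate is a heuristic quality screen, not a validated
  quality metric.
- Table-cell editing is restricted to the Done flag (a plugin decision;
  the framework forwards the event and imposes nothing).
- Sessions store images uncompressed inside the zip container; very
  large series produce proportionally large session files.
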