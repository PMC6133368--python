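"""Synthetic multi-echo Dixon phantom written as standards-compliant DICOM.

The generator emulates the directory/filename layout the reference
application expects (``Dixon*`` directories, ``*_RE_*.dcm`` /
``*_IM_*.dcm`` files) with a fully known ground truth.  Each pixel
carries water amplitude W, fat amplitude F and relaxation rate R2*; the
complex signal at echo time TE is

    s(TE) = (W + F * exp(i * 2 pi df TE)) * exp(-R2* TE) + noise

with df the fat-water chemical-shift offset at the configured field
strength and circular complex Gaussian noise of per-component standard
deviation ``noise_sigma`` (an SNR of 50 on a region with W+F = 100 means
sigma = 2).  The real part goes to the RE files, the imaginary part to
the IM files.

Pixels are stored as 16-bit signed integers with per-file rescale
slope/intercept spanning the signal range, so a standards-compliant
reader recovers the float signal to better than 0.1%.  All embedded
dates, times and UIDs are derived from the spec, so the same seed
produces a byte-identical output tree.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian

from .errors import PhantomSpecError
from .fatquant import fat_water_offset_hz, rasterize_polygon

_UID_ROOT = "1.2.826.0.1.3680043.10.511"
_NOMINAL_DATE = "20240101"
_NOMINAL_TIME = "120000"


@dataclasses.dataclass
class PhantomRegion:
    """A homogeneous tissue compartment painted over the background.

    ``rect`` is (row0, row1, col0, col1) with exclusive upper bounds;
    alternatively ``polygon`` is a list of (row, col) vertices.  Later
    regions overwrite earlier ones (painter's order).
    """

    w: float
    f: float
    r2star: float  # 1/s
    rect: tuple[int, int, int, int] | None = None
    polygon: list[list[float]] | None = None

    @property
    def pdff_percent(self) -> float:
        total = self.w + self.f
        return 0.0 if total == 0 else 100.0 * self.f / total


@dataclasses.dataclass
class PhantomSpec:
    n_slices: int = 4
    image_shape: tuple[int, int] = (64, 64)
    regions: list[PhantomRegion] = dataclasses.field(default_factory=list)
    background: PhantomRegion = dataclasses.field(
        default_factory=lambda: PhantomRegion(w=60.0, f=0.0, r2star=25.0))
    echo_times_ms: list[float] = dataclasses.field(
        default_factory=lambda: [1.2, 2.9, 4.6, 6.3, 8.0, 9.7])
    b0_tesla: float = 1.5
    noise_sigma: float = 0.0
    seed: int = 1234
    patient_name: str = "PHANTOM01"
    slice_spacing_mm: float = 5.0
    dir_template: str = "Dixon{slice:02d}"
    file_template: str = "s{slice:02d}_{channel}_e{echo}.dcm"

    def validate(self) -> None:
        if self.n_slices < 1:
            raise PhantomSpecError("n_slices must be >= 1")
        if len(self.echo_times_ms) < 3:
            raise PhantomSpecError(
                f"need >= 3 echo times, got {len(self.echo_times_ms)}")
        if self.noise_sigma < 0:
            raise PhantomSpecError("noise_sigma must be >= 0")


def parameter_maps(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray,
                                               np.ndarray]:
    """Ground-truth (W, F, R2*) maps: background first, then regions in
    painter's order."""
    shape = tuple(spec.image_shape)
    w = np.full(shape, float(spec.background.w))
    f = np.full(shape, float(spec.background.f))
    r2 = np.full(shape, float(spec.background.r2star))
    for region in spec.regions:
        if region.rect is not None:
            r0, r1, c0, c1 = region.rect
            sel = np.zeros(shape, dtype=bool)
            sel[r0:r1, c0:c1] = True
        elif region.polygon is not None:
            sel = rasterize_polygon(region.polygon, shape)
        else:
            raise PhantomSpecError("region needs a rect or a polygon")
        w[sel], f[sel], r2[sel] = region.w, region.f, region.r2star
    return w, f, r2


def complex_signal(spec: PhantomSpec, te_ms: float) -> np.ndarray:
    """Noiseless complex signal of the whole image at one echo time."""
    w, f, r2 = parameter_maps(spec)
    te_s = te_ms / 1000.0
    phase = 2.0 * np.pi * fat_water_offset_hz(spec.b0_tesla) * te_s
    return (w + f * np.exp(1j * phase)) * np.exp(-r2 * te_s)


def _quantize(arr: np.ndarray) -> tuple[np.ndarray, float, float]:
    """int16 stored values plus the slope/intercept written to the file."""
    lo = float(arr.min())
    hi = float(arr.max())
    slope = (hi - lo) / 32767.0 if hi > lo else 1.0
    slope = float(f"{slope:.10g}")  # match the DS string the file carries
    intercept = float(f"{lo:.10g}")
    stored = np.round((arr - intercept) / slope).astype(np.int16)
    return stored, slope, intercept


def _write_dicom(path: Path, arr: np.ndarray, *, te_ms: float,
                 slice_location: float, b0: float, patient: str,
                 instance_number: int, sop_uid: str, series_uid: str,
                 study_uid: str) -> np.ndarray:
    """Write one image; returns the decoded values the file round-trips to."""
    stored, slope, intercept = _quantize(arr)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    meta.ImplementationClassUID = f"{_UID_ROOT}.1"
    meta.ImplementationVersionName = "SLICEFLEX_1"

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = pydicom.uid.MRImageStorage
    ds.SOPInstanceUID = sop_uid
    ds.SeriesInstanceUID = series_uid
    ds.StudyInstanceUID = study_uid
    ds.Modality = "MR"
    ds.PatientName = patient
    ds.PatientID = patient
    ds.StudyDate = _NOMINAL_DATE
    ds.ContentDate = _NOMINAL_DATE
    ds.AcquisitionDate = _NOMINAL_DATE
    ds.StudyTime = _NOMINAL_TIME
    ds.ContentTime = _NOMINAL_TIME
    ds.AcquisitionTime = _NOMINAL_TIME
    ds.EchoTime = f"{te_ms:.10g}"
    ds.SliceLocation = f"{slice_location:.10g}"
    ds.MagneticFieldStrength = f"{b0:.10g}"
    ds.InstanceNumber = instance_number
    ds.Rows, ds.Columns = stored.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1  # signed
    ds.RescaleSlope = f"{slope:.10g}"
    ds.RescaleIntercept = f"{intercept:.10g}"
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
    return stored.astype(np.float64) * slope + intercept


def generate_phantom(spec: PhantomSpec, out_dir: str | Path) -> dict[str, Any]:
    """Write the phantom DICOM tree plus a ``manifest.json`` sidecar.

    Returns the manifest dict; its ``"arrays"`` key (in memory only, not
    in the JSON sidecar) maps each relative file path to the exact float
    array a standards-compliant reader recovers from that file.
    """
    spec.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    files: list[dict[str, Any]] = []
    arrays: dict[str, np.ndarray] = {}
    instance = 0
    study_uid = f"{_UID_ROOT}.{spec.seed % 100000}.0"
    for si in range(spec.n_slices):
        slice_dir = out_dir / spec.dir_template.format(slice=si + 1)
        slice_dir.mkdir(exist_ok=True)
        loc = si * spec.slice_spacing_mm
        for ei, te_ms in enumerate(spec.echo_times_ms):
            signal = complex_signal(spec, te_ms)
            if spec.noise_sigma > 0:
                noise = rng.normal(0.0, spec.noise_sigma, signal.shape + (2,))
                signal = signal + noise[..., 0] + 1j * noise[..., 1]
            for channel, values in (("RE", signal.real), ("IM", signal.imag)):
                instance += 1
                name = spec.file_template.format(slice=si + 1,
                                                 channel=channel, echo=ei + 1)
                path = slice_dir / name
                sop_uid = f"{_UID_ROOT}.{spec.seed % 100000}.{instance}"
                series_uid = f"{_UID_ROOT}.{spec.seed % 100000}.9{si + 1}"
                decoded = _write_dicom(
                    path, values, te_ms=te_ms, slice_location=loc,
                    b0=spec.b0_tesla, patient=spec.patient_name,
                    instance_number=instance, sop_uid=sop_uid,
                    series_uid=series_uid, study_uid=study_uid)
                rel = str(path.relative_to(out_dir))
                arrays[rel] = decoded
                files.append({"path": rel, "channel": channel,
                              "slice_index": si, "echo_index": ei,
                              "te_ms": te_ms, "slice_location": loc,
                              "instance_number": instance})

    manifest: dict[str, Any] = {
        "patient_name": spec.patient_name,
        "n_slices": spec.n_slices,
        "image_shape": list(spec.image_shape),
        "echo_times_ms": list(spec.echo_times_ms),
        "b0_tesla": spec.b0_tesla,
        "noise_sigma": spec.noise_sigma,
        "seed": spec.seed,
        "background": dataclasses.asdict(spec.background),
        "regions": [dataclasses.asdict(r) for r in spec.regions],
        "ground_truth_pdff": [r.pdff_percent for r in spec.regions],
        "files": files,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    manifest["arrays"] = arrays
    return manifest


# --------------------------------------------------------------------------
# The standard fixture used across the test suite

#: region rectangles (row0, row1, col0, col1) of the standard fixture
STANDARD_RECTS = ((8, 24, 8, 24), (8, 24, 40, 56), (40, 56, 8, 24))
#: ground-truth fat fractions (percent) of the standard fixture regions
STANDARD_PDFFS = (10.0, 25.0, 40.0)


def standard_fixture(noise: str = "none", b0_tesla: float = 1.5,
                     seed: int = 1234) -> PhantomSpec:
    """The fixed phantom the test suite and examples run on.

    4 slices of 64x64 pixels with three rectangular regions at fat
    fractions 10/25/40% (W+F = 100 signal units each) over a fat-free
    background, 6 echoes from 1.2 to 9.7 ms.  ``noise="snr50"`` adds
    complex Gaussian noise at SNR 50 relative to the brightest region
    (sigma = 2); ``noise="none"`` is noiseless.
    """
    if noise == "none":
        sigma = 0.0
    elif noise == "snr50":
        sigma = 100.0 / 50.0
    else:
        raise PhantomSpecError(f"unknown noise variant {noise!r}")
    regions = [
        PhantomRegion(w=90.0, f=10.0, r2star=40.0, rect=STANDARD_RECTS[0]),
        PhantomRegion(w=75.0, f=25.0, r2star=50.0, rect=STANDARD_RECTS[1]),
        PhantomRegion(w=60.0, f=40.0, r2star=60.0, rect=STANDARD_RECTS[2]),
    ]
    return PhantomSpec(n_slices=4, image_shape=(64, 64), regions=regions,
                       b0_tesla=b0_tesla, noise_sigma=sigma, seed=seed)


def simulate_region_means(spec: PhantomSpec, region_index: int,
                          rng: np.random.Generator,
                          margin: int = 2) -> list[float]:
    """One noisy realization of a region's per-echo mean ROI magnitudes.

    The region is uniform, so the noiseless complex signal is a scalar
    per echo; per-pixel complex noise is added over the region's
    rectangle (shrunk by ``margin``), the magnitude taken, and the
    spatial mean returned — exactly what a drawn ROI would measure.
    """
    region = spec.regions[region_index]
    if region.rect is None:
        raise PhantomSpecError("simulate_region_means needs a rect region")
    r0, r1, c0, c1 = region.rect
    npx = (r1 - r0 - 2 * margin) * (c1 - c0 - 2 * margin)
    if npx < 1:
        raise PhantomSpecError("margin leaves no pixels in the region")
    delta_f = fat_water_offset_hz(spec.b0_tesla)
    means = []
    for te_ms in spec.echo_times_ms:
        te_s = te_ms / 1000.0
        s = (region.w + region.f * np.exp(2j * np.pi * delta_f * te_s)) \
            * np.exp(-region.r2star * te_s)
        noise = rng.normal(0.0, spec.noise_sigma, (npx, 2)) \
            if spec.noise_sigma > 0 else np.zeros((npx, 2))
        mags = np.abs(s + noise[:, 0] + 1j * noise[:, 1])
        means.append(float(mags.mean()))
    return means


def spec_from_json(path: str | Path) -> PhantomSpec:
    """Load a PhantomSpec from a JSON document."""
    doc = json.loads(Path(path).read_text())

    def region(r: dict[str, Any]) -> PhantomRegion:
        r = dict(r)
        if r.get("rect") is not None:
            r["rect"] = tuple(r["rect"])
        return PhantomRegion(**r)

    regions = [region(r) for r in doc.pop("regions", [])]
    background = doc.pop("background", None)
    spec = PhantomSpec(regions=regions, **doc)
    if background:
        spec.background = region(background)
    spec.image_shape = tuple(spec.image_shape)
    spec.validate()
    return spec
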