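"""Fatquant: ROI-based proton density fat fraction (PDFF) quantification.

The reference compute plugin.  One slice holds real and imaginary images
of a multi-echo Dixon acquisition at three or more echo times.  Water and
fat protons resonate at slightly different frequencies (a chemical shift
of about 3.4 ppm of the scanner frequency, proportional to field
strength B0), so the magnitude signal beats as a function of echo time.
The mean magnitude over a user-drawn region of interest is fitted to the
single-peak magnitude model

    S(TE) = sqrt(W^2 + F^2 + 2 W F cos(2 pi df TE)) * exp(-R2* TE)

with water amplitude W >= 0, fat amplitude F >= 0, effective relaxation
rate R2* in [0, 1000] 1/s and df the fat-water frequency offset derived
from B0.  PDFF = 100 * F / (W + F) percent.  The magnitude model is
symmetric under swapping W and F, so the fit is multi-started and ties
are broken toward the lower fat fraction.

Results are exported as a spreadsheet (slice positions as rows, per-ROI
fat fractions as columns), gated on the goodness of fit: the file is
written only when every fitted ROI's coefficient of determination R^2
lies above a configurable threshold.
"""

from __future__ import annotations

import copy
import logging
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (ConsistencyError, EmptyRoiError, FitDataError,
                     NothingToExportError, PasteError)
from .plugin import ComputeSlice, PluginDescriptor, VersionedClass

log = logging.getLogger(__name__)

FATQUANT_VERSION = "1.0"
COMPUTE_BASE_VERSION = "1.0"

GYROMAGNETIC_RATIO_MHZ_PER_T = 42.577
FAT_WATER_SHIFT_PPM = 3.4
R2STAR_MAX = 1000.0  # 1/s
DEFAULT_R2_THRESHOLD = 0.95


def fat_water_offset_hz(b0_tesla: float) -> float:
    """Chemical-shift frequency offset between fat and water at B0."""
    if b0_tesla <= 0:
        raise FitDataError(f"field strength must be positive, got {b0_tesla}")
    return FAT_WATER_SHIFT_PPM * GYROMAGNETIC_RATIO_MHZ_PER_T * b0_tesla


def dixon_magnitude(te_s: np.ndarray, w: float, f: float, r2star: float,
                    delta_f_hz: float) -> np.ndarray:
    """Single-peak magnitude signal model evaluated at echo times (s)."""
    te_s = np.asarray(te_s, dtype=np.float64)
    beat = w * w + f * f + 2.0 * w * f * np.cos(2.0 * np.pi * delta_f_hz * te_s)
    return np.sqrt(np.maximum(beat, 0.0)) * np.exp(-r2star * te_s)


# --------------------------------------------------------------------------
# Polygon rasterization (even-odd rule on pixel centers)

def rasterize_polygon(vertices: Sequence[Sequence[float]],
                      shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose center lies inside the polygon.

    Vertices are (row, col) pairs; the polygon is closed automatically.
    Membership follows the even-odd (crossing number) rule: a pixel
    center is inside iff a ray cast in the +col direction crosses the
    polygon boundary an odd number of times.
    """
    verts = np.asarray(vertices, dtype=np.float64)
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (row, col) vertices")
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows, dtype=np.float64),
                         np.arange(cols, dtype=np.float64), indexing="ij")
    inside = np.zeros(shape, dtype=bool)
    n = verts.shape[0]
    for i in range(n):
        y1, x1 = verts[i]
        y2, x2 = verts[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edge never crosses a horizontal ray
        crosses = (y1 > rr) != (y2 > rr)
        with np.errstate(invalid="ignore"):
            x_int = x1 + (rr - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (cc < x_int)
    return inside


class RoiData:
    """One region of interest: contours, derived mask, per-echo source
    data for the fit, and the resulting fit parameters."""

    def __init__(self) -> None:
        self.contours: list[list[list[float]]] = []  # [[row, col], ...] each
        self.mask: np.ndarray | None = None
        self.echo_times_s: list[float] = []
        self.mean_intensities: list[float] = []
        self.fit: dict[str, float] | None = None  # {"W", "F", "R2star"}
        self.r_squared: float | None = None

    @property
    def pdff_percent(self) -> float | None:
        if self.fit is None:
            return None
        w, f = self.fit["W"], self.fit["F"]
        return 0.0 if w + f == 0 else 100.0 * f / (w + f)

    def is_empty(self) -> bool:
        return self.mask is None or not self.mask.any()


def merge_contours(roi: RoiData, new_stroke: Sequence[Sequence[float]],
                   shape: tuple[int, int]) -> RoiData:
    """Merge a drawn stroke into the ROI: the mask becomes the union of
    the previous mask and the rasterized (auto-closed) polygon.

    Strokes with fewer than 3 vertices are stray clicks and are ignored
    with a warning.
    """
    stroke = [list(map(float, v)) for v in new_stroke]
    if len(stroke) < 3:
        log.warning("ignoring stroke with %d vertices (need >= 3)", len(stroke))
        return roi
    new_mask = rasterize_polygon(stroke, shape)
    roi.mask = new_mask if roi.mask is None else (roi.mask | new_mask)
    roi.contours.append(stroke)
    return roi


def mean_roi_intensity(magnitudes: Sequence[np.ndarray],
                       mask: np.ndarray) -> list[float]:
    """Arithmetic mean of each echo's magnitude image over the mask."""
    if mask is None or not mask.any():
        raise EmptyRoiError("ROI contains no pixels")
    return [float(m[mask].mean()) for m in magnitudes]


# --------------------------------------------------------------------------
# Fitting

def _r_squared(y: np.ndarray, residuals: np.ndarray) -> float:
    ss_res = float(np.sum(residuals ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res <= 1e-12 * y.size else 0.0
    return 1.0 - ss_res / ss_tot


def fit_intensities(echo_times_s: Sequence[float],
                    intensities: Sequence[float],
                    b0_tesla: float) -> tuple[dict[str, float], float]:
    """Bounded least-squares fit of the magnitude Dixon model.

    Multi-start over initial fat fractions of 10/50/90% resolves the
    water-fat swap ambiguity of the magnitude model; among solutions with
    equal residual the lower fat fraction wins.  Returns the fit
    parameters ``{"W", "F", "R2star"}`` and the coefficient of
    determination.
    """
    te = np.asarray(echo_times_s, dtype=np.float64)
    y = np.asarray(intensities, dtype=np.float64)
    if te.size < 3 or y.size != te.size:
        raise FitDataError(
            f"need >= 3 echoes with matching intensities, got {te.size} "
            f"echo times and {y.size} intensities")
    if np.any(y <= 0):
        raise FitDataError("intensities must be positive")
    delta_f = fat_water_offset_hz(b0_tesla)

    # R2* initial guess from the log-slope of the envelope.
    span = te[-1] - te[0]
    if span > 0 and y[0] > 0 and y[-1] > 0:
        r2_init = float(np.clip(np.log(y[0] / y[-1]) / span, 0.0, 500.0))
    else:
        r2_init = 30.0
    amp = float(y.max())

    def residual(params: np.ndarray) -> np.ndarray:
        w, f, r2 = params
        return dixon_magnitude(te, w, f, r2, delta_f) - y

    candidates: list[tuple[float, float, np.ndarray]] = []
    for pdff0 in (0.1, 0.5, 0.9):
        x0 = np.array([(1.0 - pdff0) * amp, pdff0 * amp, r2_init])
        sol = least_squares(residual, x0,
                            bounds=([0.0, 0.0, 0.0],
                                    [np.inf, np.inf, R2STAR_MAX]),
                            ftol=1e-12, xtol=1e-12, gtol=1e-12)
        for params in (sol.x, sol.x[[1, 0, 2]]):  # model symmetric in W<->F
            w, f, r2 = params
            res = residual(np.array([w, f, r2]))
            ss = float(np.sum(res ** 2))
            total = w + f
            pdff = 0.0 if total == 0 else 100.0 * f / total
            candidates.append((ss, pdff, np.array([w, f, r2])))

    best_ss = min(c[0] for c in candidates)
    tol = best_ss * 1e-9 + 1e-12 * float(np.sum(y ** 2))
    ss, pdff, params = min((c for c in candidates if c[0] <= best_ss + tol),
                           key=lambda c: c[1])
    fit = {"W": float(params[0]), "F": float(params[1]),
           "R2star": float(params[2])}
    return fit, _r_squared(y, residual(params))


# --------------------------------------------------------------------------
# The plugin class

class FatquantSlice(ComputeSlice):
    """One slice of a real/imaginary multi-echo Dixon acquisition with
    up to ``len(roi_hotkeys)`` regions of interest."""

    ENTRY_PROPERTIES = {"pSliceLocation": "slice_location",
                        "pSliceDone": "done"}
    ENTRY_METHODS = {"mGetPDFF": "get_pdff"}

    #: contour-set clipboard shared between slices (copy/paste ROIs)
    _clipboard: dict[str, Any] | None = None

    def __init__(self) -> None:
        super().__init__()
        self.real_label = "Real"
        self.imag_label = "Imaginary"
        self.rois: list[RoiData] = [RoiData() for _ in range(3)]
        self.hotkeys: list[str] = ["1", "2", "3"]
        self.active_roi: int | None = None
        self.greyed = False
        self.display_mode = "magnitude"
        self.display_echo = 0
        self.echo_times_s: list[float] = []
        self.b0_tesla = 1.5
        self._stroke: list[list[float]] | None = None

    # -- mandatory hooks ---------------------------------------------------

    def init_app(self, config) -> None:
        if config is not None:
            names = list(config.image_names) or ["Real", "Imaginary"]
            self.real_label = names[0]
            self.imag_label = names[1] if len(names) > 1 else names[0]
            self.hotkeys = list(config.roi_hotkeys) or ["1", "2", "3"]
        self.rois = [RoiData() for _ in self.hotkeys]
        reals = self.images.get(self.real_label, [])
        if reals:
            self.echo_times_s = [
                float(r.tags.get("EchoTime", 0.0)) / 1000.0 for r in reals]
            b0 = reals[0].tags.get("MagneticFieldStrength")
            if b0 is not None:
                self.b0_tesla = float(b0)

    def get_img2display(self, mode: str | None = None) -> np.ndarray:
        mode = mode or self.display_mode
        echo = self.display_echo
        if mode == "magnitude":
            return self.compute_magnitudes()[echo]
        if mode == "real":
            return self.images[self.real_label][echo].pixel_data
        if mode == "imaginary":
            return self.images[self.imag_label][echo].pixel_data
        raise ValueError(f"unknown display mode {mode!r}")

    def post_plot(self) -> list[dict]:
        overlays = []
        for i, roi in enumerate(self.rois):
            if self.greyed and self.active_roi is not None:
                state = "active" if i == self.active_roi else "greyed"
            else:
                state = "colored"
            for contour in roi.contours:
                overlays.append({"type": "polyline", "vertices": contour,
                                 "state": state, "roi": i})
        return overlays

    def draw_graph(self) -> dict[str, list]:
        if self.active_roi is None:
            return {"points": [], "curve": []}
        roi = self.rois[self.active_roi]
        if roi.fit is None:
            return {"points": [], "curve": []}
        points = list(zip(roi.echo_times_s, roi.mean_intensities))
        te = np.linspace(min(roi.echo_times_s), max(roi.echo_times_s), 100)
        curve_y = dixon_magnitude(te, roi.fit["W"], roi.fit["F"],
                                  roi.fit["R2star"],
                                  fat_water_offset_hz(self.b0_tesla))
        return {"points": points,
                "curve": list(zip(te.tolist(), curve_y.tolist()))}

    def get_textbox_lines(self) -> list[str]:
        if self.display_mode == "magnitude":
            kind = "Magnitude"
        elif self.display_mode == "real":
            kind = self.images[self.real_label][0].image_type
        else:
            kind = self.images[self.imag_label][0].image_type
        return [f"Slice {self.index + 1}", kind]

    def custom_save(self, session, directory) -> None:
        try:
            path, warnings = save_xls(session, directory)
            for w in warnings:
                log.warning("%s", w)
            if path is not None:
                log.info("spreadsheet written to %s", path)
        except NothingToExportError:
            log.warning("no fitted ROI in session; spreadsheet not written")

    # -- events ------------------------------------------------------------

    def image_button_down(self, event, ui_state=None) -> None:
        if self.active_roi is None:
            msg = "stroke ignored: no active ROI (press a hotkey first)"
            log.warning(msg)
            if ui_state is not None:
                ui_state.warnings.append(msg)
            self._stroke = None
            return
        self._stroke = [[float(event.payload["row"]),
                         float(event.payload["col"])]]

    def image_button_motion(self, event, ui_state=None) -> None:
        if self._stroke is not None:
            self._stroke.append([float(event.payload["row"]),
                                 float(event.payload["col"])])

    def image_button_up(self, event, ui_state=None) -> None:
        if self._stroke is None:
            return
        if "row" in event.payload:
            self._stroke.append([float(event.payload["row"]),
                                 float(event.payload["col"])])
        stroke, self._stroke = self._stroke, None
        shape = self.image_shape()
        stroke = [[min(max(r, 0.0), shape[0] - 1.0),
                   min(max(c, 0.0), shape[1] - 1.0)] for r, c in stroke]
        roi = self.rois[self.active_roi]
        merge_contours(roi, stroke, shape)
        if not roi.is_empty():
            self.refit_roi(self.active_roi)

    def key_press(self, event, ui_state=None) -> None:
        key = str(event.payload.get("key", ""))
        if key in self.hotkeys:
            self.active_roi = self.hotkeys.index(key)
            self.greyed = True

    def key_release(self, event, ui_state=None) -> None:
        self.greyed = False

    def table_cell_edit(self, event, entry_name: str) -> None:
        # Only the Done flag is editable from the table.
        if entry_name == "pSliceDone":
            self.done = bool(event.payload.get("value"))

    # -- computation -------------------------------------------------------

    def image_shape(self) -> tuple[int, int]:
        first = next(iter(self.images.values()))[0]
        return first.pixel_data.shape

    def compute_magnitudes(self) -> list[np.ndarray]:
        """Per-echo magnitude images sqrt(real^2 + imaginary^2)."""
        reals = self.images[self.real_label]
        imags = self.images[self.imag_label]
        if len(reals) != len(imags):
            raise ConsistencyError(
                f"{len(reals)} real vs {len(imags)} imaginary echoes")
        out = []
        for re, im in zip(reals, imags):
            if re.pixel_data.shape != im.pixel_data.shape:
                raise ConsistencyError(
                    f"shape mismatch {re.pixel_data.shape} vs "
                    f"{im.pixel_data.shape}")
            out.append(np.sqrt(re.pixel_data.astype(np.float64) ** 2
                               + im.pixel_data.astype(np.float64) ** 2))
        return out

    def refit_roi(self, roi_index: int) -> None:
        roi = self.rois[roi_index]
        means = mean_roi_intensity(self.compute_magnitudes(), roi.mask)
        roi.echo_times_s = list(self.echo_times_s)
        roi.mean_intensities = means
        roi.fit, roi.r_squared = fit_intensities(
            roi.echo_times_s, means, self.b0_tesla)

    def get_pdff(self, roi_index: int) -> float | None:
        """Fat fraction of ROI ``roi_index`` (1-based) in percent, or the
        not-computed sentinel (None; rendered blank in the table)."""
        roi = self.rois[roi_index - 1]
        return roi.pdff_percent

    def apply_stroke(self, roi_index: int,
                     polygon: Sequence[Sequence[float]]) -> None:
        """Headless equivalent of drawing one stroke on ROI ``roi_index``
        (0-based): merge, then re-fit."""
        roi = self.rois[roi_index]
        merge_contours(roi, polygon, self.image_shape())
        if not roi.is_empty():
            self.refit_roi(roi_index)

    # -- menu callbacks ----------------------------------------------------

    def copy_rois(self) -> None:
        if all(not roi.contours for roi in self.rois):
            raise EmptyRoiError("copy requires at least one non-empty ROI")
        FatquantSlice._clipboard = {
            "shape": self.image_shape(),
            "contours": [copy.deepcopy(roi.contours) for roi in self.rois],
        }

    def paste_rois(self) -> None:
        clip = FatquantSlice._clipboard
        if clip is None:
            raise PasteError("nothing to paste: copy ROIs first")
        if tuple(clip["shape"]) != tuple(self.image_shape()):
            raise PasteError(
                f"clipboard shape {clip['shape']} does not match slice "
                f"shape {self.image_shape()}")
        self.rois = [RoiData() for _ in self.rois]
        for i, contours in enumerate(clip["contours"]):
            for contour in contours:
                merge_contours(self.rois[i], contour, self.image_shape())
            if not self.rois[i].is_empty():
                self.refit_roi(i)

    def show_magnitude(self) -> None:
        self.display_mode = "magnitude"

    def show_real_part(self) -> None:
        self.display_mode = "real"

    def show_imaginary_part(self) -> None:
        self.display_mode = "imaginary"

    # -- persistence -------------------------------------------------------

    def get_payload(self) -> dict[str, Any]:
        return {
            "rois": [{
                "contours": roi.contours,
                "echo_times_s": roi.echo_times_s,
                "mean_intensities": roi.mean_intensities,
                "fit": roi.fit,
                "r_squared": roi.r_squared,
            } for roi in self.rois],
            "active_roi": self.active_roi,
            "display_mode": self.display_mode,
            "display_echo": self.display_echo,
        }

    def set_payload(self, payload: dict[str, Any]) -> None:
        docs = payload.get("rois", [])
        self.rois = [RoiData() for _ in docs] or self.rois
        shape = self.image_shape() if self.images else None
        for roi, doc in zip(self.rois, docs):
            roi.contours = [[list(map(float, v)) for v in contour]
                            for contour in doc.get("contours", [])]
            roi.echo_times_s = list(doc.get("echo_times_s", []))
            roi.mean_intensities = list(doc.get("mean_intensities", []))
            roi.fit = doc.get("fit")
            roi.r_squared = doc.get("r_squared")
            if shape is not None:
                for contour in roi.contours:
                    mask = rasterize_polygon(contour, shape)
                    roi.mask = mask if roi.mask is None else roi.mask | mask
        self.active_roi = payload.get("active_roi")
        self.display_mode = payload.get("display_mode", "magnitude")
        self.display_echo = int(payload.get("display_echo", 0))
        if self.images:
            reals = self.images.get(self.real_label, [])
            if reals:
                self.echo_times_s = [
                    float(r.tags.get("EchoTime", 0.0)) / 1000.0
                    for r in reals]
                b0 = reals[0].tags.get("MagneticFieldStrength")
                if b0 is not None:
                    self.b0_tesla = float(b0)


def _migrate_fatquant(payload: dict[str, Any], old_version: str) -> dict[str, Any]:
    """v1.0 is the first release; nothing to rewrite yet."""
    return payload


def fatquant_descriptor() -> PluginDescriptor:
    return PluginDescriptor(
        identifier="@cComputeFatquant",
        constructor=FatquantSlice,
        version_chain=[
            VersionedClass("FatquantSlice", FATQUANT_VERSION,
                           _migrate_fatquant),
            VersionedClass("ComputeSlice", COMPUTE_BASE_VERSION, None),
        ],
    )


# --------------------------------------------------------------------------
# Export and ROI sidecars

def save_xls(session, directory: str | Path,
             r2_threshold: float = DEFAULT_R2_THRESHOLD,
             filename: str | None = None) -> tuple[Path | None, list[str]]:
    """Write the PDFF results spreadsheet, gated on goodness of fit.

    One row per slice (first column the slice position in mm), one PDFF
    column per ROI.  The file is only created when every fitted ROI's
    R^2 lies at or above ``r2_threshold``; otherwise no file is written
    and the returned warnings name each offending (slice, ROI, R^2).
    A ``.xlsx`` filename selects Excel output; the default is CSV.
    """
    directory = Path(directory)
    fitted = [(si, ri, roi)
              for si, slice_obj in enumerate(session.slices)
              for ri, roi in enumerate(slice_obj.rois)
              if roi.fit is not None]
    if not fitted:
        raise NothingToExportError("no fitted ROI in the session")
    warnings = [
        f"slice {si + 1} ROI {ri + 1}: R^2={roi.r_squared:.4f} below "
        f"threshold {r2_threshold}"
        for si, ri, roi in fitted if roi.r_squared < r2_threshold]
    if warnings:
        return None, warnings

    n_rois = max(len(s.rois) for s in session.slices)
    rows = []
    for slice_obj in session.slices:
        row: dict[str, Any] = {"Pos": slice_obj.slice_location}
        for ri in range(n_rois):
            roi = slice_obj.rois[ri] if ri < len(slice_obj.rois) else None
            pdff = roi.pdff_percent if roi is not None else None
            row[f"PDFF({ri + 1})"] = "" if pdff is None else pdff
        rows.append(row)
    frame = pd.DataFrame(rows)

    if filename is None:
        filename = (f"{session.patient_name}_{session.acquisition_time}_"
                    f"{session.application_name}_PDFF.csv")
    path = directory / filename
    if path.suffix.lower() == ".xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)
    return path, []


def export_rois(session) -> dict[str, Any]:
    """ROI sidecar document: per slice, the list of polygons per ROI."""
    return {"slices": [{
        "index": si,
        "rois": [copy.deepcopy(slice_obj.rois[ri].contours)
                 for ri in range(len(slice_obj.rois))],
    } for si, slice_obj in enumerate(session.slices)]}


def apply_rois(session, sidecar: dict[str, Any]) -> None:
    """Apply a ROI sidecar to a session (headless stand-in for drawing).

    ``{"all_slices": [[poly, ...], ...]}`` applies one contour set per
    ROI to every slice; ``{"slices": [{"index": i, "rois": [...]}]}``
    targets individual slices.  Fits are run after merging.
    """
    if "all_slices" in sidecar:
        targets = [(slice_obj, sidecar["all_slices"])
                   for slice_obj in session.slices]
    else:
        targets = [(session.slices[doc["index"]], doc["rois"])
                   for doc in sidecar.get("slices", [])]
    for slice_obj, roi_polys in targets:
        for ri, polygons in enumerate(roi_polys):
            for polygon in polygons:
                slice_obj.apply_stroke(ri, polygon)
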