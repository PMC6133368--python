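"""Headless session controller.

This layer owns the overall workflow of a slice-by-slice analysis:
discovering and loading a dataset into per-slice compute objects,
dispatching user events to the plugin, running the ordered UI-update
routine, building the menu tree, and persisting sessions with version
migration.  The "UI" is an inspectable :class:`UIState` value — no
widgets are rendered, which keeps every interaction scriptable and
testable.

Sessions are stored as zip containers (extension ``.session``) holding a
``manifest.json`` plus one raw binary file per image array.  Contents are
plain self-describing records, detached from any live code object, so a
newer release can migrate an old container class by class.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
import zipfile
from pathlib import Path
from typing import Any

import numpy as np

from .config import ApplicationConfig, parse_entry_call
from .errors import (ConsistencyError, DispatchError, EmptyDatasetError,
                     FormatError, ForwardVersionError, MigrationError)
from .image_model import IMAGE_CLASS_VERSION, ImageRecord
from .plugin import (ComputeSlice, PluginRegistry, graph_update, image_update,
                     text_update)

log = logging.getLogger(__name__)

CONTROLLER_VERSION = "1.0"

#: SliceLocation values are grouped after rounding to this many decimals (mm).
_LOCATION_DECIMALS = 3

EVENT_NAMES = frozenset({
    "image_button_down", "image_button_motion", "image_button_up",
    "graph_button_down", "mouse_wheel", "key_press", "key_release",
    "table_cell_select", "table_cell_edit", "menu_click",
})


@dataclasses.dataclass
class Event:
    """A user event; ``payload`` content depends on ``name``.

    Image events carry 0-based ``(row, col)`` pixel coordinates, key
    events a ``key`` character, table events ``(row, col)`` cell indices
    (plus ``value`` for edits), menu clicks a ``path`` list and mouse
    wheel a ``delta``.
    """

    name: str
    payload: dict[str, Any] = dataclasses.field(default_factory=dict)


@dataclasses.dataclass
class UIState:
    """The complete inspectable front-end state."""

    current_slice_index: int = 0
    displayed_image: np.ndarray | None = None
    overlays: list[dict] = dataclasses.field(default_factory=list)
    graph: dict[str, list] = dataclasses.field(
        default_factory=lambda: {"points": [], "curve": []})
    text_lines: list[str] = dataclasses.field(default_factory=list)
    table: list[list[Any]] = dataclasses.field(default_factory=list)
    menu_tree: list[dict] = dataclasses.field(default_factory=list)
    warnings: list[str] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class Session:
    """An ordered array of compute slices plus complete version info."""

    slices: list[ComputeSlice]
    version_info: dict[str, Any]
    source_folder: str = ""
    application_name: str = ""
    patient_name: str = ""
    acquisition_time: str = ""
    compute_class: str = ""


# --------------------------------------------------------------------------
# Dataset discovery and loading

def discover_images(root: str | Path,
                    config: ApplicationConfig) -> dict[str, list[Path]]:
    """Find each channel's files by directory + filename glob pattern.

    For channel *i*, files matching ``image_filename_patterns[i]`` are
    collected from subdirectories of ``root`` matching
    ``image_directory_patterns[i]`` and returned lexicographically
    sorted.  A channel with zero matches is an error: the dataset cannot
    be analyzed without it.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"no such dataset directory: {root}")
    found: dict[str, list[Path]] = {}
    for name, dir_pat, file_pat in zip(config.image_names,
                                       config.image_directory_patterns,
                                       config.image_filename_patterns):
        dirs = sorted(p for p in root.glob(dir_pat) if p.is_dir())
        files: list[Path] = []
        for d in dirs:
            files.extend(p for p in d.glob(file_pat) if p.is_file())
        files.sort()
        if not files:
            raise EmptyDatasetError(
                f"no files for channel {name!r} under {root} "
                f"(directory pattern {dir_pat!r}, filename pattern {file_pat!r})")
        found[name] = files
    return found


def _location_key(loc: float) -> float:
    return round(float(loc), _LOCATION_DECIMALS)


def load_dataset(root: str | Path, app_config: ApplicationConfig,
                 registry: PluginRegistry) -> Session:
    """Load a dataset directory into a Session, one slice per distinct
    SliceLocation, with the plugin's ``init_app`` run on every slice."""
    from .image_model import read_dicom

    root = Path(root)
    descriptor = registry.get(app_config.compute_class)
    paths = discover_images(root, app_config)

    # channel -> location -> records
    grouped: dict[str, dict[float, list[ImageRecord]]] = {}
    for channel, files in paths.items():
        by_loc: dict[float, list[ImageRecord]] = {}
        for seq, p in enumerate(files):
            rec = read_dicom(p, image_type=channel)
            rec.sequence_number = seq
            loc = rec.tags.get("SliceLocation")
            if loc is None:
                raise ConsistencyError(f"{p} lacks a SliceLocation tag")
            by_loc.setdefault(_location_key(loc), []).append(rec)
        grouped[channel] = by_loc

    channels = list(grouped)
    locations = set(grouped[channels[0]])
    for channel in channels[1:]:
        if set(grouped[channel]) != locations:
            orphans = sorted(set(grouped[channel]) ^ locations)
            raise ConsistencyError(
                f"channels cover different slice locations; orphan "
                f"locations: {orphans}")
    echo_counts = {len(recs) for by_loc in grouped.values()
                   for recs in by_loc.values()}
    if len(echo_counts) != 1:
        raise ConsistencyError(
            f"echo counts differ across channels/slices: {sorted(echo_counts)}")

    slices: list[ComputeSlice] = []
    for loc in sorted(locations):
        slice_obj = descriptor.constructor()
        slice_obj.slice_location = loc
        for channel in channels:
            slice_obj.add_images(channel, grouped[channel][loc])
        slice_obj.init_app(app_config)
        slices.append(slice_obj)
    for i, s in enumerate(slices):
        s.index = i

    first = slices[0].images[channels[0]][0]
    patient = str(first.tags.get("PatientName", ""))
    acq = _acquisition_stamp(first)
    version_info = {
        "controller_version": CONTROLLER_VERSION,
        "compute": {vc.name: vc.version for vc in descriptor.version_chain},
        "image": {"ImageRecord": IMAGE_CLASS_VERSION},
        "framework_config_version": "1.0",
        "application_config_version": app_config.version,
    }
    log.info("loaded %d slices from %s", len(slices), root)
    return Session(slices=slices, version_info=version_info,
                   source_folder=str(root),
                   application_name=app_config.application_name,
                   patient_name=patient, acquisition_time=acq,
                   compute_class=app_config.compute_class)


def _acquisition_stamp(record: ImageRecord) -> str:
    date = str(record.tags.get("AcquisitionDate", "")) or "00000000"
    time = str(record.tags.get("AcquisitionTime", "")) or "000000"
    return f"{date}T{time.split('.')[0]}"


# --------------------------------------------------------------------------
# Session persistence

def get_save_file_prefix(session: Session, now: str | None = None) -> str:
    """``{patientName}_{acquisitionTime}_{currentTime}_{application}_data``"""
    if now is None:
        now = _dt.datetime.now().strftime("%Y%m%dT%H%M%S")
    return (f"{session.patient_name}_{session.acquisition_time}_{now}_"
            f"{session.application_name}_data")


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def save_session(session: Session, folder: str | Path,
                 now: str | None = None,
                 run_custom_save: bool = True) -> Path:
    """Persist a session to ``folder`` and run the plugin's custom-save
    hook.  Returns the path of the written ``.session`` container."""
    folder = Path(folder)
    if not folder.is_dir():
        raise IOError(f"not a writable directory: {folder}")
    path = folder / (get_save_file_prefix(session, now) + ".session")

    manifest: dict[str, Any] = {
        "version_info": _jsonify(session.version_info),
        "application_name": session.application_name,
        "compute_class": session.compute_class,
        "patient_name": session.patient_name,
        "acquisition_time": session.acquisition_time,
        "source_folder": session.source_folder,
        "slices": [],
    }
    arrays: dict[str, np.ndarray] = {}
    for si, slice_obj in enumerate(session.slices):
        channels: dict[str, list[dict]] = {}
        for channel, records in slice_obj.images.items():
            entries = []
            for ei, rec in enumerate(records):
                arr_name = f"arrays/{si:03d}_{channel}_{ei:02d}.bin"
                arrays[arr_name] = np.ascontiguousarray(rec.pixel_data)
                entries.append({
                    "array": arr_name,
                    "dtype": rec.pixel_data.dtype.str,
                    "shape": list(rec.pixel_data.shape),
                    "filename": rec.filename,
                    "path": rec.path,
                    "acquisition_date": rec.acquisition_date,
                    "sequence_number": rec.sequence_number,
                    "class_version": rec.class_version,
                    "image_type": rec.image_type,
                    "tags": _jsonify(rec.tags),
                })
            channels[channel] = entries
        manifest["slices"].append({
            "slice_location": slice_obj.slice_location,
            "done": bool(slice_obj.done),
            "channels": channels,
            "app_payload": _jsonify(slice_obj.get_payload()),
        })

    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        stamp = (2020, 1, 1, 0, 0, 0)  # fixed: container bytes reproducible
        info = zipfile.ZipInfo("manifest.json", date_time=stamp)
        zf.writestr(info, json.dumps(manifest, indent=1, sort_keys=True))
        for arr_name in sorted(arrays):
            info = zipfile.ZipInfo(arr_name, date_time=stamp)
            zf.writestr(info, arrays[arr_name].tobytes())

    if run_custom_save and session.slices:
        session.slices[0].custom_save(session, folder)
    log.info("session saved to %s", path)
    return path


def _version_tuple(v: str) -> tuple[int, ...]:
    return tuple(int(part) for part in str(v).split("."))


def load_session(path: str | Path, registry: PluginRegistry) -> Session:
    """Load a ``.session`` container, migrating outdated class payloads.

    For every class in the plugin's version chain whose stored version is
    older than the running code, the class's migration function is
    applied to each slice payload — most specific class first, proceeding
    to the superclass.  Containers newer than the code are refused.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such session file: {path}")
    try:
        zf = zipfile.ZipFile(path)
    except zipfile.BadZipFile as exc:
        raise FormatError(f"not a session container: {path}") from exc
    with zf:
        manifest = json.loads(zf.read("manifest.json"))
        blobs = {n: zf.read(n) for n in zf.namelist() if n != "manifest.json"}

    descriptor = registry.get(manifest["compute_class"])
    stored_versions = manifest["version_info"].get("compute", {})

    ctrl_stored = manifest["version_info"].get("controller_version",
                                               CONTROLLER_VERSION)
    if _version_tuple(ctrl_stored) > _version_tuple(CONTROLLER_VERSION):
        raise ForwardVersionError(
            f"session written by controller {ctrl_stored}, running "
            f"{CONTROLLER_VERSION}")

    # Determine pending migrations, most specific class first.
    pending: list[tuple[str, str, Any]] = []
    for vc in descriptor.version_chain:
        stored = stored_versions.get(vc.name, vc.version)
        if _version_tuple(stored) > _version_tuple(vc.version):
            raise ForwardVersionError(
                f"session stores {vc.name} v{stored}, code is at "
                f"v{vc.version}")
        if _version_tuple(stored) < _version_tuple(vc.version):
            if vc.migrate is None:
                raise MigrationError(
                    f"no migration for {vc.name} v{stored} -> v{vc.version}")
            pending.append((vc.name, stored, vc.migrate))

    slices: list[ComputeSlice] = []
    for sdoc in manifest["slices"]:
        slice_obj = descriptor.constructor()
        slice_obj.slice_location = float(sdoc["slice_location"])
        slice_obj.done = bool(sdoc["done"])
        for channel, entries in sdoc["channels"].items():
            records = []
            for entry in entries:
                arr = np.frombuffer(
                    blobs[entry["array"]],
                    dtype=np.dtype(entry["dtype"])).reshape(entry["shape"])
                records.append(ImageRecord(
                    pixel_data=arr.copy(),
                    filename=entry["filename"],
                    path=entry["path"],
                    acquisition_date=entry["acquisition_date"],
                    sequence_number=entry["sequence_number"],
                    class_version=entry["class_version"],
                    image_type=entry["image_type"],
                    tags=dict(entry["tags"]),
                ))
            slice_obj.add_images(channel, records)
        payload = dict(sdoc["app_payload"])
        for name, stored, migrate in pending:
            log.info("migrating %s payload v%s", name, stored)
            payload = migrate(payload, stored)
        slice_obj.set_payload(payload)
        slices.append(slice_obj)
    for i, s in enumerate(slices):
        s.index = i

    version_info = dict(manifest["version_info"])
    version_info["controller_version"] = CONTROLLER_VERSION
    version_info["compute"] = {vc.name: vc.version
                               for vc in descriptor.version_chain}
    return Session(slices=slices, version_info=version_info,
                   source_folder=manifest.get("source_folder", ""),
                   application_name=manifest["application_name"],
                   patient_name=manifest["patient_name"],
                   acquisition_time=manifest["acquisition_time"],
                   compute_class=manifest["compute_class"])


# --------------------------------------------------------------------------
# Menu construction

def build_menu(config: ApplicationConfig) -> list[dict]:
    """Deterministic menu tree: the framework's Load Data / Save Data
    entries first, then the config's entries in config order."""
    from .config import parse_menu_entries

    tree: list[dict] = [
        {"label": "Load Data", "callback": "load_data", "children": []},
        {"label": "Save Data", "callback": "save_data", "children": []},
    ]

    def insert(children: list[dict], path: list[str], callback: str) -> None:
        label = path[0]
        if len(path) == 1:
            children.append({"label": label, "callback": callback,
                             "children": []})
            return
        for node in children:
            if node["label"] == label and node["callback"] is None:
                insert(node["children"], path[1:], callback)
                return
        node = {"label": label, "callback": None, "children": []}
        children.append(node)
        insert(node["children"], path[1:], callback)

    for entry in parse_menu_entries(config):
        insert(tree, entry.path, entry.callback)
    return tree


def _find_menu_callback(tree: list[dict], path: list[str]) -> str | None:
    for node in tree:
        if node["label"] != path[0]:
            continue
        if len(path) == 1:
            return node["callback"]
        return _find_menu_callback(node["children"], path[1:])
    return None


# --------------------------------------------------------------------------
# UI update and event dispatch

def ui_update(session: Session, ui_state: UIState,
              config: ApplicationConfig,
              registry: PluginRegistry | None = None) -> UIState:
    """The ordered UI-update routine.

    Image, graph and text are regenerated through the plugin hooks in
    that order; the table is populated last so any change the hooks made
    to the session is reflected in it.  Cell (r, c) is the value of
    ``config.table_entry_calls[c]`` evaluated against slice r.
    """
    if not session.slices:
        raise ConsistencyError("ui_update requires a session with >= 1 slice")
    idx = min(max(ui_state.current_slice_index, 0), len(session.slices) - 1)
    ui_state.current_slice_index = idx
    slice_obj = session.slices[idx]

    image_update(slice_obj, ui_state)
    graph_update(slice_obj, ui_state)
    text_update(slice_obj, ui_state)

    calls = [parse_entry_call(text) for text in config.table_entry_calls]
    table: list[list[Any]] = []
    for s in session.slices:
        row = []
        for call in calls:
            value = s.resolve_entry(call)
            row.append("" if value is None else value)
        table.append(row)
    ui_state.table = table
    ui_state.menu_tree = build_menu(config)
    return ui_state


def dispatch_event(session: Session, ui_state: UIState, event: Event,
                   registry: PluginRegistry,
                   config: ApplicationConfig) -> UIState:
    """Route one user event, then run the UI-update routine."""
    if event.name not in EVENT_NAMES:
        raise DispatchError(f"unknown event name {event.name!r}; known: "
                            f"{sorted(EVENT_NAMES)}")
    slice_obj = session.slices[ui_state.current_slice_index]

    if event.name == "table_cell_select":
        row = int(event.payload["row"])
        if not 0 <= row < len(session.slices):
            raise DispatchError(f"table row {row} out of range")
        ui_state.current_slice_index = row
    elif event.name == "table_cell_edit":
        col = int(event.payload.get("col", -1))
        entry_name = ""
        if 0 <= col < len(config.table_entry_calls):
            entry_name = parse_entry_call(config.table_entry_calls[col]).name
        handler = getattr(slice_obj, "table_cell_edit", None)
        if callable(handler):
            handler(event, entry_name)
    elif event.name in ("image_button_down", "image_button_motion",
                        "image_button_up"):
        getattr(slice_obj, event.name)(event, ui_state)
    elif event.name == "graph_button_down":
        handler = getattr(slice_obj, "graph_button_down", None)
        if callable(handler):
            handler(event, ui_state)
    elif event.name == "mouse_wheel":
        delta = int(event.payload.get("delta", 0))
        idx = ui_state.current_slice_index + delta
        ui_state.current_slice_index = min(max(idx, 0),
                                           len(session.slices) - 1)
    elif event.name in ("key_press", "key_release"):
        getattr(slice_obj, event.name)(event, ui_state)
    elif event.name == "menu_click":
        path = list(event.payload["path"])
        callback = _find_menu_callback(build_menu(config), path)
        if callback is None:
            raise DispatchError(f"no menu entry at path {path!r}")
        if callback not in ("load_data", "save_data"):
            method = getattr(slice_obj, callback, None)
            if not callable(method):
                raise DispatchError(
                    f"menu callback {callback!r} is not a plugin method")
            method()
    return ui_update(session, ui_state, config, registry)


# --------------------------------------------------------------------------
# Auto-save

def maybe_auto_save(session: Session, folder: str | Path,
                    last_save: float, now: float,
                    auto_save_interval_s: float) -> Path | None:
    """Save when the configured interval has elapsed; the host owns the
    clock and calls this from its timer.  Returns the path when saved."""
    if now - last_save >= auto_save_interval_s:
        return save_session(session, folder)
    return None
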