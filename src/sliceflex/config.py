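"""The two JSON configuration documents that drive the framework.

``frameworkConfig.json`` stores general program parameters (auto-save
interval, UI element visibility, selected event callbacks, keyboard
shortcuts).  ``applicationConfig.json`` stores everything specific to one
application: which compute plugin to instantiate, how to discover image
files, what the result table shows, and which menu entries to add.

Key names are camelCase in the JSON documents; unknown keys are preserved
on round trip but otherwise ignored, so configs written by newer code
still load.  ``imgSearchDir`` / ``imgSearchName`` are accepted as aliases
for ``imageDirectoryPattern`` / ``imageFilenamePattern``.
"""

from __future__ import annotations

import dataclasses
import json
import re
from pathlib import Path
from typing import Any

from .errors import ConfigParseError, ConfigValidationError

FRAMEWORK_CONFIG_VERSION = "1.0"
APPLICATION_CONFIG_VERSION = "1.0"

#: Event names the controller recognizes (see controller.Event).
RECOGNIZED_EVENTS = frozenset({
    "image_button_down", "image_button_motion", "image_button_up",
    "graph_button_down", "mouse_wheel", "key_press", "key_release",
    "table_cell_select", "table_cell_edit", "menu_click",
})

_ALIASES = {
    "imgSearchDir": "imageDirectoryPattern",
    "imgSearchName": "imageFilenamePattern",
}


@dataclasses.dataclass
class MenuEntry:
    """One application menu entry: a path (top-level field, then leaf
    label) and the identifier of the plugin method it invokes."""

    path: list[str]
    callback: str


@dataclasses.dataclass
class EntryCall:
    """A parsed table entry call.

    ``"pSliceLocation"`` is a property lookup; ``"mGetPDFF(1)"`` is a
    method call with a 1-based integer argument.
    """

    kind: str  # "property-lookup" | "method-call"
    name: str
    arg: int | None = None


@dataclasses.dataclass
class FrameworkConfig:
    auto_save_interval_s: float = 300.0
    ui_visibility: dict[str, str] = dataclasses.field(
        default_factory=lambda: {"image": "on", "graph": "on",
                                 "table": "on", "textbox": "on"})
    selected_callbacks: dict[str, str] = dataclasses.field(default_factory=dict)
    key_shortcuts: dict[str, str] = dataclasses.field(default_factory=dict)
    version: str = FRAMEWORK_CONFIG_VERSION
    extra: dict[str, Any] = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        if not self.auto_save_interval_s > 0:
            raise ConfigValidationError(
                "autoSaveIntervalS must be > 0, got "
                f"{self.auto_save_interval_s}")
        for event in self.selected_callbacks:
            if event not in RECOGNIZED_EVENTS:
                raise ConfigValidationError(
                    f"selectedCallbacks names unrecognized event {event!r}; "
                    f"known events: {sorted(RECOGNIZED_EVENTS)}")


@dataclasses.dataclass
class ApplicationConfig:
    application_name: str
    compute_class: str
    save_data_function: str = ""
    image_class: str = "cImageDcm"
    image_names: list[str] = dataclasses.field(default_factory=list)
    image_directory_patterns: list[str] = dataclasses.field(default_factory=list)
    image_filename_patterns: list[str] = dataclasses.field(default_factory=list)
    table_headers: list[str] = dataclasses.field(default_factory=list)
    table_entry_calls: list[str] = dataclasses.field(default_factory=list)
    menu_entries: list[MenuEntry] = dataclasses.field(default_factory=list)
    roi_hotkeys: list[str] = dataclasses.field(default_factory=list)
    ui_visibility: dict[str, str] = dataclasses.field(default_factory=dict)
    version: str = APPLICATION_CONFIG_VERSION
    extra: dict[str, Any] = dataclasses.field(default_factory=dict)

    def validate(self) -> None:
        if not self.application_name:
            raise ConfigValidationError("applicationName must be non-empty")
        if not (len(self.image_names) == len(self.image_directory_patterns)
                == len(self.image_filename_patterns)):
            raise ConfigValidationError(
                "imageNames, imageDirectoryPattern and imageFilenamePattern "
                f"must have equal lengths, got {len(self.image_names)}/"
                f"{len(self.image_directory_patterns)}/"
                f"{len(self.image_filename_patterns)}")
        if len(self.table_headers) != len(self.table_entry_calls):
            raise ConfigValidationError(
                "tableColumnHeaders and tableEntryCalls must have equal "
                f"lengths, got {len(self.table_headers)} vs "
                f"{len(self.table_entry_calls)}")
        for text in self.table_entry_calls:
            parse_entry_call(text)
        parse_menu_entries(self)
        for key in self.roi_hotkeys:
            if len(key) != 1:
                raise ConfigValidationError(
                    f"roiHotkeys entries must be single characters, got {key!r}")


_ENTRY_CALL_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*(?:\(\s*(\d+)\s*\))?\s*$")


def parse_entry_call(text: str) -> EntryCall:
    """Parse a table entry call string into an :class:`EntryCall`."""
    if not text or not text.strip():
        raise ConfigParseError("empty table entry call")
    m = _ENTRY_CALL_RE.match(text)
    if not m:
        raise ConfigParseError(f"malformed table entry call {text!r}")
    name, arg = m.group(1), m.group(2)
    if arg is None:
        return EntryCall(kind="property-lookup", name=name)
    arg_i = int(arg)
    if arg_i < 1:
        raise ConfigParseError(
            f"table entry call argument must be >= 1 (1-based): {text!r}")
    return EntryCall(kind="method-call", name=name, arg=arg_i)


def parse_menu_entries(config: ApplicationConfig) -> list[MenuEntry]:
    """Return the config's menu entries in order, rejecting duplicates."""
    seen: set[tuple[str, ...]] = set()
    out: list[MenuEntry] = []
    for entry in config.menu_entries:
        if len(entry.path) < 2:
            raise ConfigValidationError(
                f"menu path must have at least a top-level field and a leaf, "
                f"got {entry.path!r}")
        key = tuple(entry.path)
        if key in seen:
            raise ConfigValidationError(f"duplicate menu path {entry.path!r}")
        seen.add(key)
        out.append(entry)
    return out


# --------------------------------------------------------------------------
# JSON (de)serialization

_FW_KEYS = {
    "autoSaveIntervalS": "auto_save_interval_s",
    "uiVisibility": "ui_visibility",
    "selectedCallbacks": "selected_callbacks",
    "keyShortcuts": "key_shortcuts",
    "configVersion": "version",
}

_APP_KEYS = {
    "applicationName": "application_name",
    "ComputeClassFunctionCall": "compute_class",
    "saveDataFunction": "save_data_function",
    "imageClassFunctionCall": "image_class",
    "imageNames": "image_names",
    "imageDirectoryPattern": "image_directory_patterns",
    "imageFilenamePattern": "image_filename_patterns",
    "tableColumnHeaders": "table_headers",
    "tableEntryCalls": "table_entry_calls",
    "roiHotkeys": "roi_hotkeys",
    "uiVisibility": "ui_visibility",
    "configVersion": "version",
}


def _read_json(path: str | Path) -> dict[str, Any]:
    try:
        text = Path(path).read_text()
    except FileNotFoundError:
        raise FileNotFoundError(f"no such config file: {path}") from None
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigParseError(
            f"malformed JSON in {path} at line {exc.lineno}, "
            f"column {exc.colno}: {exc.msg}") from exc
    if not isinstance(doc, dict):
        raise ConfigParseError(f"config root must be a JSON object: {path}")
    return doc


def load_framework_config(path: str | Path) -> FrameworkConfig:
    doc = _read_json(path)
    cfg = FrameworkConfig()
    extra = {}
    for key, value in doc.items():
        field = _FW_KEYS.get(key)
        if field is None:
            extra[key] = value
        else:
            setattr(cfg, field, value)
    cfg.extra = extra
    cfg.validate()
    return cfg


def load_application_config(path: str | Path) -> ApplicationConfig:
    doc = _read_json(path)
    fields: dict[str, Any] = {}
    extra: dict[str, Any] = {}
    menu_entries: list[MenuEntry] = []
    for key, value in doc.items():
        key = _ALIASES.get(key, key)
        if key == "menuEntries":
            for item in value:
                menu_entries.append(
                    MenuEntry(path=list(item["path"]),
                              callback=str(item.get("callback", ""))))
            continue
        field = _APP_KEYS.get(key)
        if field is None:
            extra[key] = value
        else:
            fields[field] = value
    if "application_name" not in fields:
        raise ConfigValidationError(f"applicationName missing in {path}")
    if "compute_class" not in fields:
        raise ConfigValidationError(
            f"ComputeClassFunctionCall missing in {path}")
    cfg = ApplicationConfig(**fields, menu_entries=menu_entries, extra=extra)
    cfg.validate()
    return cfg


def framework_config_to_doc(cfg: FrameworkConfig) -> dict[str, Any]:
    doc: dict[str, Any] = {
        "autoSaveIntervalS": cfg.auto_save_interval_s,
        "uiVisibility": cfg.ui_visibility,
        "selectedCallbacks": cfg.selected_callbacks,
        "keyShortcuts": cfg.key_shortcuts,
        "configVersion": cfg.version,
    }
    doc.update(cfg.extra)
    return doc


def application_config_to_doc(cfg: ApplicationConfig) -> dict[str, Any]:
    doc: dict[str, Any] = {
        "applicationName": cfg.application_name,
        "ComputeClassFunctionCall": cfg.compute_class,
        "saveDataFunction": cfg.save_data_function,
        "imageClassFunctionCall": cfg.image_class,
        "imageNames": cfg.image_names,
        "imageDirectoryPattern": cfg.image_directory_patterns,
        "imageFilenamePattern": cfg.image_filename_patterns,
        "tableColumnHeaders": cfg.table_headers,
        "tableEntryCalls": cfg.table_entry_calls,
        "menuEntries": [{"path": e.path, "callback": e.callback}
                        for e in cfg.menu_entries],
        "roiHotkeys": cfg.roi_hotkeys,
        "uiVisibility": cfg.ui_visibility,
        "configVersion": cfg.version,
    }
    doc.update(cfg.extra)
    return doc


def save_framework_config(cfg: FrameworkConfig, path: str | Path) -> Path:
    cfg.validate()
    path = Path(path)
    path.write_text(json.dumps(framework_config_to_doc(cfg), indent=2) + "\n")
    return path


def save_application_config(cfg: ApplicationConfig, path: str | Path) -> Path:
    cfg.validate()
    path = Path(path)
    path.write_text(json.dumps(application_config_to_doc(cfg), indent=2) + "\n")
    return path


# --------------------------------------------------------------------------
# Defaults (the reference Fatquant application)

def default_framework_config() -> FrameworkConfig:
    return FrameworkConfig(
        auto_save_interval_s=300.0,
        ui_visibility={"image": "on", "graph": "on",
                       "table": "on", "textbox": "on"},
        selected_callbacks={},
        key_shortcuts={},
    )


def default_application_config() -> ApplicationConfig:
    """The configuration of the reference fat-quantification application.

    Channel-to-pattern pairing is positional: Real maps to ``*_RE_*.dcm``
    and Imaginary to ``*_IM_*.dcm``; both channels live in ``Dixon*``
    directories.
    """
    return ApplicationConfig(
        application_name="Fatquant",
        compute_class="@cComputeFatquant",
        save_data_function="@mSaveXLS",
        image_class="@cImageDcm",
        image_names=["Real", "Imaginary"],
        image_directory_patterns=["Dixon*", "Dixon*"],
        image_filename_patterns=["*_RE_*.dcm", "*_IM_*.dcm"],
        table_headers=["Pos", "Done", "PDFF(1)", "PDFF(2)", "PDFF(3)"],
        table_entry_calls=["pSliceLocation", "pSliceDone",
                           "mGetPDFF(1)", "mGetPDFF(2)", "mGetPDFF(3)"],
        menu_entries=[
            MenuEntry(["Functions", "Copy ROIs"], "copy_rois"),
            MenuEntry(["Functions", "Paste ROIs"], "paste_rois"),
            MenuEntry(["Image", "Show Magnitude"], "show_magnitude"),
            MenuEntry(["Image", "Show RealPart"], "show_real_part"),
            MenuEntry(["Image", "Show ImaginaryPart"], "show_imaginary_part"),
        ],
        roi_hotkeys=["1", "2", "3"],
        ui_visibility={"image": "on", "graph": "on", "table": "on"},
    )


def write_default_configs(directory: str | Path) -> tuple[Path, Path]:
    """Write frameworkConfig.json and applicationConfig.json pre-filled
    with the reference application's values; returns the two paths."""
    directory = Path(directory)
    if not directory.is_dir():
        raise IOError(f"not a writable directory: {directory}")
    fw = save_framework_config(default_framework_config(),
                               directory / "frameworkConfig.json")
    app = save_application_config(default_application_config(),
                                  directory / "applicationConfig.json")
    return fw, app
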