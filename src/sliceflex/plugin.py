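"""The per-slice compute contract and the plugin registry.

A compute plugin owns all input and derived data for one slice of a
multislice dataset — for example the real and imaginary images of one MR
slice — plus whatever results the application computes on it.  The
controller talks to plugins exclusively through the mandatory hooks
declared in :data:`REQUIRED_HOOKS`; a plugin missing any of them is
rejected at registration time, not when the hook is first called.

Hook names are snake_case; the historical camelCase method names they
correspond to are listed in ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Any, Callable

from .errors import ConsistencyError, RegistrationError
from .image_model import ImageRecord

COMPUTE_BASE_VERSION = "1.0"

#: Hooks every compute plugin must implement.
REQUIRED_HOOKS = (
    "init_app",
    "get_img2display",
    "post_plot",
    "draw_graph",
    "get_textbox_lines",
    "custom_save",
    "image_button_down",
    "image_button_motion",
    "image_button_up",
    "key_press",
    "key_release",
)

#: Tolerance (mm) within which images count as belonging to one slice.
SLICE_LOCATION_TOL_MM = 1e-6


class ComputeSlice:
    """Abstract per-slice container of grouped images plus app results.

    Subclasses implement all hooks in :data:`REQUIRED_HOOKS` and declare
    table accessors via :attr:`ENTRY_PROPERTIES` / :attr:`ENTRY_METHODS`,
    mapping entry-call names (e.g. ``"pSliceLocation"``) to attribute or
    method names on the subclass.
    """

    #: entry-call property name -> python attribute name
    ENTRY_PROPERTIES: dict[str, str] = {}
    #: entry-call method name -> python method name (called with 1-based arg)
    ENTRY_METHODS: dict[str, str] = {}

    def __init__(self) -> None:
        self.images: dict[str, list[ImageRecord]] = {}
        self.slice_location: float = 0.0
        self.done: bool = False
        self.index: int = 0  # position in the session's slice array
        self.app_payload: dict[str, Any] = {}

    # -- image bookkeeping -------------------------------------------------

    def add_images(self, channel: str, records: list[ImageRecord]) -> None:
        """Attach one channel's records (sorted by EchoTime when present),
        enforcing that all images in the slice share one SliceLocation."""
        def echo_key(rec: ImageRecord):
            return (rec.tags.get("EchoTime", 0.0),
                    rec.tags.get("InstanceNumber", rec.sequence_number))
        records = sorted(records, key=echo_key)
        for rec in records:
            loc = rec.tags.get("SliceLocation")
            if loc is not None and not math.isclose(
                    loc, self.slice_location, abs_tol=SLICE_LOCATION_TOL_MM):
                raise ConsistencyError(
                    f"image {rec.filename} at SliceLocation {loc} added to "
                    f"slice at {self.slice_location}")
        self.images[channel] = records

    def resolve_entry(self, call) -> Any:
        """Evaluate a parsed table entry call against this slice."""
        from .errors import TableError
        if call.kind == "property-lookup":
            attr = self.ENTRY_PROPERTIES.get(call.name)
            if attr is None or not hasattr(self, attr):
                raise TableError(
                    f"slice at {self.slice_location} mm has no property for "
                    f"entry call {call.name!r}")
            return getattr(self, attr)
        attr = self.ENTRY_METHODS.get(call.name)
        if attr is None or not hasattr(self, attr):
            raise TableError(
                f"slice at {self.slice_location} mm has no method for "
                f"entry call {call.name!r}")
        return getattr(self, attr)(call.arg)

    # -- serialization ----------------------------------------------------

    def get_payload(self) -> dict[str, Any]:
        """Plain-document application payload stored in the session."""
        return dict(self.app_payload)

    def set_payload(self, payload: dict[str, Any]) -> None:
        self.app_payload = dict(payload)


@dataclasses.dataclass
class VersionedClass:
    """One link of a plugin's inheritance chain: class name, current
    version, and the migration applied to payloads stored at an older
    version (pure: (payload document, old version) -> payload document)."""

    name: str
    version: str
    migrate: Callable[[dict[str, Any], str], dict[str, Any]] | None = None


@dataclasses.dataclass
class PluginDescriptor:
    """Registry entry resolving a config identifier to a plugin class."""

    identifier: str
    constructor: Callable[[], ComputeSlice]
    version_chain: list[VersionedClass]  # most specific class first


def normalize_identifier(identifier: str) -> str:
    """Identifiers in config files may carry a leading '@'; strip it."""
    return identifier.lstrip("@")


class PluginRegistry:
    """Maps application-config compute-class identifiers to plugins."""

    def __init__(self) -> None:
        self._plugins: dict[str, PluginDescriptor] = {}

    def register(self, descriptor: PluginDescriptor) -> None:
        key = normalize_identifier(descriptor.identifier)
        if key in self._plugins:
            raise RegistrationError(f"plugin {key!r} already registered")
        cls = descriptor.constructor
        probe = cls if isinstance(cls, type) else type(cls())
        missing = [h for h in REQUIRED_HOOKS
                   if not callable(getattr(probe, h, None))]
        if missing:
            raise RegistrationError(
                f"plugin {key!r} is missing required hooks: "
                f"{', '.join(sorted(missing))}")
        self._plugins[key] = descriptor

    def get(self, identifier: str) -> PluginDescriptor:
        key = normalize_identifier(identifier)
        try:
            return self._plugins[key]
        except KeyError:
            raise RegistrationError(f"no plugin registered as {key!r}") from None


def default_registry() -> PluginRegistry:
    """Registry with the built-in reference plugin registered."""
    from .fatquant import fatquant_descriptor
    reg = PluginRegistry()
    reg.register(fatquant_descriptor())
    return reg


# --------------------------------------------------------------------------
# Generic UI-update helpers

def draw_contour(contours: list, active_index: int | None = None) -> list[dict]:
    """Build overlay primitives for stored contours.

    One polyline per contour; when ``active_index`` (0-based) is given,
    that contour is flagged ``"active"`` and all others ``"greyed"``,
    otherwise every contour is ``"colored"``.
    """
    overlays = []
    for i, vertices in enumerate(contours):
        if active_index is None:
            state = "colored"
        else:
            state = "active" if i == active_index else "greyed"
        overlays.append({"type": "polyline", "vertices": vertices,
                         "state": state})
    return overlays


def image_update(slice_obj: ComputeSlice, ui_state, mode=None) -> None:
    """Clear residual image display state, then delegate to the plugin."""
    ui_state.displayed_image = None
    ui_state.overlays = []
    ui_state.displayed_image = slice_obj.get_img2display(mode)
    ui_state.overlays = list(slice_obj.post_plot())


def graph_update(slice_obj: ComputeSlice, ui_state) -> None:
    ui_state.graph = {"points": [], "curve": []}
    ui_state.graph = slice_obj.draw_graph()


def text_update(slice_obj: ComputeSlice, ui_state) -> None:
    ui_state.text_lines = []
    ui_state.text_lines = list(slice_obj.get_textbox_lines())
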