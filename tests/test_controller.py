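"""Controller layer: discovery, loading, persistence with migration,
event dispatch, the ordered UI-update routine and menu construction."""

import shutil

import numpy as np
import pytest

from sliceflex import (Event, ImageRecord, Session, UIState, build_menu,
                       discover_images, dispatch_event, load_dataset,
                       load_session, save_session, ui_update)
from sliceflex.controller import CONTROLLER_VERSION, get_save_file_prefix
from sliceflex.errors import (ConsistencyError, DispatchError,
                              EmptyDatasetError, ForwardVersionError,
                              MigrationError)
from sliceflex.plugin import (ComputeSlice, PluginDescriptor, PluginRegistry,
                              REQUIRED_HOOKS, VersionedClass)


class TestDiscovery:
    def test_both_channels_found_with_reference_patterns(
            self, phantom_tree, app_config):
        root, manifest = phantom_tree
        found = discover_images(root, app_config)
        n = manifest["n_slices"] * len(manifest["echo_times_ms"])
        assert sorted(found) == ["Imaginary", "Real"]
        assert len(found["Real"]) == n
        assert len(found["Imaginary"]) == n
        assert all("_RE_" in p.name for p in found["Real"])
        assert found["Real"] == sorted(found["Real"])

    def test_channel_without_matches_is_an_empty_dataset_error(
            self, phantom_tree, app_config, tmp_path):
        root, _ = phantom_tree
        partial = tmp_path / "partial"
        shutil.copytree(root, partial)
        for p in partial.rglob("*_IM_*.dcm"):
            p.unlink()
        with pytest.raises(EmptyDatasetError, match=r"\*_IM_\*"):
            discover_images(partial, app_config)


class TestLoadDataset:
    def test_one_slice_per_location_with_sorted_echoes(self, session):
        assert len(session.slices) == 4
        locations = [s.slice_location for s in session.slices]
        assert locations == sorted(locations)
        for s in session.slices:
            assert set(s.images) == {"Real", "Imaginary"}
            for records in s.images.values():
                assert len(records) == 6
                echoes = [r.tags["EchoTime"] for r in records]
                assert echoes == sorted(echoes)
                assert all(r.tags["SliceLocation"] ==
                           pytest.approx(s.slice_location) for r in records)

    def test_session_metadata_from_tags(self, session, app_config):
        assert session.patient_name == "PHANTOM01"
        assert session.acquisition_time == "20240101T120000"
        assert session.application_name == app_config.application_name
        assert session.version_info["controller_version"] == CONTROLLER_VERSION
        assert session.version_info["compute"]

    def test_missing_echo_in_one_channel_is_a_consistency_error(
            self, phantom_tree, app_config, registry, tmp_path):
        root, _ = phantom_tree
        broken = tmp_path / "broken"
        shutil.copytree(root, broken)
        victim = sorted(broken.rglob("*_RE_*.dcm"))[0]
        victim.unlink()
        with pytest.raises(ConsistencyError):
            load_dataset(broken, app_config, registry)


# ---------------------------------------------------------------------------
# Persistence and version migration

class TestSessionRoundTrip:
    def test_filename_follows_naming_scheme(self, fitted_session, tmp_path):
        path = save_session(fitted_session, tmp_path, now="20990101T000000")
        assert path.name == ("PHANTOM01_20240101T120000_20990101T000000_"
                             "Fatquant_data.session")
        assert get_save_file_prefix(fitted_session, "X").endswith(
            "_Fatquant_data")

    def test_save_load_is_identity_on_content(self, fitted_session, tmp_path,
                                              registry):
        path = save_session(fitted_session, tmp_path)
        loaded = load_session(path, registry)
        assert len(loaded.slices) == len(fitted_session.slices)
        for a, b in zip(fitted_session.slices, loaded.slices):
            assert a.slice_location == b.slice_location
            assert a.done == b.done
            for channel in a.images:
                for ra, rb in zip(a.images[channel], b.images[channel]):
                    assert ra.pixel_data.dtype == rb.pixel_data.dtype
                    np.testing.assert_array_equal(ra.pixel_data, rb.pixel_data)
                    assert ra.tags == rb.tags
            assert a.get_payload() == b.get_payload()
        assert loaded.patient_name == fitted_session.patient_name
        assert loaded.acquisition_time == fitted_session.acquisition_time

    def test_custom_save_hook_called_exactly_once(self, fitted_session,
                                                  tmp_path, monkeypatch):
        calls = []
        slice0 = fitted_session.slices[0]
        monkeypatch.setattr(slice0, "custom_save",
                            lambda session, folder: calls.append(folder))
        save_session(fitted_session, tmp_path)
        assert len(calls) == 1


def _mini_plugin(child_version, base_version, spy):
    """A minimal two-class plugin whose migrations record their order."""
    hooks = {h: (lambda self, *a, **k: None) for h in REQUIRED_HOOKS}
    Mini = type("Mini", (ComputeSlice,), hooks)

    def migrate_child(payload, old):
        spy.append(("MiniChild", old))
        return {**payload, "child_migrated": True}

    def migrate_base(payload, old):
        spy.append(("MiniBase", old))
        return {**payload, "base_migrated": True}

    descriptor = PluginDescriptor(
        identifier="MiniPlugin", constructor=Mini,
        version_chain=[VersionedClass("MiniChild", child_version,
                                      migrate_child),
                       VersionedClass("MiniBase", base_version,
                                      migrate_base)])
    reg = PluginRegistry()
    reg.register(descriptor)
    return reg


def _mini_session(compute_versions):
    reg = _mini_plugin("1.0", "1.0", [])
    slice_obj = reg.get("MiniPlugin").constructor()
    slice_obj.slice_location = 0.0
    slice_obj.add_images("Main", [ImageRecord(
        pixel_data=np.arange(6, dtype=np.int16).reshape(2, 3),
        filename="m.dcm", tags={"SliceLocation": 0.0})])
    slice_obj.app_payload = {"value": 7}
    return Session(
        slices=[slice_obj],
        version_info={"controller_version": CONTROLLER_VERSION,
                      "compute": compute_versions},
        application_name="Mini", patient_name="P",
        acquisition_time="20240101T000000", compute_class="MiniPlugin")


class TestVersionMigration:
    def test_outdated_container_migrated_once_child_before_base(
            self, tmp_path):
        session = _mini_session({"MiniChild": "1.0", "MiniBase": "1.0"})
        path = save_session(session, tmp_path, run_custom_save=False)
        spy = []
        reg = _mini_plugin("2.0", "2.0", spy)
        loaded = load_session(path, reg)
        assert spy == [("MiniChild", "1.0"), ("MiniBase", "1.0")]
        payload = loaded.slices[0].get_payload()
        assert payload["child_migrated"] and payload["base_migrated"]
        assert payload["value"] == 7
        assert loaded.version_info["compute"] == {"MiniChild": "2.0",
                                                  "MiniBase": "2.0"}

    def test_current_version_container_applies_zero_migrations(self, tmp_path):
        session = _mini_session({"MiniChild": "1.0", "MiniBase": "1.0"})
        path = save_session(session, tmp_path, run_custom_save=False)
        spy = []
        loaded = load_session(path, _mini_plugin("1.0", "1.0", spy))
        assert spy == []
        assert loaded.slices[0].get_payload() == {"value": 7}

    def test_forward_version_refused(self, tmp_path):
        session = _mini_session({"MiniChild": "3.0", "MiniBase": "1.0"})
        path = save_session(session, tmp_path, run_custom_save=False)
        with pytest.raises(ForwardVersionError):
            load_session(path, _mini_plugin("2.0", "1.0", []))

    def test_version_gap_without_migration_function_is_an_error(
            self, tmp_path):
        session = _mini_session({"MiniChild": "1.0", "MiniBase": "0.5"})
        path = save_session(session, tmp_path, run_custom_save=False)
        spy = []
        reg = _mini_plugin("1.0", "1.0", spy)
        reg.get("MiniPlugin").version_chain[1].migrate = None
        with pytest.raises(MigrationError, match="MiniBase"):
            load_session(path, reg)


# ---------------------------------------------------------------------------
# UI update, dispatch, menus

class TestUiUpdate:
    def test_hook_order_image_graph_text_then_table(self, fitted_session,
                                                    app_config, registry):
        order = []
        slice0 = fitted_session.slices[0]
        for hook, label in [("get_img2display", "image"),
                            ("draw_graph", "graph"),
                            ("get_textbox_lines", "text"),
                            ("get_pdff", "table")]:
            original = getattr(slice0, hook)
            def wrapper(*a, _o=original, _l=label, **k):
                order.append(_l)
                return _o(*a, **k)
            setattr(slice0, hook, wrapper)
        ui_update(fitted_session, UIState(), app_config, registry)
        compact = [x for i, x in enumerate(order) if i == 0 or x != order[i - 1]]
        assert compact == ["image", "graph", "text", "table"]

    def test_table_dimensions_and_reference_columns(self, fitted_session,
                                                    app_config, registry):
        ui = ui_update(fitted_session, UIState(), app_config, registry)
        assert len(ui.table) == len(fitted_session.slices)
        assert all(len(row) == len(app_config.table_headers)
                   for row in ui.table)
        row0 = ui.table[0]
        assert row0[0] == fitted_session.slices[0].slice_location
        assert row0[1] is False
        for col, truth in zip(row0[2:5], (10.0, 25.0, 40.0)):
            assert col == pytest.approx(truth, abs=0.5)

    def test_unfitted_roi_renders_blank(self, session, app_config, registry):
        ui = ui_update(session, UIState(), app_config, registry)
        assert ui.table[0][2:5] == ["", "", ""]

    def test_idempotent_without_intervening_event(self, fitted_session,
                                                  app_config, registry):
        a = ui_update(fitted_session, UIState(), app_config, registry)
        b = ui_update(fitted_session, UIState(), app_config, registry)
        np.testing.assert_array_equal(a.displayed_image, b.displayed_image)
        assert a.overlays == b.overlays
        assert a.graph == b.graph
        assert a.text_lines == b.text_lines
        assert a.table == b.table
        assert a.menu_tree == b.menu_tree


class TestDispatch:
    def test_table_cell_select_switches_slice(self, fitted_session,
                                              app_config, registry):
        ui = ui_update(fitted_session, UIState(), app_config, registry)
        ui = dispatch_event(fitted_session, ui,
                            Event("table_cell_select", {"row": 2, "col": 0}),
                            registry, app_config)
        assert ui.current_slice_index == 2
        assert ui.text_lines[0] == "Slice 3"

    def test_menu_click_invokes_plugin_callback_once(self, fitted_session,
                                                     app_config, registry,
                                                     monkeypatch):
        calls = []
        slice0 = fitted_session.slices[0]
        monkeypatch.setattr(slice0, "copy_rois", lambda: calls.append(1))
        dispatch_event(fitted_session, UIState(),
                       Event("menu_click", {"path": ["Functions",
                                                     "Copy ROIs"]}),
                       registry, app_config)
        assert calls == [1]

    def test_unknown_event_name_is_a_dispatch_error(self, fitted_session,
                                                    app_config, registry):
        with pytest.raises(DispatchError, match="dbl_click"):
            dispatch_event(fitted_session, UIState(),
                           Event("dbl_click", {}), registry, app_config)

    def test_mouse_wheel_clamps_to_slice_range(self, fitted_session,
                                               app_config, registry):
        ui = UIState()
        ui = dispatch_event(fitted_session, ui,
                            Event("mouse_wheel", {"delta": -3}),
                            registry, app_config)
        assert ui.current_slice_index == 0
        ui = dispatch_event(fitted_session, ui,
                            Event("mouse_wheel", {"delta": 99}),
                            registry, app_config)
        assert ui.current_slice_index == len(fitted_session.slices) - 1

    def test_table_cell_edit_toggles_done_flag(self, fitted_session,
                                               app_config, registry):
        ui = ui_update(fitted_session, UIState(), app_config, registry)
        ui = dispatch_event(fitted_session, ui,
                            Event("table_cell_edit",
                                  {"row": 0, "col": 1, "value": True}),
                            registry, app_config)
        assert fitted_session.slices[0].done is True
        assert ui.table[0][1] is True

    def test_random_event_storm_never_corrupts_the_session(
            self, fitted_session, app_config, registry):
        """Fuzz: any documented event sequence leaves invariants intact."""
        rng = np.random.default_rng(7)
        ui = ui_update(fitted_session, UIState(), app_config, registry)
        events = []
        for _ in range(60):
            kind = rng.integers(0, 6)
            if kind == 0:
                events.append(Event("table_cell_select",
                                    {"row": int(rng.integers(0, 4)),
                                     "col": int(rng.integers(0, 5))}))
            elif kind == 1:
                events.append(Event("mouse_wheel",
                                    {"delta": int(rng.integers(-2, 3))}))
            elif kind == 2:
                events.append(Event("key_press",
                                    {"key": str(rng.integers(0, 5))}))
            elif kind == 3:
                events.append(Event("key_release", {}))
            elif kind == 4:
                r = float(rng.uniform(0, 63))
                c = float(rng.uniform(0, 63))
                events.extend([
                    Event("image_button_down", {"row": r, "col": c}),
                    Event("image_button_motion", {"row": r + 6, "col": c}),
                    Event("image_button_motion", {"row": r + 6, "col": c + 6}),
                    Event("image_button_up", {"row": r, "col": c + 6})])
            else:
                events.append(Event("graph_button_down",
                                    {"row": 0.0, "col": 0.0}))
        for event in events:
            ui = dispatch_event(fitted_session, ui, event, registry,
                                app_config)
            locations = [s.slice_location for s in fitted_session.slices]
            assert locations == sorted(locations)
            assert 0 <= ui.current_slice_index < len(fitted_session.slices)
            assert len(ui.table) == len(fitted_session.slices)
            for s in fitted_session.slices:
                for roi in s.rois:
                    pdff = roi.pdff_percent
                    assert pdff is None or 0.0 <= pdff <= 100.0


class TestMenus:
    def test_framework_entries_always_present(self, app_config):
        app_config.menu_entries = []
        tree = build_menu(app_config)
        assert [node["label"] for node in tree] == ["Load Data", "Save Data"]

    def test_reference_menu_field_counts(self, app_config):
        tree = build_menu(app_config)
        by_label = {node["label"]: node for node in tree}
        assert len(by_label["Functions"]["children"]) == 2
        assert len(by_label["Image"]["children"]) == 3
        assert [c["label"] for c in by_label["Image"]["children"]] == [
            "Show Magnitude", "Show RealPart", "Show ImaginaryPart"]

    def test_deterministic_across_builds(self, app_config):
        assert build_menu(app_config) == build_menu(app_config)
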