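"""Shared fixtures: a standard noiseless phantom tree generated once per
test session, plus config/registry factories and ROI helpers."""

from __future__ import annotations

import pytest

from sliceflex import (default_application_config, default_registry,
                       generate_phantom, load_dataset, standard_fixture)
from sliceflex.fatquant import FatquantSlice
from sliceflex.phantom import STANDARD_RECTS


@pytest.fixture(autouse=True)
def _reset_roi_clipboard():
    FatquantSlice._clipboard = None
    yield
    FatquantSlice._clipboard = None


@pytest.fixture(scope="session")
def phantom_tree(tmp_path_factory):
    """Noiseless standard phantom DICOM tree plus its manifest."""
    root = tmp_path_factory.mktemp("phantom")
    manifest = generate_phantom(standard_fixture("none"), root)
    return root, manifest


@pytest.fixture()
def app_config():
    return default_application_config()


@pytest.fixture()
def registry():
    return default_registry()


@pytest.fixture()
def session(phantom_tree, app_config, registry):
    """A freshly loaded session over the standard noiseless phantom."""
    root, _ = phantom_tree
    return load_dataset(root, app_config, registry)


def rect_polygon(rect, margin=0):
    """Closed (row, col) polygon covering exactly the pixel centers of
    ``rect`` = (row0, row1, col0, col1), shrunk by ``margin`` pixels."""
    r0, r1, c0, c1 = rect
    r0, r1, c0, c1 = r0 + margin, r1 - margin, c0 + margin, c1 - margin
    return [[r0 - 0.5, c0 - 0.5], [r0 - 0.5, c1 - 0.5],
            [r1 - 0.5, c1 - 0.5], [r1 - 0.5, c0 - 0.5]]


def standard_sidecar(margin=2):
    """ROI sidecar covering the three fixture regions on every slice."""
    return {"all_slices": [[rect_polygon(rect, margin)]
                           for rect in STANDARD_RECTS]}


@pytest.fixture()
def fitted_session(session):
    """Standard session with the three fixture ROIs drawn and fitted."""
    from sliceflex import apply_rois
    apply_rois(session, standard_sidecar())
    return session
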