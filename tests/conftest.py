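"""Shared fixtures: phantoms and decompositions reused across test modules.

Expensive end-to-end artifacts (longitudinal mouse run) are session-scoped so
the pipeline executes once and several tests interrogate the same outputs.
"""

from __future__ import annotations

import numpy as np
import pytest

import adipoquant as aq
from adipoquant.dixon import decompose_three_point


SNR30 = 1.0 / 30.0


@pytest.fixture(scope="session")
def mouse_protocol():
    return aq.MOUSE_7T


@pytest.fixture(scope="session")
def mouse_anatomy():
    spec = aq.mouse_spec()
    return aq.build_phantom(spec, aq.MOUSE_7T)


@pytest.fixture(scope="session")
def mouse_series_noisefree(mouse_anatomy):
    return aq.simulate_echoes(mouse_anatomy, aq.MOUSE_7T, b0_amplitude_hz=120.0)


@pytest.fixture(scope="session")
def mouse_series_snr30(mouse_anatomy):
    return aq.simulate_echoes(
        mouse_anatomy, aq.MOUSE_7T, b0_amplitude_hz=120.0, noise_sd=SNR30, seed=42
    )


@pytest.fixture(scope="session")
def mouse_fw_noisefree(mouse_anatomy, mouse_series_noisefree):
    return decompose_three_point(mouse_series_noisefree, mask=mouse_anatomy.body_mask)


@pytest.fixture(scope="session")
def mouse_fw_snr30(mouse_anatomy, mouse_series_snr30):
    return decompose_three_point(mouse_series_snr30, mask=mouse_anatomy.body_mask)


@pytest.fixture(scope="session")
def ff_truth(mouse_anatomy):
    total = mouse_anatomy.water + mouse_anatomy.fat
    return np.where(total > 0, mouse_anatomy.fat / np.maximum(total, 1e-12), 0.0)


@pytest.fixture(scope="session")
def mouse_longitudinal_dirs(tmp_path_factory):
    """Three-timepoint mouse phantom datasets (VAT 1 → 0.88 → 0.75) on disk."""
    root = tmp_path_factory.mktemp("mouse_long")
    spec = aq.mouse_spec(noise_sd=SNR30, seed=11)
    pairs = aq.make_longitudinal(spec, aq.MOUSE_7T, {"vat": [1.0, 0.88, 0.75]})
    dirs = []
    for t, (anatomy, series) in enumerate(pairs):
        d = root / f"t{t}"
        d.mkdir()
        aq.write_dataset(series, anatomy, str(d))
        dirs.append(str(d))
    truths = [a.compartment_volumes_mm3() for a, _ in pairs]
    return dirs, truths


@pytest.fixture(scope="session")
def mouse_subject_report(mouse_longitudinal_dirs, tmp_path_factory):
    dirs, truths = mouse_longitudinal_dirs
    out = tmp_path_factory.mktemp("mouse_report")
    cfg = aq.RunConfig(
        subject_id="m01",
        protocol="mouse7t",
        method="3pt",
        timepoint_dirs=dirs,
        timepoint_labels=["day3", "day12", "day17"],
        out_dir=str(out),
        seed=11,
    )
    report = aq.run_subject(cfg)
    return report, truths, cfg


@pytest.fixture(scope="session")
def table1():
    return aq.load_table1()
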