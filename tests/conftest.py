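"""Shared fixtures: beams, phantoms, and the expensive session-level studies
(multi-seed accuracy replication, interplay study) reused across tests."""

from __future__ import annotations

import numpy as np
import pytest

from pbtrack import acquisition as acq
from pbtrack import artifacts, runner, scene


@pytest.fixture(scope="session")
def probeam() -> acq.BeamModel:
    """Clinical 230 MeV beam, 7.8 mm FWHM at the scintillator entrance."""
    return acq.BeamModel()


@pytest.fixture(scope="session")
def mit_beam() -> acq.BeamModel:
    """Synchrotron 180 MeV beam, 9.3 mm FWHM in air (slab experiments)."""
    return acq.BeamModel(energy_E0=180.0, fwhm_entrance=9.3)


@pytest.fixture(scope="session")
def deep_scint_beam() -> acq.BeamModel:
    """Default beam viewed in a deeper scintillator so the full WET range
    [0, 250] mm maps to in-detector peak depths (round-trip tests)."""
    return acq.BeamModel(scintillator_depth=340.0)


@pytest.fixture()
def no_noise() -> acq.NoiseSpec:
    return acq.NoiseSpec.off()


@pytest.fixture()
def optics_off() -> acq.OpticsModel:
    return acq.OpticsModel(vignetting=False)


@pytest.fixture(scope="session")
def slab_phantom() -> scene.PhantomModel:
    return scene.build_slab_phantom()


@pytest.fixture(scope="session")
def thorax_phantom() -> scene.PhantomModel:
    return scene.build_thorax_phantom(30.0)


def water_slab_phantom(thickness: float) -> scene.PhantomModel:
    """A single water slab of given water-equivalent thickness plus a dummy
    (far away) moving primitive, for controlled WET round trips."""
    slab = scene.Primitive(
        "slab", "slab", scene.WATER, dict(lo=[-60, -60, -300], hi=[60, 60, -300 + thickness])
    )
    dummy = scene.Primitive(
        "dummy", "sphere", scene.AIR, dict(center=[0, 0, 900], radius=1.0), moving=True
    )
    return scene.PhantomModel([slab, dummy], "dummy")


@pytest.fixture(scope="session")
def artifact_study() -> artifacts.ArtifactStudyResult:
    """The full interplay study at default settings (shared: ~15 s)."""
    return artifacts.run_artifact_study(artifacts.ArtifactStudyConfig(seed=0))


@pytest.fixture(scope="session")
def table1_replication():
    """Multi-seed replication of all seven accuracy configurations
    (20 frames, 10 seeds each; the expensive session fixture)."""
    return runner.replicate_table1(n_seeds=10, base_seed=0, n_frames=20)
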