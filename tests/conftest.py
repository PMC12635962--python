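"""Shared fixtures: suite-matched configuration and cached benchmark runs.

The benchmark suite and its pipeline results are session-scoped because
several test modules interrogate the same scenes (detection accuracy, QC
behavior, end-to-end recovery) and the scenes are deterministic for a
fixed seed.
"""

from __future__ import annotations

import pytest

from guvphase import RunConfig, benchmark_suite, process_scene
from guvphase.synthetic import suite_config

SUITE_SEED = 20260920


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return suite_config()


@pytest.fixture(scope="session")
def suite():
    return benchmark_suite(SUITE_SEED)


@pytest.fixture(scope="session")
def suite_results(suite, config):
    """Mapping case name -> (case, SceneResult) for the full benchmark."""
    return {case.name: (case, process_scene(case.scene, config)) for case in suite}
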