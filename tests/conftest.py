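"""Shared fixtures: the packaged library and one fully-analysed synthetic study.

The synthetic study is generated once per session (fixed seed) and shared by
the annotation, stats, pipeline and acceptance tests; it is the default
scenario of the generator, i.e. the study design the package emulates.
"""

import pytest

import bileprof as bp


@pytest.fixture(scope="session")
def library():
    return bp.load_default_library()


@pytest.fixture(scope="session")
def scenario():
    return bp.ScenarioConfig.default()


@pytest.fixture(scope="session")
def study(scenario):
    return bp.make_plasma_study(scenario, seed=17)


@pytest.fixture(scope="session")
def invitro_runs(scenario):
    runs, truth = bp.make_invitro_suite(scenario, seed=18)
    return runs, truth


@pytest.fixture(scope="session")
def pipeline_result(study, invitro_runs):
    runs, _ = invitro_runs
    return bp.run_pipeline(
        study.feature_objects(),
        study.design,
        spectra={s.key: s for s in study.spectra},
        invitro_runs=runs,
    )
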