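import numpy as np
import pytest

from lumbomech.anatomy import SpineSpec, generate_spine, generate_torso


@pytest.fixture(scope="session")
def spec():
    return SpineSpec()


@pytest.fixture(scope="session")
def bundle(spec):
    return generate_spine(spec)


@pytest.fixture(scope="session")
def torso_bundle(spec):
    return generate_torso(spec, generate_spine(spec))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def settled_intact(spec):
    """Settled, calibrated muscle-driven reference model, shared read-only.

    Tests that change posture or add devices must snapshot/restore or build
    their own model."""
    from lumbomech.spine import build_reference_model

    model = build_reference_model(spec)
    model._session_snap = model.mb.snapshot()
    model._session_e = model.muscle_system.e.copy()
    return model


@pytest.fixture(scope="session")
def torso_model(torso_bundle):
    from lumbomech.orthosis import build_torso_model

    return build_torso_model(torso_bundle)


@pytest.fixture(scope="session")
def orthosis_band(torso_model):
    from lumbomech.orthosis import build_orthosis

    return build_orthosis(torso_model)


@pytest.fixture(scope="session")
def iap_curve(torso_model, orthosis_band):
    """Tightened bands and FE-IAP values over the tightening sweep.

    Computed once per session (the FE solves are expensive) and shared by
    the orthosis tests and the acceptance suite.
    Returns [(fraction, tightened_band, iap_mmHg), ...]."""
    import copy

    from lumbomech.orthosis import tighten, fe_iap

    out = []
    for f in (0.0, 0.04, 0.08):
        b = tighten(torso_model, orthosis_band, f)
        iap = fe_iap(torso_model, b)
        # snapshot: tighten() reuses state, later calls must not alias
        out.append((f, copy.deepcopy(b), iap))
    return out


@pytest.fixture()
def restored_intact(settled_intact):
    """The settled model, restored to its upright state after each test."""
    m = settled_intact
    yield m
    m.mb.restore(m._session_snap)
    m.muscle_system.set_excitations(m._session_e)
    m.iap.enabled = False
    m.iap.extra_force = 0.0
    for w in list(m.external):
        m.remove_external(w)
    m.set_thorax_target(0.0)
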