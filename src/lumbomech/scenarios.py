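"""End-to-end device scenarios.

Three treatment scenarios modify the intact muscle-driven model:

1. two-level posterior fixation L3-L5 (pedicle screws 5 mm, rods 7 mm),
   with the L4 target frame removed and the expected L3-L5 rotation
   reduced by 68%, redistributed over the remaining target frames;
2. single-level L4/5 interbody fusion: nucleotomy + facetectomy, a
   banana-shaped expandable cage (15 mm design height, friction 0.5)
   expanded in the passive state, plus posterior fixation L4-L5
   (screws 6 mm, rods 5.5 mm), with the L4-L5 rotation share reduced
   by 90%;
3. abdominal soft tissue with an extensible lumbar orthosis whose
   intra-abdominal pressurisation supports the thorax.
"""

from __future__ import annotations

import numpy as np

from .anatomy import SpineSpec, generate_spine, generate_torso
from .instrumentation import (FixatorSpec, CageSpec, ResectionSpec,
                              implant_fixator, resect, insert_cage,
                              expand_cage, rod_section_loads,
                              cage_contact_force)
from .muscles import TargetFrame
from .protocols import redistribute_targets
from .spine import SpineModel, build_reference_model

SCENARIOS = ("intact", "scenario1", "scenario2", "scenario3")


def make_intact(spec: SpineSpec | None = None, settle: bool = True,
                calibrate: bool = False) -> SpineModel:
    if calibrate:
        return build_reference_model(spec)
    model = SpineModel(generate_spine(spec or SpineSpec()))
    if settle:
        model.settle_reference()
    return model


def apply_scenario1(model: SpineModel, reduction: float = 0.68):
    """Posterior fixation L3-L5 bridging L4 on an intact model."""
    rods = implant_fixator(model, FixatorSpec(levels=("L3", "L5"),
                                              screw_diameter=5.0,
                                              rod_diameter=7.0))
    for r in rods:
        r.lock(model.mb)
    # remove the L4 target frame; reduce the L3..L5 expected rotation by
    # 68% and redistribute, conserving the total thoracic rotation
    l4 = next(t for t in model.targets if t.body == "L4")
    others = [t for t in model.targets if t.share > 0 and t.body != "L4"]
    add = l4.share / len(others)
    for t in others:
        t.share += add
    l4.share = 0.0
    l4.weight = 0.0
    model.targets = redistribute_targets(model.targets, ["L3", "L5"], reduction)
    return rods


def apply_scenario2(model: SpineModel, reduction: float = 0.90):
    """L4/5 interbody fusion: NY + FY, expandable cage, PF L4-L5.

    The surgical step runs in the passive state (prone position, phase [i]):
    gravity off, excitations zero; call before the settling phase."""
    mb = model.mb
    grav, scale = mb.gravity_on, mb.gravity_scale
    mb.gravity_on = False
    e_save = None
    if model.muscle_system is not None:
        e_save = model.muscle_system.e.copy()
        model.muscle_system.e = np.zeros_like(e_save)
    resect(model, ResectionSpec("NY", "L4L5"))
    resect(model, ResectionSpec("FY", "L4L5"))
    cage = insert_cage(model, CageSpec(), level="L4L5")
    distraction = expand_cage(model, cage)
    rods = implant_fixator(model, FixatorSpec(levels=("L4", "L5"),
                                              screw_diameter=6.0,
                                              rod_diameter=5.5,
                                              free_rod_length=None))
    for r in rods:
        r.lock(mb)
    mb.gravity_on, mb.gravity_scale = grav, scale
    if e_save is not None:
        model.muscle_system.e = e_save
    model.targets = redistribute_targets(model.targets, ["L5"], reduction)
    return cage, rods, distraction


def scenario1_rod_loads(model: SpineModel, postures=(0.0,)) -> dict:
    """Rod internal loads (left rod) over thorax postures, Nm/N."""
    out = {}
    rods = [r for r in model.instrumentation
            if r.__class__.__name__ == "RodConstruct"]
    left = next(r for r in rods if r.side == "L")
    for ang in postures:
        model.track(ang)
        loads = rod_section_loads(model, left)
        out[ang] = {"FZ": loads.FZ, "Mb_sag": loads.Mb_sag}
    return out


def scenario3_models(spec: SpineSpec | None = None,
                     grid_resolution=(9, 9, 10)):
    """Spine + torso + orthosis for the soft-tissue scenario."""
    from .orthosis import build_torso_model, build_orthosis

    spec = spec or SpineSpec()
    bundle = generate_torso(spec, generate_spine(spec), grid_resolution)
    model = SpineModel(bundle)
    torso = build_torso_model(bundle)
    orth = build_orthosis(torso)
    return model, torso, orth


def diaphragm_area(torso) -> float:
    """Base area (mm^2) of the diaphragm dome over the abdominal cavity."""
    r = 0.62 * min(torso.params["a"], torso.params["b"])
    return float(np.pi * r * r)


def apply_orthosis_support(model: SpineModel, torso, orth, fraction: float):
    """Tighten the orthosis and route the FE-IAP as a cranial thorax force.

    The soft-tissue pressure acts on the diaphragm and hence the thorax;
    the surrogate force is p * A_diaphragm.  Returns the FE-IAP in mmHg."""
    from .orthosis import tighten, fe_iap, KPA_PER_MMHG

    orth = tighten(torso, orth, fraction)
    iap_mmhg = fe_iap(torso, orth)
    p_kpa = iap_mmhg * KPA_PER_MMHG
    force_N = p_kpa * 1e-3 * diaphragm_area(torso)   # kPa*mm^2 = mN
    model.iap.extra_force = force_N
    model.iap.enabled = True
    return iap_mmhg
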