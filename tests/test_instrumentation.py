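"""Implants: rod internal loads, fixator construction, resections, cage."""

import numpy as np
import pytest

from lumbomech.anatomy import SpineSpec, generate_spine
from lumbomech.spine import SpineModel
from lumbomech.instrumentation import (RodModel, FixatorSpec, CageSpec,
                                       ResectionSpec, implant_fixator,
                                       remove_fixator, rod_section_loads,
                                       resect, insert_cage, expand_cage,
                                       cage_contact_force, ResectionError,
                                       CageExpansionError,
                                       OverlappingImplantError)
from lumbomech.measures import measure_rom
from lumbomech.protocols import apply_pure_moment


@pytest.fixture(scope="module")
def mod_bundle():
    return generate_spine(SpineSpec())


class TestRodModel:
    @pytest.fixture(scope="class")
    def rod(self):
        return RodModel(length=59.5, diameter=7.0, clamp_length=9.5)

    def test_unloaded_rod_zero_section_loads(self, rod):
        F, M = rod.section_loads(np.zeros(12))
        assert np.abs(F).max() == 0.0
        assert np.abs(M).max() == 0.0

    def test_cantilever_moment_matches_euler_bernoulli(self, rod):
        """Tip transverse force F at lever L/2 from the cut: Mb = F L/2."""
        F = 50.0
        qB = np.linalg.solve(rod.K_red[6:, 6:], np.array([F, 0, 0, 0, 0, 0.0]))
        Fs, Ms = rod.section_loads(np.concatenate([np.zeros(6), qB]))
        assert abs(Ms[1]) == pytest.approx(F * rod.length / 2, rel=0.03)

    def test_axial_patch(self, rod):
        P = 100.0
        qB = np.linalg.solve(rod.K_red[6:, 6:], np.array([0, 0, -P, 0, 0, 0.0]))
        Fs, Ms = rod.section_loads(np.concatenate([np.zeros(6), qB]))
        assert Fs[2] == pytest.approx(-P, rel=0.02)
        assert abs(Ms[0]) < 0.02 * P * rod.length

    def test_tip_deflection_matches_beam_theory(self, rod):
        E, I = 110000.0, np.pi * 7.0 ** 4 / 64
        F = 50.0
        qB = np.linalg.solve(rod.K_red[6:, 6:], np.array([F, 0, 0, 0, 0, 0.0]))
        L = rod.length - rod.clamp_length
        assert qB[0] == pytest.approx(F * L ** 3 / (3 * E * I), rel=0.05)


class TestFixator:
    def test_scenario1_free_rod_length(self, mod_bundle):
        m = SpineModel(mod_bundle, section=("L3", "L4", "L5"))
        rods = implant_fixator(m, FixatorSpec(levels=("L3", "L5")))
        assert rods[0].free_rod_length == pytest.approx(40.5, abs=1e-6)
        assert rods[0].max_unsupported_screw_length > 0

    def test_overlapping_implant_rejected(self, mod_bundle):
        m = SpineModel(mod_bundle, section=("L3", "L4", "L5"))
        implant_fixator(m, FixatorSpec(levels=("L3", "L5")))
        with pytest.raises(OverlappingImplantError):
            implant_fixator(m, FixatorSpec(levels=("L3", "L5")))

    def test_bilateral_symmetry_under_sagittal_load(self, mod_bundle):
        m = SpineModel(mod_bundle, section=("L3", "L4", "L5"))
        rods = implant_fixator(m, FixatorSpec(levels=("L3", "L5")))
        for r in rods:
            r.lock(m.mb)
        apply_pure_moment(m, 5.0, "flexion")
        lL = rod_section_loads(m, rods[0])
        lR = rod_section_loads(m, rods[1])
        assert lL.FZ == pytest.approx(lR.FZ, abs=1e-6)
        assert lL.Mb_sag == pytest.approx(lR.Mb_sag, abs=1e-8)
        assert lL.Mb_sag < 0   # flexion-negative sign convention

    def test_removal_restores_intact_stiffness(self, mod_bundle):
        m = SpineModel(mod_bundle, section=("L4", "L5"))
        rom0 = measure_rom(m, 6.6, "flexion", level="L4L5")
        rods = implant_fixator(m, FixatorSpec(levels=("L4", "L5"),
                                              free_rod_length=None))
        for r in rods:
            r.lock(m.mb)
        rom_fix = measure_rom(m, 6.6, "flexion", level="L4L5")
        remove_fixator(m, rods)
        rom1 = measure_rom(m, 6.6, "flexion", level="L4L5")
        assert rom_fix < 0.2 * rom0
        assert rom1 == pytest.approx(rom0, rel=1e-6)


class TestResections:
    def _model(self, mod_bundle):
        return SpineModel(mod_bundle, section=("L4", "L5"))

    def test_nucleotomy_keeps_annulus(self, mod_bundle):
        m = self._model(mod_bundle)
        resect(m, ResectionSpec("NY", "L4L5"))
        d = m.discs["L4L5"]
        assert not d.active["nucleus"]
        assert d.active["annulus"]
        from lumbomech.spine import NoNucleusError

        with pytest.raises(NoNucleusError):
            m.idp("L4L5")

    def test_repeat_resection_rejected(self, mod_bundle):
        m = self._model(mod_bundle)
        resect(m, ResectionSpec("NY", "L4L5"))
        with pytest.raises(ResectionError):
            resect(m, ResectionSpec("NY", "L4L5"))

    def test_resecting_absent_structure_rejected(self, mod_bundle):
        m = self._model(mod_bundle)
        with pytest.raises(ResectionError):
            resect(m, ResectionSpec("NY", "L1L2"))   # not in the section

    def test_discectomy_implies_nucleotomy(self, mod_bundle):
        m = self._model(mod_bundle)
        resect(m, ResectionSpec("DY", "L4L5"))
        d = m.discs["L4L5"]
        assert not d.active["nucleus"] and not d.active["annulus"]

    def test_vertebrectomy_removes_load_path(self, mod_bundle):
        m = SpineModel(mod_bundle, section=("L3", "L4", "L5"))
        resect(m, ResectionSpec("VY", "L4"))
        assert not m.discs["L3L4"].active["annulus"]
        assert not m.discs["L4L5"].active["annulus"]
        assert not m.mb.bodies["L4"].dynamic
        # no force path: L3 feels nothing from below
        r = m.mb.residual()
        assert np.abs(r).max() < 1e-9


class TestCage:
    @pytest.fixture()
    def fused(self, mod_bundle):
        m = SpineModel(mod_bundle, section=("L4", "L5"))
        resect(m, ResectionSpec("NY", "L4L5"))
        resect(m, ResectionSpec("FY", "L4L5"))
        cage = insert_cage(m, CageSpec())
        return m, cage

    def test_insertion_requires_nucleotomy(self, mod_bundle):
        m = SpineModel(mod_bundle, section=("L4", "L5"))
        with pytest.raises(CageExpansionError):
            insert_cage(m, CageSpec())

    def test_expansion_distraction_press_fit(self, fused, spec):
        m, cage = fused
        d = expand_cage(m, cage)
        # ~1 mm distraction, ~6% of the mean lumbar disc height
        assert 0.75 < d < 1.15
        assert 0.04 < d / spec.mean_lumbar_disc_height < 0.07
        f, _ = cage_contact_force(m, cage)
        assert f > 0            # anterior press-fit force with intact annulus
        assert cage.mu == pytest.approx(0.5)

    def test_zero_height_change_zero_force_change(self, fused):
        m, cage = fused
        expand_cage(m, cage)
        f0, _ = cage_contact_force(m, cage)
        d = expand_cage.__wrapped__ if hasattr(expand_cage, "__wrapped__") else None
        # expanding again by zero leaves the contact force unchanged
        h = cage.height
        cage.height = h
        m.mb.static_settle(dof_mask=m.mb.sagittal_dof_mask())
        f1, _ = cage_contact_force(m, cage)
        assert f1 == pytest.approx(f0, rel=0.02)

    def test_friction_cone_on_cage_contact(self, fused):
        m, cage = fused
        expand_cage(m, cage)
        apply_pure_moment(m, 5.0, "flexion")
        n = cage.upper_body.rotation[:, 2]
        for f, fn in zip(cage.last_forces, cage.last_normal):
            ft = f - (f @ n) * n
            assert np.linalg.norm(ft) <= 0.5 * fn + 1e-6

    def test_fused_rom_below_ten_percent_of_intact(self, mod_bundle):
        m0 = SpineModel(mod_bundle, section=("L4", "L5"))
        rom_intact = measure_rom(m0, 10.0, "flexion", level="L4L5",
                                 follower_N=200.0)
        m, cage = SpineModel(mod_bundle, section=("L4", "L5")), None
        resect(m, ResectionSpec("NY", "L4L5"))
        resect(m, ResectionSpec("FY", "L4L5"))
        cage = insert_cage(m, CageSpec())
        expand_cage(m, cage)
        rods = implant_fixator(m, FixatorSpec(levels=("L4", "L5"),
                                              screw_diameter=6.0,
                                              rod_diameter=5.5,
                                              free_rod_length=None))
        for r in rods:
            r.lock(m.mb)
        rom_fused = measure_rom(m, 10.0, "flexion", level="L4L5",
                                follower_N=200.0)
        assert rom_fused < 0.10 * rom_intact
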