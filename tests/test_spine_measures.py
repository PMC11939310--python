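"""Spine model assembly, measurement probes and result tables."""

import numpy as np
import pytest

from lumbomech.anatomy import SpineSpec, generate_spine
from lumbomech.spine import SpineModel, NoNucleusError
from lumbomech.measures import (MeasurementRecord, ResultTable, measure_rom,
                                segment_angles, measure_segmental_contributions,
                                measure_muscle_sums, fe_iap_mmhg)
from lumbomech.instrumentation import resect, ResectionSpec


@pytest.fixture(scope="module")
def mod_bundle():
    return generate_spine(SpineSpec())


class TestMeasurementRecords:
    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            MeasurementRecord("bogus", 1.0, "MPa")

    def test_ratio_table_requires_both_states(self):
        t = ResultTable()
        t.add(MeasurementRecord("IDP", 0.5, "MPa", scenario="intact",
                                posture="upright", detail="L4L5"))
        t.add(MeasurementRecord("IDP", 0.4, "MPa", scenario="scenario1",
                                posture="upright", detail="L4L5"))
        t.add(MeasurementRecord("IDP", 0.6, "MPa", scenario="scenario1",
                                posture="flex30", detail="L4L5"))
        r = t.ratios("scenario1")
        assert len(r) == 1           # flex30 lacks an intact partner
        assert r.iloc[0].ratio == pytest.approx(0.8)

    def test_csv_roundtrip(self, tmp_path):
        t = ResultTable()
        t.add(MeasurementRecord("ROM", 3.1, "deg", scenario="intact"))
        path = tmp_path / "r.csv"
        t.write_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert df.iloc[0]["value"] == pytest.approx(3.1)


class TestIDP:
    def test_stress_free_disc_zero(self, mod_bundle):
        m = SpineModel(mod_bundle, section=("L4", "L5"))
        assert m.idp("L4L5") == pytest.approx(0.0, abs=1e-12)

    def test_no_idp_after_nucleotomy(self, mod_bundle):
        m = SpineModel(mod_bundle, section=("L4", "L5"))
        resect(m, ResectionSpec("NY", "L4L5"))
        with pytest.raises(NoNucleusError):
            m.idp("L4L5")

    def test_compression_positive(self, mod_bundle):
        from lumbomech.mb import ExternalWrench

        m = SpineModel(mod_bundle, section=("L4", "L5"))
        w = ExternalWrench("L4", force=np.array([0, 0, -400.0]))
        m.mb.force_elements.append(w)
        m.mb.static_settle(dof_mask=m.mb.sagittal_dof_mask())
        assert m.idp("L4L5") > 0.05


class TestROM:
    def test_zero_moment_zero_rom(self, mod_bundle):
        m = SpineModel(mod_bundle, section=("L4", "L5"))
        assert measure_rom(m, 0.0, "flexion", level="L4L5") == \
            pytest.approx(0.0, abs=1e-9)

    def test_rom_is_twice_one_sided_for_symmetric_lateral(self, mod_bundle):
        m = SpineModel(mod_bundle, section=("L4", "L5"))
        from lumbomech.protocols import apply_pure_moment

        snap = m.mb.snapshot()
        apply_pure_moment(m, 5.0, "lateral")
        one = np.degrees(np.arctan2(m.mb.bodies["L4"].rotation[2, 1],
                                    m.mb.bodies["L4"].rotation[2, 2]))
        m.mb.restore(snap)
        rom = measure_rom(m, 5.0, "flexion", level="L4L5")
        plus = measure_rom(m, 5.0, "flexion", level="L4L5") / 2
        assert rom == pytest.approx(2 * plus, rel=1e-9)

    def test_welded_pair_rom_negligible(self, mod_bundle):
        m = SpineModel(mod_bundle, section=("L3", "L4", "L5"))
        m.mb.bodies["L4"].dynamic = False    # rigid weld of L4 to fixed L5
        rom = measure_rom(m, 6.6, "flexion", level="L4L5")
        assert rom < 1e-3


class TestSegmentalContributions:
    def test_upright_all_zero(self, mod_bundle):
        m = SpineModel(mod_bundle)
        up = segment_angles(m)
        contrib = measure_segmental_contributions(m, up)
        assert all(abs(v) < 1e-12 for v in contrib.values())

    def test_kinematic_closure(self, mod_bundle):
        """Per-level rotations sum to the thoracic rotation change (0.1 deg)."""
        from scipy.spatial.transform import Rotation

        m = SpineModel(mod_bundle)
        up = segment_angles(m)
        th0 = m.mb.bodies["thorax"].sagittal_angle()
        # impose an arbitrary sagittal posture directly
        rng = np.random.default_rng(3)
        for k, lv in enumerate(("L5", "L4", "L3", "L2", "L1", "thorax")):
            b = m.mb.bodies[lv]
            ang = np.radians(rng.uniform(0.5, 2.0))
            b.rotation = Rotation.from_rotvec([-ang * (k + 1) / 3, 0, 0]
                                              ).as_matrix() @ b.rotation
        contrib = measure_segmental_contributions(m, up)
        total = m.mb.bodies["thorax"].sagittal_angle() - th0
        assert sum(contrib.values()) == pytest.approx(total, abs=0.1)


class TestMuscleSums:
    def test_zero_excitation_no_stretch_zero(self, mod_bundle):
        m = SpineModel(mod_bundle)
        sums = measure_muscle_sums(m)
        assert sums["total"] == pytest.approx(0.0, abs=1e-9)

    def test_total_is_sum_of_groups(self, mod_bundle):
        m = SpineModel(mod_bundle)
        m.muscle_system.set_excitations(
            0.3 * np.ones(len(m.muscle_system.muscles)))
        sums = measure_muscle_sums(m)
        groups = [v for k, v in sums.items() if k != "total"]
        assert sums["total"] == pytest.approx(sum(groups))
        assert set(sums) == {"erector_spinae", "multifidus", "psoas_major",
                             "quadratus_lumborum", "abdominals", "total"}


class TestUnitConversions:
    def test_kpa_to_mmhg(self):
        assert fe_iap_mmhg(0.133322) == pytest.approx(1.0)


class TestSymmetryOfEquilibria:
    def test_sagittal_load_gives_mirror_symmetric_state(self, mod_bundle):
        """Full-DOF settle of a symmetric section under a sagittal moment
        leaves no out-of-plane motion (mirror state identical to itself)."""
        from lumbomech.mb import ExternalWrench

        m = SpineModel(mod_bundle, section=("L4", "L5"))
        w = ExternalWrench("L4", torque=np.array([-5000.0, 0, 0]))
        m.mb.force_elements.append(w)
        m.mb.static_settle()   # full 6-DOF settle, no symmetry enforcement
        b = m.mb.bodies["L4"]
        assert abs(b.position[0]) < 1e-6
        assert abs(b.rotation[0, 1]) < 1e-6 and abs(b.rotation[0, 2]) < 1e-6
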