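"""Measurement probes and result tables.

All probes operate on settled equilibrium states.  Conventions: IDP is
compression-positive (MPa); ROM is the total sagittal (or requested-axis)
excursion between the +M and -M equilibria in degrees; rod bending moments
are flexion-negative; FE-IAP is reported in mmHg (1 mmHg = 0.133322 kPa).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

KPA_PER_MMHG = 0.133322

MEASURE_KINDS = ("IDP", "FE-IAP", "ROM", "segmental_contribution",
                 "muscle_force_sum", "rod_FZ", "rod_Mb_sag", "cage_force",
                 "skin_pressure", "lordosis_COBB")


@dataclass
class MeasurementRecord:
    kind: str
    value: float
    units: str
    scenario: str = ""
    posture: str = ""
    detail: str = ""
    state_id: str = ""

    def __post_init__(self):
        if self.kind not in MEASURE_KINDS:
            raise ValueError(f"unknown measurement kind {self.kind}")


@dataclass
class ResultTable:
    records: list = field(default_factory=list)

    def add(self, rec: MeasurementRecord):
        self.records.append(rec)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def ratios(self, modified: str, intact: str = "intact") -> pd.DataFrame:
        """Modified-over-intact ratio per (kind, detail, posture).

        Defined only where both states exist for the same posture."""
        df = self.to_frame()
        a = df[df.scenario == modified]
        b = df[df.scenario == intact]
        keys = ["kind", "detail", "posture"]
        merged = a.merge(b, on=keys, suffixes=("_mod", "_intact"))
        merged["ratio"] = merged.value_mod / merged.value_intact
        return merged[keys + ["value_mod", "value_intact", "ratio"]]

    def write_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def measure_idp(model, level: str) -> float:
    """Nucleus hydrostatic stress of a disc, MPa, compression positive.

    Raises for a nucleotomised (cage-replaced) disc: no pressure value is
    available there."""
    return model.idp(level)


def measure_rom(section_model, magnitude_Nm: float, axis: str = "flexion",
                level: str | None = None, follower_N: float = 0.0) -> float:
    """Range of motion of a passive section: total excursion between the
    +M and -M equilibria about the load axis, degrees."""
    from .protocols import apply_pure_moment, FollowerLoad

    mb = section_model.mb
    snap = mb.snapshot()
    fl = None
    if follower_N:
        fl = FollowerLoad(section_model, follower_N)
        mb.force_elements.append(fl)
        mb.static_settle(dof_mask=mb.sagittal_dof_mask())

    def one(sign):
        mb.restore(snap)
        apply_pure_moment(section_model, sign * magnitude_Nm, axis)
        if level is not None:
            return section_model.joint_rotation(level)
        angles = [b.sagittal_angle() for b in mb.dynamic_bodies]
        return angles[0] if angles else 0.0

    try:
        plus = one(+1.0)
        minus = one(-1.0)
    finally:
        if fl is not None:
            mb.force_elements.remove(fl)
        mb.restore(snap)
    return abs(plus - minus)


def measure_segmental_contributions(model, upright_angles: dict) -> dict:
    """Per-level sagittal rotations relative to the upright posture, degrees.

    The per-level values close kinematically: they sum to the thoracic
    rotation change relative to upright."""
    out = {}
    for lv in model.discs:
        d = model.bundle.discs[lv]
        cur = (model.mb.bodies[d.upper].sagittal_angle()
               - model.mb.bodies[d.lower].sagittal_angle())
        out[lv] = cur - upright_angles[lv]
    return out


def segment_angles(model) -> dict:
    """Current per-level relative sagittal angles (upper minus lower)."""
    out = {}
    for lv in model.discs:
        d = model.bundle.discs[lv]
        out[lv] = (model.mb.bodies[d.upper].sagittal_angle()
                   - model.mb.bodies[d.lower].sagittal_angle())
    return out


def measure_muscle_sums(model) -> dict:
    """Muscle-force sums per group and in total (N), current equilibrium."""
    sums = model.muscle_sums()
    sums["total"] = float(sum(sums.values()))
    return sums


def measure_lordosis(model) -> float:
    return model.cobb_L1S1()


def fe_iap_mmhg(pressure_kpa: float) -> float:
    return pressure_kpa / KPA_PER_MMHG
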