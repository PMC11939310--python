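"""Single-level L4/5 interbody fusion with an expandable cage.

On the passive L4-L5 section: nucleotomy and facetectomy clear the disc
space, a banana-shaped expandable cage is inserted and expanded against
the endplates (press fit of about 1 mm, ~6 % of the mean lumbar disc
height), and a posterior screw/rod construct locks the segment.  The
fused segment retains only a few percent of the intact range of motion."""

from lumbomech.anatomy import SpineSpec, generate_spine
from lumbomech.spine import SpineModel
from lumbomech.instrumentation import (FixatorSpec, CageSpec, ResectionSpec,
                                       implant_fixator, resect, insert_cage,
                                       expand_cage, cage_contact_force)
from lumbomech.measures import measure_rom

spec = SpineSpec()
bundle = generate_spine(spec)

intact = SpineModel(bundle, section=("L4", "L5"))
rom0 = measure_rom(intact, 10.0, "flexion", level="L4L5", follower_N=200.0)
print(f"intact L4/5 ROM (+/-10 Nm, 200 N follower): {rom0:.2f} deg")

m = SpineModel(bundle, section=("L4", "L5"))
resect(m, ResectionSpec("NY", "L4L5"))   # nucleotomy
resect(m, ResectionSpec("FY", "L4L5"))   # facetectomy
cage = insert_cage(m, CageSpec())
d = expand_cage(m, cage)
print(f"cage expansion distraction: {d:.2f} mm "
      f"({100 * d / spec.mean_lumbar_disc_height:.1f} % of the mean "
      "lumbar disc height)")
f, pmap = cage_contact_force(m, cage)
print(f"cage contact force after expansion: {f:.0f} N "
      f"({(pmap > 0).sum()} of {len(pmap)} contact points engaged)")

rods = implant_fixator(m, FixatorSpec(levels=("L4", "L5"),
                                      screw_diameter=6.0, rod_diameter=5.5,
                                      free_rod_length=None))
for r in rods:
    r.lock(m.mb)
romf = measure_rom(m, 10.0, "flexion", level="L4L5", follower_N=200.0)
print(f"fused L4/5 ROM: {romf:.3f} deg "
      f"({100 * romf / rom0:.1f} % of intact)")
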