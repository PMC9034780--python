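"""Allocate a measured input profile to basal / oblique / tuft dendrites.

The cell's vertical charge profile is apportioned, depth bin by depth bin,
according to each compartment's share of dendritic length in the average
morphology (rescaled to the cell's own soma-pia distance); proportions
times the full-field total give absolute charges.
"""

from scracm.allocation import allocate, proportional_charge
from scracm.map_builder import vertical_profile
from scracm.pipeline import analyze_session, average_morphology_profile, simulate_cell
from scracm.synthetic_data import SimSpec

spec = SimSpec()  # ground truth: 10% basal, 15% oblique, 75% tuft
avg_morph = average_morphology_profile(n=11, seed=1)
session, _ = simulate_cell(spec, seed=4)
analysis = analyze_session(session)

profile = vertical_profile(analysis.input_map, align="pia")
alloc = allocate(profile, avg_morph, soma_pia_um=session.soma_depth_um)
split = proportional_charge(alloc.proportions, analysis.total_pc)

for name, p, q in zip(("basal", "oblique", "tuft"), split.proportions,
                      split.charges_pc):
    print(f"{name:8s} {100 * p:5.1f} %   {q:5.2f} pC")
print(f"total    100.0 %   {split.total_pc:5.2f} pC")
# Recovered proportions track the generator's targeting triple to within a
# few percentage points at the default signal-to-noise ratio.
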