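"""Simulate one mapping session and measure its responses.

Generates a thick-tufted L5 morphology, simulates a 24x12 grid-stimulation
voltage-clamp session (1 ms spots at 10 Hz, EPSC-shaped currents, Gaussian
baseline noise), then runs the detection pipeline: 40 ms baselining, 50 ms
charge window, 7x baseline-SD significance.
"""

from scracm.pipeline import analyze_session
from scracm.synthetic_data import SimSpec, generate_morphology, simulate_session

spec = SimSpec()  # targeting (basal, oblique, tuft) = (0.10, 0.15, 0.75), 8 pC
morph = generate_morphology(soma_depth_um=500.0, seed=1)
session, truth = simulate_session(spec, morph, seed=2)
analysis = analyze_session(session)

n_sig = sum(r.significant for r in analysis.responses)
print(f"ground-truth total charge: {truth.total_charge_pc:.2f} pC")
print(f"full-field measured total: {analysis.total_pc:.2f} pC")
print(f"significant spots: {n_sig} / {len(analysis.responses)}")
print(f"series-resistance QC pass: {analysis.qc_keep}; "
      f"direct photocurrent: {analysis.direct_photocurrent}")
# The measured full-field charge recovers the injected total up to noise;
# only spots whose EPSC peak clears 7x the baseline SD count as inputs.
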