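"""Full per-condition analysis in one call, for two nucleotide conditions.

Runs the whole pipeline (QC -> bleed-through correction -> FRET -> global
HMM -> statistics) on a dynamic condition (GTP analogue) and a quiescent
one (nucleotide-free), then compares them: occupancies, dwell times and the
donor-acceptor cross-correlation amplitude, the standard readout of
conformational dynamics.
"""

import numpy as np

from mxfret import get_preset, simulate_dataset
from mxfret.pipeline import PipelineConfig, run_pipeline, compare_summaries

summaries = []
for name in ("AS_apo", "AS_GMPPCP"):
    dataset = simulate_dataset(get_preset(name), n_traces=100, seed=7)
    config = PipelineConfig(
        condition=name, n_states=2, seed=7, n_boot_hist=100, n_boot_dwell=100
    )
    report = run_pipeline(config, traces=dataset.traces)
    s = report.summary()
    summaries.append(s)
    print(f"\n=== {name} ===")
    print(f"traces passing QC: {s['n_traces_passed']}/{s['n_traces_input']}")
    print(f"mixture means: {np.round(s['component_means'], 3)} "
          f"(weights {np.round(s['component_weights'], 2)})")
    print(f"high-state occupancy: {100 * s['occupancy_frame_fraction'][-1]:.1f}% of frames")
    print(f"mean dwells: {np.round(s['dwell_mean_s'], 2)} s "
          f"+- {np.round(s['dwell_bootstrap_sd_s'], 3)} (bootstrap)")
    print(f"cross-correlation amplitude: {s['cc_amplitude']:.3f}")

print("\n=== comparison ===")
table = compare_summaries(summaries)
print(table.to_string(index=False))
# The GTP-analogue condition shows a several-fold larger anti-correlation
# amplitude: the molecule actively exchanges between states, whereas the
# nucleotide-free molecule mostly dwells in its preferred high-FRET state.
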