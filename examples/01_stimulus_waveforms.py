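"""Generate the two phase-lag stimulation conditions and verify the design.

Builds the six-target CEN/DMN montage, synthesises the cross-frequency-
coupled waveforms for the 45 deg (partially in-phase) and 180 deg
(out-of-phase) conditions, and prints the realised phase lag, the peak
summed source current against the 1.5 mA safety cap, and the current-
conservation residual.
"""

import numpy as np

from cfctacs.stimgen import (
    StimConfig,
    build_condition_waveforms,
    default_montage,
    estimate_phase_lag,
    export_waveform_set,
)

config = StimConfig(f_p=6.0, f_a=40.0, a_fa=0.2, a_fp=0.8, fs=500.0, duration=6.0)
montage = default_montage(total_current_cap=1.5)

for condition in (45, 180):
    ws = build_condition_waveforms(montage, config, condition)
    lag = estimate_phase_lag(
        ws.electrode("Fpz"), ws.electrode("F3"), config.f_p, config.fs
    )
    print(f"condition {condition:>3} deg:")
    print(f"  realised DMN-vs-CEN lag : {lag:8.3f} deg (configured {condition})")
    print(f"  peak summed source      : {ws.source_current().max():8.4f} mA (cap 1.5)")
    print(f"  |net current| residual  : {np.abs(ws.net_current()).max():.2e} mA")
    path = export_waveform_set(ws, f"waveforms_{condition}.tsv")
    print(f"  exported to {path} (+ .json sidecar)")

# The realised lag should match the configured condition within a degree;
# the residual shows that stimulus + return currents cancel exactly.
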