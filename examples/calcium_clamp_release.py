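"""Dose-response of the dual-sensor release machinery to Ca2+ steps.

Clamps cytosolic Ca2+ at increasing levels and reports the peak total
release rate and its latency: higher Ca2+ gives a larger, earlier release
transient that decays within tens of milliseconds as the primed pool
empties.
"""
import numpy as np

from boutonsim import load_parameters, run_ca_clamp

params = load_parameters()
levels = [0.1, 0.5, 1, 2, 5, 10, 20, 50, 100]
res = run_ca_clamp(levels, params, T=100.0)

print("Ca clamp (uM)   peak rate (ves/ms)   time to peak (ms)")
for lev, pk, tp in zip(res.levels, res.peak_rate, res.time_to_peak):
    print(f"{lev:12.1f}   {pk:18.4f}   {tp:17.1f}")
print("\nPeak rate grows and latency shrinks with the clamp level; at rest "
      "(0.1 uM)\nonly the spontaneous pathway (~1e-4 vesicles/ms for a "
      "fully primed pool) remains.")
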