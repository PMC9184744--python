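"""Quantify MPS periodicity: averaged autocorrelation amplitude and period.

Simulates 50 axon segments carrying 190-nm-spaced rings plus a uniform
control, runs the standard analysis (project -> bin at 10 nm -> per-segment
autocorrelation -> average), and compares the two conditions with the
replicate-level t-test.
"""

import mpskit.periodicity as per
from mpskit.pipeline import averaged_autocorrelation
from mpskit.simulate import MPSSimConfig, simulate_mps_localizations, simulate_uniform_control

# periodic condition: three "biological replicates" (independent seeds)
periodic_amps, control_amps = [], []
for replicate_seed in (1, 2, 3):
    cfg = MPSSimConfig(seed=replicate_seed)
    table, rois, truth = simulate_mps_localizations(cfg)
    curve = averaged_autocorrelation(table, rois)
    result = per.periodicity_metrics(curve)
    periodic_amps.append(result.amplitude)
    if replicate_seed == 1:
        print(f"periodic:  period = {result.period:.0f} nm "
              f"(true {truth.period:.0f}), amplitude = {result.amplitude:.2f}, "
              f"valleys at {result.valley_lags[0]:.0f} / {result.valley_lags[1]:.0f} nm")

    ctable, crois = simulate_uniform_control(cfg)
    control_amps.append(per.periodicity_metrics(averaged_autocorrelation(ctable, crois)).amplitude)

print(f"control:   amplitude = {control_amps[0]:.3f} (no rings -> flat curve)")

test = per.compare_conditions(periodic_amps, control_amps)
print(f"t-test:    periodic {test.mean_a:.2f} +/- {test.sem_a:.3f} vs "
      f"control {test.mean_b:.3f} +/- {test.sem_b:.3f} (s.e.m., n=3), "
      f"t = {test.t:.1f}, p = {test.p:.1e}")
print("The amplitude (first peak minus mean of the flanking valleys) measures the")
print("degree of periodicity; the first-peak lag is the ring spacing estimate.")
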