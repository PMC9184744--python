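"""Two-color cross-correlation: where does a partner protein sit in the repeat?

Channel-2 rings are placed midway between channel-1 rings (half-period offset,
the actin-ring vs spectrin-center geometry). The first positive-lag maximum of
the averaged cross-correlation, converted to degrees of the period, reads out
the inter-channel phase shift; phase-aligned averaging shows the partner's
density midway between the reference crests.
"""

import numpy as np

import mpskit.periodicity as per
from mpskit.pipeline import segment_profiles, two_color_phase_shift
from mpskit.simulate import MPSSimConfig, simulate_two_color_localizations

cfg = MPSSimConfig(seed=1, n_channels=2, channel_phase_offset=0.5)
table, rois, truth = simulate_two_color_localizations(cfg)

shift = two_color_phase_shift(table, rois)
print(f"period (channel 1 autocorrelation): {shift['period_nm']:.0f} nm")
print(f"first positive cross-correlation maximum: {shift['extremum_lag_nm']:.0f} nm")
print(f"measured phase shift: {shift['phase_shift_deg']:.0f} degrees "
      f"(constructed offset: {truth.channel_phase_offset * 360:.0f})")

# phase-aligned averaging: align on channel 1, average both channels
refs = segment_profiles(table, rois, channel=1)
partners = segment_profiles(table, rois, channel=2)
ref_avg, par_avg = per.align_and_average(refs, partners, shift["period_nm"])
period_bins = int(round(shift["period_nm"] / ref_avg.bin_size))
ref_peak = ref_avg.bin_centers[np.argmax(ref_avg.counts[:period_bins])]
par_peak = par_avg.bin_centers[np.argmax(par_avg.counts[:period_bins])]
print(f"aligned-average crests: reference at {ref_peak:.0f} nm, "
      f"partner at {par_peak:.0f} nm -> partner sits midway between reference stripes")
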