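"""Compute time-domain, frequency-domain and nonlinear HRV parameters.

The RR series below mixes a 0.1 Hz (LF) and a 0.25 Hz (HF) oscillation with
autocorrelated noise, mimicking autonomic modulation of the heart rate.
"""

from pafscreen.hrv_frequency import freq_domain_features
from pafscreen.hrv_nonlinear import nonlinear_features
from pafscreen.hrv_time import time_domain_features
from pafscreen.synthetic import synth_rr_series

rr = synth_rr_series(
    600, mean_rr_ms=900.0, lf_amp_ms=30.0, hf_amp_ms=35.0, ar_sd_ms=15.0, seed=1
)

td = time_domain_features(rr)
fd = freq_domain_features(rr)
nl = nonlinear_features(rr)

print(f"mean RR {td.RRmean:.0f} ms, SDNN {td.SDNN:.1f} ms, RMSSD {td.RMSSD:.1f} ms, "
      f"pNN50 {td.pNN50:.1f} %")
print(f"LF {fd.LFpower:.0f} ms^2, HF {fd.HFpower:.0f} ms^2, LF/HF {fd.LF_HF:.2f}")
print(f"SD1 {nl.SD1:.1f} ms, SD2 {nl.SD2:.1f} ms, SampEn {nl.SampEn:.2f}, "
      f"DFA alpha1 {nl.alpha1:.2f}")

# SDNN reflects overall variability; the HF band power should exceed LF here
# (hf_amp > lf_amp); SD1 tracks short-term variability like RMSSD; alpha1
# between 0.5 and 1.5 indicates correlated (non-white) beat-to-beat dynamics.
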