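"""Estimate a transit time by cross-correlation and compare with the truth.

The distal flow waveform is the proximal one delayed by exactly 102.5 ms
(a fractional number of samples at 1 kHz); ensemble averaging over 25
cycles plus parabolic peak refinement recovers the delay to well below one
sample.
"""

from archpwv import compute_pwv, estimate_transit_time, synthesize_flow_pair

TRUE_DELAY_S = 0.1025

prox, dist = synthesize_flow_pair(TRUE_DELAY_S, noise_sd=0.01, seed=2)
res = estimate_transit_time(prox, dist)

print(f"imposed delay   : {TRUE_DELAY_S * 1000:.1f} ms")
print(f"estimated delay : {res.transit_time_s * 1000:.2f} ms "
      f"(peak correlation {res.peak_correlation:.3f})")
print(f"error           : {abs(res.transit_time_s - TRUE_DELAY_S) * 1e6:.0f} us")

pwv = compute_pwv(0.362, res.transit_time_s)
print(f"PWV for a 36.2 cm centerline: {pwv.reported:.2f} m/s")
# With 1% waveform noise the estimate stays within a fraction of a sample,
# giving PWV at the 0.01 m/s reporting precision.
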