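"""Treatment-quality metrics on a hand-built INR series.

Rosendaal TTR interpolates the INR linearly between visits and splits the
covered time at the exact range-crossing instants; the variance growth
rate (VGR) averages squared INR jumps per week between consecutive
visits.
"""

from vkawindows import classify_dose_change, inr_proportions, rosendaal, vgr

# days 0..30, target range 2.0-3.0
days = [0, 10, 20, 30]
inrs = [2.0, 4.0, 2.5, 1.0]

ttr, tbr, tar = rosendaal(days, inrs, 2.0, 3.0, window_start=0, window_end=30)
print(f"TTR {ttr:.1f}%  TBR {tbr:.1f}%  TAR {tar:.1f}%")
# Rising 2.0->4.0 crosses the upper limit at day 5; falling 4.0->2.5
# re-enters at day ~16.7, and 2.5->1.0 drops below 2.0 at day ~23.3.

print(f"VGR {vgr(days, inrs):.2f} INR^2/week")

prop_in, below, above, ge5, ge8 = inr_proportions(inrs, 2.0, 3.0)
print(f"INRs within/below/above range: {prop_in:.0f}% / {below:.0f}% / {above:.0f}%")

for prev, nxt in [(2.0, 1.8), (2.0, 2.1), (2.0, 2.3)]:
    print(f"dose {prev} -> {nxt} tablets/day: {classify_dose_change(prev, nxt)}")
# A >=10% change in the recommended average daily dose between two
# consecutive visits is a clinically relevant adjustment.
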