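"""Quantify percent DNA broken over a Southern-blot time course.

Lanes carry a parental band and DSB-fragment bands whose areas follow a
break-repair kinetic model (first breaks at 5 h, repair complete by 8 h);
in the rad50S background repair is deficient, so breaks accumulate.
"""

from dsbquant import GelKinetics, quantify_lane
from dsbquant.synthetic import simulate_lane_timecourse

times = [0, 3, 5, 5.5, 6, 6.5, 7, 7.5, 8]

for label, kin in [
    ("repair-proficient", GelKinetics()),
    ("rad50S (no repair)", GelKinetics(rad50S_mode=True)),
]:
    lanes = simulate_lane_timecourse(kin, times)
    broken = [quantify_lane(lane).broken_percent for lane in lanes]
    row = "  ".join(f"{b:5.2f}" for b in broken)
    print(f"{label:18s} broken % at {times} h:\n  {row}")

# The repair-proficient series rises to ~8% broken DNA at the 6.5 h peak
# and returns to zero by 8 h; the rad50S series rises and stays flat.
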