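"""Inspect the exponentially decreasing elimination schedule.

For v variables over N Monte-Carlo runs the keep ratio q_i = z e^{-t i}
starts at 1 (all variables enter run 1) and ends at 2/v (two variables
remain at run N).
"""

from carslogit import edf_schedule

schedule = edf_schedule(v=100, N=50)
print(f"z = {schedule.z:.6f}, t = {schedule.t:.6f}")
print(f"{'run':>4}{'keep ratio':>12}{'keep count':>12}")
for i in (1, 2, 5, 10, 25, 40, 50):
    print(f"{i:>4}{schedule.keep_ratio[i - 1]:>12.6f}{schedule.keep_count[i - 1]:>12}")
# The forced-elimination phase is aggressive early and gentle late: half
# the pool is gone within the first ~9 runs for v=100, N=50.
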