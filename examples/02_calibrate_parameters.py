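"""Calibrate the occupation deadline on a simulated season with swarming.

The simulator plants genuine leading-following events at night and, once a
box is occupied, emits morning swarming bursts from 05:30.  Sweeping the
morning deadline over {2, 3, 5, 8} shows the calibration logic at work:
the time-difference distributions at 2, 3 and 5 a.m. are statistically
indistinguishable (the extra events are genuine), while the 8 a.m. cell
absorbs swarming reads and its distribution shifts toward larger gaps —
flagged by the one-sided bootstrapped rank-sum test.
"""

from leadfollow import ParamGrid, SimConfig, calibration_table, simulate

recordings, truth, boxes = simulate(SimConfig(seed=5))
print(f"{len(recordings)} reads, {len(truth.events)} planted events, "
      f"{len(truth.occupation_dates)} occupied boxes")

grid = ParamGrid(lf_delays=(5.0,), turnarounds=(3.0,), deadlines=(2.0, 3.0, 5.0, 8.0))
report = calibration_table(recordings, boxes, grid, n_boot=1000, seed=1)

print("\ndeadline pair   p(two-sided)  p(one-sided)   n_lo  n_hi")
for t in report.tests:
    print(f"{t.deadline_lo:>4.0f} / {t.deadline_hi:<4.0f}    "
          f"{t.p_two_sided:>10.4f}  {t.p_one_sided:>12.4f}   {t.n_lo:>4d}  {t.n_hi:>4d}")

sel = report.selected
print(f"\nselected: lf_delay={sel.lf_delay} min, turnaround={sel.turnaround_time} min, "
      f"deadline={sel.occupation_deadline:.0f} a.m.")
# Pairs involving the 8 a.m. deadline come out significant (small p), the
# earlier pairs do not, so the selector keeps the latest uncontaminated
# deadline (5 a.m.) — the cell that maximizes events without distortion.
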