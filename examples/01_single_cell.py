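"""A first look at the cellular model.

Paces the baseline human atrial cell to steady state, prints its
biomarkers, and shows the (shallow) APD90 restitution between 1000 ms and
800 ms cycle lengths.  Runtime: about 10 s.
"""

from atriavar import ConductanceScaling, PacingProtocol, pace_cell
from atriavar.biomarkers import compute_biomarkers
from atriavar.crn import apd90_restitution
from atriavar.io import trace_to_csv

# Full protocol is 101 beats; 30 is close enough for a demo.
protocol = PacingProtocol(n_beats=30, bcl=1000.0)
last_beat, quiescent, end_state = pace_cell(ConductanceScaling(), protocol)

bm = compute_biomarkers(last_beat)
print("Baseline biomarkers (30 beats, BCL 1000 ms):")
for name in bm.NAMES:
    print(f"  {name:>6} = {getattr(bm, name):8.2f}")

trace_to_csv(last_beat, "baseline_ap.csv")
print("last-beat trace written to baseline_ap.csv")

print("\nAPD90 restitution (steady pacing at each cycle length):")
for bcl, apd in apd90_restitution(ConductanceScaling(), [1000.0, 800.0],
                                  n_beats=30):
    print(f"  BCL {bcl:6.0f} ms -> APD90 {apd:7.2f} ms")
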