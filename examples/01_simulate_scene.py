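"""Generate a synthetic farrowing scene and inspect its structure.

Builds the full default scenario (4 h nest-building, a litter of 12, 4 h
post-farrowing), prints the timeline, the per-phase behaviour budgets and
the sound-event census.  The budgets should sit near the field values:
71.7/3.3/25 % (lying / sitting-standing / rooting) before farrowing,
93.5/6.2/0.3 % during, 100/0/0 % after.
"""
from collections import Counter

from farrowcam import PenGeometry, SimConfig, simulate_scene, time_budget

geometry = PenGeometry()
cfg = SimConfig(seed=42)
timeline, script, events, audible, behaviour = simulate_scene(cfg, geometry)

print(f"onset at {timeline.t_onset / 3600:.2f} h, "
      f"{len(timeline.birth_times)} births, "
      f"farrowing ends {timeline.t_end_farrowing / 3600:.2f} h, "
      f"scene {timeline.duration / 3600:.2f} h")

for budget in time_budget(behaviour, timeline):
    shares = ", ".join(f"{k} {100 * v:.1f}%" for k, v in budget.proportions.items())
    print(f"  {budget.phase:>6}: {shares}")

census = Counter(e.label for e in events)
print("sound events:", dict(sorted(census.items())))
print(f"audible to the observer: {len(audible)} of {len(events)} "
      f"(piglet births audible: {(audible.entries['label'] == 'Piglet').sum()})")
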