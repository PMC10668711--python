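"""Detect farrowing onset, progress and end from a spot stream.

Simulates a full farrowing (4 h nest-building, 12 births, 4 h post) and
feeds the idealised spot stream to the onset monitor.  The estimated
onset should land within minutes of the true cross-over from rooting to
farrowing, and the estimated end near the last piglet activity behind
the sow.
"""
from farrowcam import PenGeometry, SimConfig, detect_onset, monitor_progress
from farrowcam.scene_sim import events_to_spot_log, simulate_scene

geometry = PenGeometry()
cfg = SimConfig(seed=7)
timeline, script, events, audible, behaviour = simulate_scene(cfg, geometry)
spots = events_to_spot_log(events, geometry)

report = detect_onset(spots)
report = monitor_progress(spots, report)

h = 3600.0
print(f"true onset  {timeline.t_onset / h:6.2f} h   estimated {report.t_onset_est / h:6.2f} h "
      f"(error {report.t_onset_est - timeline.t_onset:+.0f} s)")
print(f"true end    {timeline.t_end_farrowing / h:6.2f} h   estimated {report.t_end_est / h:6.2f} h "
      f"(error {report.t_end_est - timeline.t_end_farrowing:+.0f} s)")
print(f"progress intervals: {len(report.progress_intervals)}; "
      f"alerts: {[(round(t / h, 2), kind) for t, kind in report.alerts]}")
print("a 'stalled' alert marks a gap in rear-zone activity longer than the "
      "progress timeout - the cue a farmer would act on.")
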