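# Methods

This note documents the models, numerical choices and limitations of
`farrowcam`, in the spirit of a methods appendix. Everything quantitative
below is computed by the test suite or `scripts/acceptance.py`; nothing is
asserted that the code does not measure.

## Scene model

One crated sow is monitored in a 2.80 × 1.75 m pen with a 2.1 × 1.0 m
crate, an overhead 64-microphone acoustic camera and a reference
(human-annotated) record of audible sounds and behaviour. Coordinates are
metres from a pen corner, x along the pen axis, head end at low x, floor
at z = 0. The zone partition (head = front third of the crate, rump =
the rest of the crate, trough strip before the crate, 0.15-m fence strip
along the walls) is a modelling choice: the field zones are named but not
given coordinates, and the middle of the crate is assigned to the rump
("behind the head") so the partition stays total.

**Timeline.** `t_start ≤ t_onset ≤ births… ≤ t_end_farrowing ≤ t_stop`.
Inter-birth gaps are exponential (default mean 15 min, litter 12,
matching a ~12–13 piglet litter); farrowing ends one postnatal window
(10 min) after the last birth. Nest-building ceases at `t_onset`; the
first birth follows ~10 min later.

**Behaviour.** Lying bouts alternate with active bouts (sitting/standing
or jute-sack rooting, drawn with probability ∝ budget/mean-dwell). Bout
lengths are gamma-distributed with shape 4 (CV 0.5): behaviour bouts are
far more regular than memoryless, and with exponential bouts the time
budgets of a 4-h phase would fluctuate by ±10 pp, which no observed
ethogram does. By renewal-reward the stationary share of each state
equals its configured budget whatever the bout distribution; the mean
lying bout is derived from the lying budget. Defaults are the observed
phase budgets — 71.7/3.3/25 % (lying/sitting–standing/rooting) before
farrowing, 93.5/6.2/0.3 % during, 100/0/0 % after — with active-bout
means of 60–90 s before farrowing and a 20-s residual rooting bout during
farrowing. A 40-h phase reproduces the budgets within ±2 pp; a 4-h phase
within ±5 pp.

**Sound events.** Poisson processes per label: sow vocalisations from the
head of the crate (0.2–0.4/min), trough and fence contacts, neighbour-sow
noise placed *outside* the pen bounds, rooting bursts (10/min inside
rooting bouts, head zone), one birth event per birth time and piglet
movement (2/min for one postnatal window per birth), both in the rear
third of the crate. Births and piglet movement are flagged inaudible:
in the field, piglet births were visible to the camera but not heard by
the observer, and the audibility of an event is treated as an independent
flag because the spectral link between what a human hears and the
ultrasonic band the camera analyses is unknown. Amplitudes are lognormal
(clipped to [0.4, 2.5]) at 1 m; the audible reference log contains
exactly the audible events above the audibility threshold (0.2).

**Audio.** Each event is a band-limited Gaussian noise burst (band centre
and 2-kHz width from the camera's analysis band) with 10 % raised-cosine
ramps, propagated along the direct path only: delay = distance/c
(c = 343 m/s), spherical 1/r attenuation, white background noise at an
SNR of 26 dB re a unit source at 1 m. No reverberation and no occlusion
by the sow's body — the model is free-field, so passing tests bound what
the method can do under ideal propagation, not in a reverberant barn.
The simulated recorder starts 1.5 s late, reproducing the constant spot-
stream lag that the detector corrects by adding 1.5 s.

## Beamformer

Time-domain delay-and-sum with 1/N normalisation on a 0.05-m floor grid;
sub-sample delays by linear interpolation (at 192 kHz a half-sample
rounding error is 41° of carrier phase at 44 kHz, which measurably dents
the coherent peak; nearest-sample shifting remains available as a flag).
Frames are 50 ms with a 50-ms hop; one spot per frame at most.

**"No clear source" rule.** The frame's map maximum must exceed the map
median by 6 dB; the median is a per-frame noise floor, robust to
nonstationary background. The field system's actual criterion is not
public; threshold, frame length and grid spacing are all configuration.

**Spatial filter.** The beamformer *searches* 0.8 m beyond the shown
region and then hides out-of-region maxima. Restricting the search
itself to the pen would instead leak an out-of-pen source's sidelobes
into the shown map; searching wide lets a neighbour-sow source localise
at its true position outside the pen and vanish behind the filter.

**Array layout.** The default camera is an irregular (Poisson-disk,
fixed-seed) planar 64-microphone layout with a 0.32-m aperture. At
8-mm wavelengths any periodic centimetre-pitch grid produces grating
lobes of near-full height — a regular 8 × 8, 0.04-m-pitch array mislaid
off-grid sources by 0.4–0.5 m in exactly the way periodic-array theory
predicts — and irregular layouts, as used by commercial acoustic cameras,
spread that aliased energy into a ~1/√N sidelobe floor. The regular
square layout remains available (`overhead_array`) and still localises
on-lattice calibration sources correctly.

**Long scenes.** A 30-min, 64-channel scene cannot be beamformed
time-domain sample-by-sample in reasonable time, so the scanner (i) renders
the scene in 10-s chunks with a rolling tail buffer (the sample stream is
identical to a one-shot render), (ii) gates frames on broadband RMS
against the chunk's median frame RMS — a silent frame cannot contain a
clear source — and (iii) processes gated frames in complex baseband:
demodulate at the band centre, decimate ×16 (6 kHz complex rate for a
2-kHz band), align to the nearest decimated sample and steer with the
exact carrier phase e^{j2πf₀τ}. This is the standard narrowband-
equivalent of the same delay-and-sum operation; the test suite checks it
against the time-domain kernel on identical frames. Candidate positions
come from an *envelope*-aligned coarse map (its peak is as wide as the
burst's ~17-cm correlation length, so a 0.1-m coarse grid cannot drop the
true source between nodes the way the ~6-cm coherent main lobe can),
then the coherent map is refined on the 0.05-m lattice around the best
candidates. The demo 30-min scene is sampled at 96 kHz — still beyond
twice the band's upper edge — purely to bound the render cost; short
scenes and the localisation tests use the full 192 kHz.

## Matcher

Pairing spots with audible reference sounds is an exact maximum-
cardinality, minimum-total-|Δt| one-to-one assignment over pairs with
|Δt| ≤ 1 s, solved blockwise (connected components of the feasibility
graph) with the Hungarian algorithm. A nearest-|Δt| greedy heuristic was
considered and rejected: it is provably suboptimal (refs {0, 1}, spots
{−1, 0.5}, tolerance 1 — greedy finds one pair, the maximum is two), and
the matcher is required to agree with a brute-force maximum matching.

Behaviours are states, not point events: a spot inside an *active*
behaviour interval (rooting, eating, standing, leg movement,
sitting/standing — not lying), with zone corresponding per the behaviour
table, is behaviour-backed; the interval can back any number of spots,
and tolerance applies at its edges. An active interval containing no
spot at all counts one FN. In the combined mode a spot is correct if
either stream (or both) supports it. Lying is silence: correct negatives
are counted on the complement of spot times, audible-sound spans and
active-behaviour intervals, one CN per full 2 s of a silent stretch
(`floor` mode; `per_stretch` — one CN per stretch — is available because
the field counting rule for long silences is not stated and the printed
CN total cannot be re-derived without the raw logs).

Clouds — five or more spots within 1 s and 0.3 m — are collapsed to
their first spot before matching, following the slow-replay observation
that spot clouds start with one spot in the correct place.

**Specificity.** The printed formula in the source reads CN/(FN+CP),
which gives 47.5 on the published counts and matches neither printed
column; the standard definition CN/(CN+FP) reproduces the printed 12.8
in both wrong-location policies and is used. Precision (CP/(CP+FP)) and
% correct positive (CP/total) carry no printed formula; these are the
field-standard interpretations. Metric rounding is half-up to one
decimal, at presentation only.

## Onset monitor

All thresholds are configuration, not measurements — the monitoring idea
is proposed in the source without numeric criteria. Defaults: 600-s
sliding window; arm at ≥ 2 head-zone spots/min (sustained nest-building);
cessation when the rate falls below 1/min (the 0.3 % residual rooting
during farrowing keeps the during-farrowing head rate well under this);
confirm with ≥ 5 rear-zone spots within one window (births under way);
estimate onset as the last head-zone spot before the confirmed cessation.
Progress timeout 1800 s for stall alerts and the end estimate; the end
additionally requires head activity to stay below the cessation rate so
that occasional vocalisations of the resting sow do not postpone it
forever. Raising the rear-cluster minimum can only delay onset (the
confirmed candidate set shrinks). Across 20 simulated farrowings the
median |onset error| is 4-5 min and the end lands within minutes of the
last piglet activity; leg-movement behaviour is mapped to rump-zone spots
in the simulator but is not a separate detector input — its description
is insufficient to model.

## Problem sizes used by tests and acceptance

Localisation checks use single 40-ms bursts; the end-to-end check runs
one full 30-min scene (64 channels, 96 kHz, ~4 min of compute); onset
recovery uses 20 independent full farrowing scenes at event-log level;
budget convergence uses one 40-h behaviour script. Recovery is scored
for in-pen events only (the spatial filter hides the rest) against a
±1-s, one-grid-cell window; the residual misses are concurrent events
competing for the single spot a frame can hold.

## Known limitations

Free-field propagation (no reverberation, occlusion or air absorption);
a single pen per scene; audibility as an independent flag rather than a
spectral model; one spot per frame (multi-peak extraction deferred);
onset thresholds tuned to the simulator's event rates, to be recalibrated
on real spot streams; the published combined sound-and-behaviour metrics
cannot be reproduced numerically because their underlying counts were
never printed — the package reproduces that comparison qualitatively on
synthetic scenes instead.
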