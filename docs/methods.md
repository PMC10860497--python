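# Methods

This note documents the model behind the toolkit, the numerical conventions
it commits to, what the synthetic scenes do and do not emulate, and the
design choices made where the procedure itself leaves room.

## Stimulus model and timing

A stimulus is a constant-frame-rate video with three segments: an
unchanging *lead*, a *morph* during which one large scene region fades
linearly in RGB from a start color to an end color, and an unchanging
*tail*. All timing lives in `MorphConfig`:

| parameter | default | meaning |
|---|---|---|
| `fps` | 12 | frames per second; all durations must be whole frames |
| `lead_s` / `tail_s` | 2 s | bookends showing the first/last frame unchanged |
| `morph_s` | 16 s | slow fade; `fps * morph_s` = 192 morph frames |
| `quick_change_count` | 3 | one event per togglable feature (0–3) |
| `quick_change_duration_s` | 1 s | each quick change cross-fades over 12 frames |
| `min_gap_s` | 1 s | minimum separation between quick-change windows |
| `seed` | — | master seed; recorded in the manifest |

Defaults give a 20 s, 240-frame video. The config validates that
`quick_change_count * (duration + min_gap) <= morph_s`, which also
guarantees the scheduler can always pack the windows.

Morph frame `i` (0-based, `n` frames) is computed per pixel and channel in
float64 as `round(S + i/(n-1) * (E - S))` with **half-up rounding** — a
fixed convention chosen over numpy's banker's rounding so every frame is
reproducible bit for bit across platforms. The inclusive-endpoint fraction
`i/(n-1)` makes the first and last morph frames exact copies of the inputs.
Consequences of this arithmetic:

- every pixel/channel trajectory is monotone between its endpoints;
- the slow fade is a *quantized* ramp: a channel whose total change is `D`
  counts steps `D` times, and the first/last `ceil(0.5*(n-1)/D)` morph
  frames are bit-identical to the bookend frames (the *quantization dead
  zone*). For the default 192-frame morph, a 96-count change leaves 1 dead
  frame per end, a 71-count change 2.

## Quick changes

The procedure states only that quick changes are non-instantaneous, lasting
1 s; the transition mechanism is an open choice. We use a per-pixel linear
cross-fade between the pre-flip and post-flip morph series at the same
morph index, with weight `alpha = (j+1)/12` at window offset `j`, so the
final window frame equals the post-flip series exactly and the slow fade
never pauses (the morph index always advances one per frame). Windows are
half-open `[onset, onset+12)` in morph-frame coordinates, pairwise
separated by at least the 1 s gap, and onsets are drawn by rejection
sampling without replacement from all feasible indices — uniform over the
feasible set by construction — with the event-to-feature assignment a
uniform random permutation under the same seed. Each feature flips exactly
once, from the first to the second label of its state domain.

The fixation overlay (a filled white circle, radius 6 px, image center) is
drawn on every lead and tail frame; the four-line cross-hair (horizontal,
vertical, two diagonals, 5 px wide, spanning the full image) is flashed for
the last 0.5 s of the lead and the first 0.5 s of the tail. The flash
duration is configurable; 0.5 s is our choice where the procedure specifies
none.

## Synthetic scenes

`scene.demo_spec` / `scene.battery_specs` render cartoon-like stand-ins for
hand-edited source images: a large, centrally located ellipse or rounded
rectangle (the slow-change element) on a plain background, plus up to three
small glyph features (arrow orientation, dot-cluster presence, bar
orientation) in the margins. Inside the slow region a deterministic
luminance texture — a pure integer-hash function of `(render_seed, x, y)`,
uniform on `[-a, a]` with default amplitude 8 — emulates pictorial
structure while keeping the region mean within one count of the nominal
fill color. Feature boxes are always repainted from the background, so
their pixels never depend on the slow color even when a box overlaps the
region.

What this emulates well: the composite-set combinatorics (2 × 2^k
co-registered images), color isolation (only the slow region differs
between color versions), state isolation (only a feature's box differs
between its states), and measurable region-mean colorimetry. What it does
not emulate: because the texture offset is *added* to both endpoint colors,
every region pixel shares the same per-channel delta `D`, which makes the
region-mean trajectory a globally synchronized staircase — the worst case
for linearity measurement. Real artwork, whose hue-shifted pixels have
heterogeneous deltas, produces smoother mean trajectories; passing QC on
the synthetic staircase is therefore the conservative direction. The
default canvas is 480 × 480 (square, like the published stimuli; the
sources state no resolution). Tests and the acceptance script render most
scenes at 64–240 px — the structure under test is resolution-independent —
and one full-size 480 px stimulus is generated and validated end to end.

The five battery color pairs (start → end) use one nominal RGB per color
name: Yellow (230, 200, 40), Orange (226, 129, 33), Purple (128, 62, 160),
Blue (58, 84, 196) — saturated mid-brightness values chosen once as
plausible cartoon fills; the "non-standardized" purple–orange variant
shifts brightness deterministically per scene to emulate colors tailored to
each image.

## Video containers

Quality control needs bit-exact round-trips, so the default codec writes
uncompressed 24-bit RGB frames into a plain RIFF/AVI container (BI_RGB,
bottom-up BGR rows, constant frame rate in the stream header) and reads it
back natively — no external encoder is involved, and
`decode(encode(x)) == x` holds exactly. FFV1/MKV (lossless) and H.264/MP4
(browser-playable deployment) presets shell out to an `ffmpeg` binary when
one is on PATH and raise a clear environment error otherwise. Every encode
writes a JSON manifest (schema v1) echoing the full configuration, the
schedule, nominal and measured endpoint colors, and — for lossless runs —
per-frame SHA-256 checksums; regenerating from the manifest's config
reproduces every checksum.

## Validation (QC)

The validator re-derives everything from pixels:

1. **Region mask** — pixels where first and last frame differ (per-channel
   tolerance 0 lossless, 8 lossy), refined by dropping pixels that ever
   jump more than 8 counts between consecutive frames (quick-change pixels
   move an order of magnitude faster than the slow fade, so this separates
   them even where a feature overlaps the region).
2. **Breakpoints** — exhaustive least-squares search over all integer
   breakpoint pairs of a flat–linear–flat model on the per-channel
   region-mean trajectory (sequences are a few hundred frames; exhaustive
   search is cheap, deterministic, ties to the first minimum). Recovered
   lead/tail lengths exceed the configured ones by exactly the quantization
   dead zone described above; the check corrects for it (computed from the
   measured endpoint colors, not from the manifest) and then requires exact
   agreement for lossless input, ±1 frame for lossy.
3. **Linearity** — per-channel slope and R² of the morph-segment fit. A
   quantized ramp of range `D` has an R² floor of about `1 − 1/D²`, so the
   0.999 threshold is asserted only over channels with `D ≥ 32`; smaller
   channels are reported but carry no linearity information.
4. **Quick-change onsets** — frame-to-frame mean absolute difference
   *outside* the slow mask; frames above 5× the morph-segment median are
   grouped into events whose first changed frame is the onset (tolerance ±1
   frame lossless, ±2 lossy).
5. **Endpoint colors** — region means of the first/last frames, compared to
   the manifest's measured means (exact for lossless, ±3 counts lossy).

A structurally broken video (e.g. constant color) yields a failing report
with diagnostics, never an exception.

## Statistics

Responses arrive as a coder-filled CSV; the coding criterion (any mention
of a change in the slowly changing element counts as detection) is
judgment-based and deliberately not automated. Blank quick-change cells
mean "no such change in this stimulus", so opportunity counts are conserved
under regrouping. Implemented tests: detection proportions (reported to 3
decimals, raw floats retained); pooled two-proportion z (two-sided);
paired t on differences (df = n−1; `tail="one"` halves the two-sided p —
exposed because adjacent-vs-distant color comparisons are directional;
identical vectors return t = 0, p = 1, while constant nonzero differences
are degenerate); one-way repeated-measures ANOVA with the level×subject
interaction as error (df = (k−1, (k−1)(n−1)); (4, 40) for 5 colors × 11
images); Pearson r with the t-approximation p (df = n−2). The t test and
correlation wrap scipy.stats; the z test and ANOVA are direct
sum-of-squares implementations, cross-checked in the test suite against
statsmodels and pingouin to 1e-10.

## Known limitations

- Only color morphs of a single region: no geometric morphing, no multiple
  slow-change regions.
- The quick-change cross-fade is one reasonable reading of
  "non-instantaneous"; staged partial states would look different in the
  difference signal (the onset detector would still find them).
- Synthetic scenes are structurally faithful but visually minimal; passing
  QC here demonstrates pipeline correctness, not perceptual equivalence to
  hand-drawn artwork, and no perceptual (CIE/ΔE) color metrics are used.
- Uniform-delta texture makes region trajectories maximally staircase-like
  (see above); real images should only validate more cleanly.
- Human detection rates cannot be reproduced computationally; the
  statistics module reproduces the *arithmetic* of such analyses and is
  validated against independent implementations, not against human data.
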