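# slowchange

A toolkit for building, validating and analyzing **slow change blindness**
video stimuli.

Observers routinely fail to notice even large changes in a scene when those
changes unfold gradually — a striking phenomenon that is hard to study
because usable stimuli are scarce and because asking "did you see a change?"
after one trial tends to spoil all later trials. The standard remedy is a
video in which a large, central scene element fades from one color to
another over many seconds while a few small, *obvious* "quick changes"
(an object flipping, appearing, or rotating) give the experimenter a
truthful pretext to ask about changes without pointing at the slow one.

`slowchange` implements that stimulus pipeline end to end, for vision
scientists who need batteries of such videos plus the bookkeeping to trust
and analyze them:

- **scene synthesis** (`slowchange.scene`) — procedural, cartoon-like
  composite image sets: one large central slow-change region (with
  deterministic luminance texture) and up to three togglable glyph features,
  rendered for every combination of color × feature state;
- **composite I/O** (`slowchange.composites`) — the
  `Img#_Color_state….png` naming grammar, grid completeness checks, loading;
- **morph engine** (`slowchange.morph`) — linear RGB interpolation between
  the two color versions, randomized non-overlapping quick-change windows,
  and frame assembly from the parallel morph series;
- **video codec** (`slowchange.video`) — lossless native AVI (bit-exact
  round-trips, no external encoder needed), optional ffmpeg-backed
  FFV1/H.264, and a JSON manifest that fully determines regeneration;
- **quality control** (`slowchange.qc`) — frame-accurate recovery of the
  generation parameters from pixels alone;
- **statistics** (`slowchange.stats`) — detection proportions, paired *t*,
  one-way repeated-measures ANOVA, two-proportion *z*, Pearson correlation,
  for coder-labelled response tables.

## The stimulus model

A stimulus with frame rate $f$ (default 12 fps) is

$$\underbrace{2\,\mathrm{s}}_{\text{lead}}\; \underbrace{16\,\mathrm{s\ morph}}_{n = 192\ \text{frames}}\; \underbrace{2\,\mathrm{s}}_{\text{tail}} \;=\; 20\,\mathrm{s},\ 240\ \text{frames}.$$

Morph frame $i \in \{0,\dots,n-1\}$ is, per pixel and channel,

$$F_i = \mathrm{round}\!\left(S + \tfrac{i}{n-1}\,(E - S)\right),$$

with half-up rounding, where $S$ and $E$ are the start- and end-color
composites for the current quick-change state. One such *morph series*
exists per feature-state combination; the assembled video advances the
morph index by exactly one per frame and switches between parallel series
when a quick change occurs, cross-fading linearly over a 1 s (12-frame)
window. Onsets are drawn uniformly over the feasible frame indices with a
minimum 1 s gap between windows. An optional central fixation mark (with a
full-image four-line cross-hair flashed at its offset/onset) covers the
lead and tail.

## Worked example

```
$ slowchange synth --features 2 --size 480 --pair blue-yellow --out composites
...
wrote 8 composites to composites        # 2 colors x 2^2 feature states

$ slowchange generate --input composites --image-id 1 \
      --start-color Blue --end-color Yellow --seed 42 --out stimulus.avi
stimulus.avi (240 frames, 20.0 s)

$ slowchange validate stimulus.avi
duration: 20.000 s at 12 fps (240 frames)
segments: lead=25 morph=190 tail=25
morph linearity R^2 (R,G,B): 0.999966, 0.999925, 0.999958
region mean start: (57.99, 83.99, 195.99)
region mean end:   (229.99, 199.99, 39.99)
quick-change onsets (frame indices): [40, 164]
[PASS] monotone_trajectory: per-channel region mean is monotone across the morph
[PASS] morph_linearity: min R^2 over assessable channels = 0.999925 (threshold 0.999)
[PASS] fps: container fps 12, expected 12
[PASS] frame_count: 240 frames, expected 240
[PASS] breakpoints: lead/morph/tail = 25/190/25; expected 24/192/24 with a quantization dead zone of 1 frame(s) at each morph end
[PASS] quick_change_onsets: recovered [40, 164], manifest [40, 164] (tolerance +/-1 frames)
[PASS] endpoint_colors: max endpoint region-mean error 0.000 (tolerance 0.0)
overall: PASS
```

The validator decodes the video and re-measures everything from pixels: the
20 s / 240-frame structure, the flat–linear–flat region-mean trajectory
(the one extra flat frame at each morph end is the unavoidable rounding
dead zone for this color distance — see `docs/methods.md`), the exact
endpoint colors (region means of the blue and yellow fills), and the two
quick-change onsets, which match the manifest exactly.

Batteries (`slowchange batch`) generate one video per (scene, color pair)
cell — e.g. 11 scenes × 5 pairs → 55 videos — with per-cell seeds derived
stably from a master seed, plus an index CSV. Coded observer responses are
summarized with `slowchange stats`.

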