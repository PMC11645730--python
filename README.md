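# tmjmotion

Video-based kinematic assessment of temporomandibular joint (TMJ) mouth
opening, for clinicians and researchers studying functionally limited
temporomandibular disorders (TMD). Two 5-mm white stickers are placed on the
face — marker **A** at the nasolabial-groove midpoint and marker **B** at the
chin–labial-groove depression — and a frontal video of a natural
open–close cycle is recorded with the head fixed. `tmjmotion` detects and
tracks the two fiducials at sub-pixel precision, converts to millimetres
from the known sticker size, and computes the kinematic indices used to
quantify restricted or deviated mouth opening:

- **maximum mouth-opening distance** — the vertical displacement
  |y(B′) − y(B)| between the closed state B and the maximally open state B′;
- **maximum offset distance** — the largest horizontal displacement
  |x(B″) − x(B)| of the lower-lip landmark over the cycle, and its signed
  value at maximum opening;
- **maximum offset angle** — the largest signed angle between the rest
  segment AB and the moving segment A″B″ (positive = deviation to the
  subject's right);
- **offset direction** — left / right / none (dead zone 0.5 mm);
- **fluctuation series** — per-frame offset distance and angle across the
  cycle, whose frame-to-frame oscillation (summarised as the RMS of first
  differences) reflects joint-movement stability.

Group comparisons (patients vs controls) use a normality-gated two-sample
test: pooled-variance t (df = n_A + n_B − 2) with a 95% CI when both groups
pass Shapiro–Wilk, otherwise Mann–Whitney U with a Hodges–Lehmann shift. A
summaries-only mode reconstructs the pooled t-test from per-group
(mean, SEM, n), and offset-direction frequencies are compared with Fisher's
exact test.

Because clinical videos are rarely shareable, the package ships a synthetic
jaw-motion generator (rigid rotation about the condylar axis plus a
configurable lateral-deviation profile, rendered as anti-aliased discs with
noise) that provides exact ground truth for every pipeline stage.

## Worked example

Simulate a 101-frame opening cycle with a 4-mm rightward deviation, analyze
it, and compare two published group summaries:

```bash
tmjmotion simulate --out-dir /tmp/cycle --n-frames 101 --jaw-length 100 \
    --opening-deg 22 --deviation-mm 4 --width 360 --height 360 --mm-per-px 0.3
tmjmotion analyze --frames /tmp/cycle --out-dir /tmp/cycle_out
```

which prints (the analyzer knows nothing of the generator's parameters):

```
max opening 29.29 mm | max offset 4.00 mm | max offset angle 4.52 deg | direction right
```

Here 29.29 mm is the recovered vertical opening (ground truth 29.37 mm for
a 22° condylar rotation of a 100-mm jaw sampled at 101 frames), 4.00 mm the
recovered peak lateral deviation (truth 4.00 mm), and the direction is the
subject's right. `/tmp/cycle_out/` contains `features.json` (all indices
plus calibration provenance), `trajectory.csv`, `fluctuation.csv` and a
two-panel fluctuation diagram `fluctuation.png`.

Comparing a patient group (A) against controls (B) from printed summaries
(mean, SEM, n):

```bash
tmjmotion compare --summary 25.64 1.094 44 29.84 0.7984 37
```

```
summary: diff (B-A) = 4.20, SE = 1.40, 95% CI [1.41, 6.99], p = 0.003618 (pooled_t)
```

i.e. the controls' natural mouth opening is 4.20 mm larger on average, with
a confidence interval excluding zero. `tmjmotion compare --group-a a.csv
--group-b b.csv` runs the same machinery on raw per-subject feature tables
and adds the Fisher test on offset-direction counts.

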