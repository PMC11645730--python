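# Methods

## Kinematic model of the synthetic generator

The mandible is modelled as a rigid body rotating about the condylar axis.
In the sagittal plane the condyle→chin vector has length `jaw_length` L
(default 80–100 mm, the adult condyle-to-chin scale) and rest elevation
α₀ = asin(Δy / L), where Δy is the vertical condyle–B separation. An opening
rotation by θ(t) moves the chin marker B vertically by

    opening(t) = L · [sin(α₀ + θ(t)) − sin α₀].

A frontal camera sees only this vertical component of the rotation; the
horizontal (anterior) component is depth and is deliberately discarded —
the same reason 2-D video under-measures true opening, which we accept as a
modelling assumption rather than correct for. Lateral path deviation, the
clinically relevant asymmetry, is imposed directly on B's x coordinate by a
signed profile d(t) (+ = subject's right). Marker A follows B with a small
coupling fraction (default 0.05, bounded at 0.2) modelling soft-tissue drag
at the nasolabial groove, where skin–bone relative displacement is minimal.

Default profiles: a raised-cosine opening θ(t) = θ_peak·(1 − cos 2πt)/2
(smooth open–close, zero at both ends) and a compactly supported
cosine-squared deviation bump with configurable peak phase; a peak phase
later than 0.5 reproduces deviation that intensifies during closing. Peak
opening defaults to 18° (≈ 25 mm of vertical opening at the default
geometry, the natural — not forced-maximal — opening scale);
`opening_angle_for_distance` inverts the formula when a target opening in
millimetres is wanted.

Ground-truth features are always obtained by exhaustively scanning the
per-frame model evaluations; the closed-form peak values serve only as an
independent cross-check (they agree to 1e-9 when the frame grid contains
the profile peaks, e.g. 101 frames with peaks at t = 0.5).

## Rendering

Markers are rendered as anti-aliased discs (4× supersampled pixel
coverage) of radius 2.5 mm (5-mm sticker) on a uniform dark background
(0.1 vs 0.9 intensity), with optional additive Gaussian noise and an
optional bright border whose inner-edge columns emulate the acquisition
device's frame. All randomness flows from one integer seed and rendering is
bit-reproducible. Frames default to 1280×720 at 30 fps — plausible phone
video values, configurable, and not claimed from any source; the test and
benchmark stacks use 360×360 px at 0.3 mm/px and 61–101 frames, which keeps
the full grid benchmarks around a minute while leaving the discs ≈ 8 px in
radius, comfortably above the detector's resolution floor.

The renderer's `mirror_x` flag (default true) maps the subject's right to
image-left, as an unmirrored camera does; the calibration records the same
flag so signed lateral quantities are always reported in the subject's
frame.

## Detection and tracking

Detection is a global threshold (Otsu by default; fixed for controlled
experiments), 8-connected component labelling, an area gate and a
circularity gate (4π·area/perimeter² ≥ 0.6, lenient because an oblique
sticker is slightly elliptical), followed by a background-subtracted
intensity-weighted centroid: weights are intensity minus threshold, so the
anti-aliased rim carries the sub-pixel information while the saturated
plateau contributes no bias. Measured accuracy on rendered discs is
≈ 0.03 px RMS noiseless and well inside 0.5 px at noise SD 0.02. The
default area gate is [20 px², 1% of frame area]; when the expected marker
radius is known, `DetectionParams.for_marker_radius` tightens it to the
disc area ± 60%.

Frame-to-frame association assigns each of A/B to the nearest observation
within a gate of 3× the marker diameter (small relative to the A–B
separation, generous relative to inter-frame motion at video rates). The
first frame must yield both markers; single missing frames are linearly
interpolated and flagged, runs of ≥ 2 are reported as gaps, and > 20%
missing frames aborts.

Calibration defaults to the sticker diameter: mm/px = 5 mm divided by the
mean equivalent-circle diameter 2·√(area/π) of the rest-frame blobs. A
border-width method (sub-pixel inner-edge localisation on the column-median
intensity profile) is available when the device's inner width is known;
the two agree within 3% on synthetic stacks carrying both references.

## Key frames and features

The rest state is taken from the initial quasi-static run — the maximal
prefix in which B stays within the motion threshold (0.5 mm) of the first
frame. The rest *position* is the per-axis median over that run (noise
suppression); the rest *index* is the run's last frame, the frame
immediately before opening begins, a choice that makes the key-frame
indices shift by exactly k when k static frames are prepended. Maximum
opening is the frame of largest vertical B displacement from rest;
re-closure is the last frame afterwards that returns within the threshold.

The offset angle is defined as the signed angle between the rest segment AB
and the per-frame segment A″B″. AB is the only segment defined at rest, the
definition degrades gracefully to 0° for pure vertical opening, and with A
nearly stationary it is within 0.1° of the small-angle reading
atan(offset/(|AB| + opening)). Offset-distance and angle maxima are taken
over the whole cycle's per-frame series, not only at maximum opening,
because deviation can peak during closing; the at-maximum-opening values
are reported alongside so either convention is available. Both the signed
offset at maximum opening and the unsigned cycle maximum are emitted.

A direction call below 0.5 mm of lateral offset is suppressed ("none"):
that is sub-sticker precision, below the calibration noise floor. Markers
closer than 5 mm at rest are rejected as implausible landmark geometry.

The stability summary of a fluctuation series is the RMS of its first
differences — zero for smooth constant motion, strictly increasing with
frame-to-frame jitter. It is a simple, monotone formalisation of "larger
oscillation = poorer stability"; no canonical formula exists for it.

## Group statistics

Per-group summaries are mean, SD (n−1), SEM and Shapiro–Wilk normality p
(α = 0.05 per group). When both groups pass, the comparison is a
pooled-variance two-sample t with df = n_A + n_B − 2, difference defined as
mean(B) − mean(A) (control minus patient), CI from the t quantile (computed
from the distribution, not a table); Welch is available behind a flag but
the pooled form is the default because it is the one consistent with
published SEs/CIs at these group sizes. Non-normal data route to a
two-sided Mann–Whitney U with the Hodges–Lehmann shift (median of pairwise
differences) and its rank-based CI via the normal approximation to U.

The summaries-only path reconstructs SD = SEM·√n and applies the same
pooled machinery, so `compare_from_summaries(summarize(a)…, summarize(b)…)`
reproduces the raw-data t path to 1e-9. Published "mean ± x" values are
interpreted as mean ± SEM: that is the only reading under which the
published standard errors and CIs are internally consistent with the group
sizes, and it is recorded here as an explicit interpretation.

Direction frequencies are compared with Fisher's exact test on the 2×2
left/right table ("none" calls excluded); a chi-square variant is available
when all expected counts are ≥ 5 and is labelled in the output.

## What the synthetic benchmarks do and do not show

The generator emulates the geometry and photometry that drive the
pipeline's accuracy: disc size, contrast, sub-pixel motion, sensor-like
noise, soft-tissue coupling, lateral-deviation morphology. It does not
emulate skin texture, specular highlights, illumination drift, head motion
(the acquisition protocol fixes the head), occlusions, rolling shutter, or
depth-of-field foreshortening. Passing the recovery grid therefore
demonstrates correctness of the algorithmic chain — detection, tracking,
calibration, feature geometry — under the stated imaging assumptions, not
robustness to uncontrolled clinical video. Group means of patient cohorts
cannot be recomputed without the original videos; the statistics layer is
instead validated exactly against the published summary tables and by
simulation (CI coverage 95% ± 1.5% at n = (44, 37); Fisher vs exhaustive
hypergeometric enumeration to < 1e-10 for all margins ≤ 25).

## Numerical choices and edge cases

- Circularity is clamped to 1 (discretisation can push 4πA/P² slightly
  above it). A zero-perimeter (single-pixel) component counts as circular
  but is excluded by the area gate in practice.
- Otsu thresholding on a strictly uniform frame is undefined; the detector
  returns an empty list instead.
- Two initial-frame candidates at exactly equal height are an ambiguity
  error: with the head fixed, A and B cannot be level.
- A cycle whose profile never moves B beyond the motion threshold raises a
  "no opening event" error; a cycle that does not re-close simply has no
  re-closure index.
- The degenerate all-constant model yields all-zero features with no key
  frames rather than an error, so that symmetry tests can use it.
- Equal-magnitude ties in per-frame maxima resolve to the earliest frame
  (numpy argmax convention).
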