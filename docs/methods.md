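# Methods

## Problem setting

Open cranial vault remodeling for craniosynostosis proceeds through
eleven ordered phases, each defined by the instruments present in the
surgical field:

| Phase | Activity | Right-phase tools |
|---|---|---|
| P1 | Skin incision | Scalpel |
| P2 | Cranial surface exposure | Osteotome, Forceps |
| P3 | Cutting guides placement | SO guide, FT guide |
| P4 | Fixation of registration pins | SO guide, FT guide, Handpiece |
| P5 | Registration | Pointer, SO guide, FT guide |
| P6 | Frontal bone osteotomy | Motor |
| P7 | SO bar bone osteotomy | Motor, Osteotome |
| P8 | Navigation of remodeled bones | Pointer |
| P9 | Screwing | Handpiece, Forceps |
| P10 | Skin placement | Forceps |
| P11 | Suturing | Scissors, Forceps |

Frames are annotated with a 10-bit multilabel vector: the nine tools in
canonical (alphabetical) order followed by `Environment`, which marks
background content (phantom, empty gloved hands) and is never a
right-phase tool.  Recognising the workflow therefore decomposes into
per-frame multilabel classification followed by temporal segmentation
of the detection sequence.

## CranioNet and the training recipe

CranioNet is a from-scratch CNN over 64×64 RGB input: per block, two
3×3 stride-1 convolutions (each followed by batch normalisation and
ReLU), a 3×3 stride-2 max pool, and dropout 0.25; convolutions are
padded (P = 1) only in the first block.  The classifier is a hidden
dense layer with ReLU, batch norm and dropout 0.5, then a dense sigmoid
output — one independent probability per label, never normalised across
labels.  The default configuration uses three blocks with 32/64/128
filters and hidden width 512, the shallowest standard doubling whose
valid-padded spatial trace stays positive from 64×64
(64→64→31→29→27→13→11→9→4).  Block count, filter counts and hidden
width are configurable; an architecture that would collapse below 1×1
is rejected with the offending stage named.

Training minimises mean binary cross-entropy plus a weighted L1 norm of
the convolution and dense kernels (λ default 10⁻⁵ — small enough never
to dominate the data term; biases and batch-norm parameters are not
penalised).  Optimisation is Adam with first-moment decay 0.9,
second-moment decay 0.999 (the conventional value; only the first
moment is part of the published recipe), ε = 10⁻⁸; weights are Xavier
(Glorot-uniform) initialised, biases zero.  The default recipe is
learning rate 10⁻⁴, batch 64, 20 epochs for from-scratch training and
10⁻⁵, 10 epochs for transfer heads.  Validation loss is computed
without augmentation, and all randomness (initialisation, shuffling,
dropout, augmentation) derives from the configured seed, so runs are
exactly reproducible.

Transfer learning wraps any frozen feature extractor: global average
pooling (spatial mean, depth preserved), dropout 0.5, and a dense
sigmoid over the labels — exactly C·L + L trainable parameters for C
backbone channels and L labels.  Tests exercise this path with a seeded
random frozen convolutional backbone rather than downloaded pretrained
weights; the adapter accepts any extractor emitting an (N, C, H, W)
feature map.

The engine underneath is pure numpy: convolutions via im2col + BLAS
matrix products, vectorised max-pool/col2im scatters, and hand-written
backward passes (verified against numeric differentiation).  This keeps
the package dependency-light and deterministic on one CPU; it is not a
GPU substitute, which bounds the problem sizes used in tests.

## Data handling

Training frames live in label-combination folders
(`Environment_Forceps_Osteotome`); tokens are matched case-insensitively
with aliases for prose spellings ("SO guide" → `SOGuide`), and an
optional `.variant` suffix distinguishes folders with equal label sets
(the phantom-only and empty-hands background folders).  Images are
resized to 64×64 and scaled to [0, 1] (the usual convention for
from-scratch networks; per-backbone preprocessing can be slotted in for
transfer models).  The pool is shuffled by seed and split
80:20 — 9,934 frames partition as 7,947:1,987.  Augmentation samples,
per image per epoch: rotation ±15° (the printed "±15 pixels" is read as
degrees, the standard parameterisation of a rotation range), width and
height shifts ±10%, shear intensity ±0.5, zoom ±10%, and a 50%
horizontal flip; out-of-bounds pixels are filled by nearest-edge
replication so no label-correlated borders appear.

## Synthetic scenes

The phantom recordings behind the original study are unpublished, so
the generator emulates their statistical structure: a green surgical
sheet with low-frequency wrinkle noise, a skin-toned phantom ellipse at
the frame edge, one glyph per tool (a distinct polygon and saturated
color, randomly positioned, rotated and scaled), blue-glove ellipses
(free-standing hands drawn under the tools, plus small edge patches
that partially occlude a glyph without hiding it), multiplicative
brightness in [0.65, 1.3] and an optional shading gradient per frame.
Co-present tools are placed on jittered, shuffled quadrant anchors so
every labelled tool stays visible — as in the source recordings, where
hands hold tools side by side.  Each tool's glyph chromaticity is
separable from the background by a simple pixel statistic, which is the
learnability contract the tests enforce.

The default training corpus mirrors the original thirteen video
streams: the eleven phase tool sets (each plus Environment), the
phantom alone, and an empty-gloved-hands variant.  Surgery videos
render a ground-truth `Timeline` (default: 4,920 frames at 15 fps split
evenly over the eleven phases — the true per-phase durations are not
published).  The log simulator bypasses the CNN entirely: per-frame
detections start at the covering phase's tool set, then boundary jitter
(uniform ± jitter frames), per-label flips and whole-frame dropouts are
applied; probabilities are fixed at 0.9/0.1 so thresholding stays
exact.

What the scenes do **not** emulate: photographic texture, 3-D pose,
motion blur, specularity, inter-tool visual similarity (the published
confusions between scalpel and osteotome cannot arise between distinct
glyphs), or realistic class imbalance.  Passing tests therefore
demonstrate that the pipeline's machinery is correct and learnable on
data of this structure — not that the accuracy figures transfer to real
operating-field video.

## Phase estimation

For each phase the binary signal is 1 where the frame's detected set
(Environment ignored) *equals* the right-phase set — presence of every
right tool and absence of every wrong one; a relaxed subset rule is
available behind a flag but is not the default, because tool sets of
different phases nest (P3 ⊂ P4, P8 ⊂ P5) and subset matching would
bleed phases into their neighbours.  Smoothing is a centred moving
average whose window shrinks at the edges, followed by strict
thresholding.

Sequential matching walks the phases in order, accepting for each the
first batch of 1s that extends past the previously accepted batch.
Because each smoothed batch edge is blurred by up to half a window,
consecutive batches routinely overlap by a few frames; a batch is
therefore admissible when it starts no more than ⌊window/2⌋ before the
cursor, while anything ending at or before the cursor is discarded
outright (a re-appearance of an earlier phase's tool set).  The limit
between consecutively detected phases is the half-up-rounded mean of
the adjoining batch end and batch start; the boundary frame belongs to
the earlier phase, the first detected phase keeps its batch start, the
last its batch end.  An undetected phase is flagged and the cursor does
not move — the least destructive policy for a case the original
workflow never exhibits.  Final intervals are always ordered and
non-overlapping.

**Calibration.**  The window (odd, in frames) and the binarisation
threshold θ are the method's two free parameters.  Defaults are
window 15 (one second at 15 fps) and θ = 0.5, appropriate for clean
detections: zero-noise logs recover every boundary within ⌈window/2⌉
frames.  Under per-label flip noise f, a frame matches its own phase
with probability p = (1−f)⁹ (≈ 0.63 at f = 0.05), so θ must sit between
the out-of-phase level (≈ 0.03, from single flips converting one
phase's set into another's) and p, with margin against fluctuations of
the window mean (σ = √(p(1−p)/w)).  The noise-robust setting used in
the tests, window 45 (3 s) and θ = 0.4, puts θ more than 3σ below p and
well above the out-of-phase level, and yields ≥ 85% mean coverage at
f = 0.05 with ±15-frame jitter.  θ above p fragments phases (the
dominant failure mode), θ near the out-of-phase level merges them.

Coverage of a phase is 100·|overlap|/|truth| with inclusive frame
counts, capped at 100; an undetected phase scores 0.

## Evaluation conventions

Per-tool confusion counts give precision, recall, F1 and per-label
accuracy as percentages, reported half-up at one decimal (full
precision is kept internally).  Metrics with a zero denominator are
*not applicable* (`None`/`NA`) rather than 0 or 100, and are excluded
from column averages, so degenerate labels cannot silently corrupt a
table.  Confusion tables can be normalised within the truly-present and
truly-absent partitions (TP% + FN% = 100, TN% + FP% = 100).  The
frame-level score is exact-match accuracy over the full 10-label
vector; it is bounded above by every per-label accuracy.  Per-tool
tables cover the nine tools (Environment is background), while the
exact-match comparison includes Environment.

## Desk-scale problem sizes

The test suite and acceptance script run the full pipeline at sizes
chosen for a single CPU: 13 × 100 = 1,300 training frames (the original
corpus had ~10,000), a width-reduced CranioNet (filters 16/32/64,
hidden 128 — the default 32/64/128/512 architecture is unchanged), and
a desk-scale optimisation recipe of learning rate 10⁻³ with batch 8 for
24 epochs (~3,900 Adam steps).  At 1/8 the corpus and a fraction of the
width, the published step size would leave the optimiser far short of
convergence within any reasonable desk budget, so the desk recipe takes
more, larger steps; the published recipe (10⁻⁴, batch 64, 20 epochs)
remains the package default and is the appropriate setting at the
original corpus size.  `TrainConfig` also exposes an optional per-epoch
learning-rate decay (off by default).  Under the desk conditions
CranioNet reaches ≥ 90% validation exact-match accuracy on the
synthetic corpus (0.94–1.00 across the seeds exercised).
Phase-estimation checks use 3,300-frame timelines (the original test
video had 4,920 frames).

## Known limitations

* The published total of 3,568,714 trainable parameters cannot be
  reproduced exactly: the block count, filter counts and dense width
  that produced it are not stated, and the default architecture here
  (32/64/128, hidden 512) yields a different total.  The parameter
  count is verified instead against layer-by-layer closed forms.
* The published per-architecture transfer parameter counts (tens of
  millions "trainable" with a frozen backbone) are inconsistent with a
  GAP + dense head and are treated as unverifiable; the head arithmetic
  C·L + L is what the package guarantees.
* One published F1 cell (97.0 for a precision/recall pair whose
  harmonic mean is 96.3) is internally inconsistent; worked-example
  checks use only self-consistent cells.
* Phase estimation is post hoc over a complete log; no online/streaming
  variant and no temporal models (HMMs etc.) are provided.
* Tool labels are presence-only: no localisation, pose, or geometry.
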