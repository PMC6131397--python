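# Methods

## The counting problem

A mouse ovary is serially sectioned, stained and digitized; each slide
carries several (typically 7–8) sections, and a specialist clicks every
primordial follicle (PMF) — an oocyte with a visible nucleolus surrounded
by a single layer of flattened granulosa cells — recording one point per
follicle. `pmfcount` replaces the visual search with a two-stage detector:
a convolutional patch classifier trained on frames around those clicks,
applied exhaustively to each section through a half-overlapping sliding
window.

## Pipeline stages and their parameters

### Section isolation (`preprocessing`)

The slide is reduced to one luminance value per pixel (ITU-R BT.601
weights 0.299/0.587/0.114; only contrast, not hue, carries the follicle
signal) and binarized, by default with Otsu's criterion (parameter-free;
a fixed threshold is available). Contours are found on a further
4×-downsampled mask — border following on a low-resolution image is both
faster and less distracted by intra-tissue detail — and each outer
contour above a minimum area (default 0.5% of the slide) becomes a
bounding box, expanded by a margin (default 2% of the box diagonal),
merged with any box it then overlaps, and cropped. Crops carry their
slide-frame offsets so click coordinates, which are stored at full
resolution, can be mapped into any crop (`to_section_coords`). A coverage
check warns about any annotation that lands in no crop: section isolation
must never cost a follicle.

### Patch dataset (`dataset_builder`)

* **frame_size** (default **48 px** at the synthetic working resolution):
  the frame is constant for all follicles and sized to always contain one —
  the largest synthetic PMF (30 px oocyte + granulosa ring) spans ≈ 42 px.
  Oversizing the frame is not harmless: the detection window equals the
  frame, and greedy non-maximum suppression keeps one frame per adjacent
  cluster, so a window much larger than the object merges neighbouring
  follicles into one cluster and silently caps recall. For ~1 µm/px real
  slides, 96–128 px is the analogous choice.
* **Negatives**: centers sampled uniformly (seeded) at least `min_dist`
  (default one frame) from every annotated follicle of any class, so no
  negative accidentally shows a follicle.
* **Augmentation**: each positive yields the original, the 7 non-identity
  symmetries of the square (rotations and reversals), and 4 seeded random
  translations of up to 25% of the frame, re-cropped from the parent
  section. The translation range is deliberately about half the sliding
  stride: at detection time a follicle can sit up to stride/2 = 12 px
  off-center in the best window, and the classifier must score those
  windows as positives too — that is precisely the failure the half-overlap
  is meant to absorb.
* **Balance**: training negatives are subsampled (seeded) to
  `ceil(neg_pos_ratio × positives)`, ratio 1.0 by default. Splits are by
  ovary, never by patch, so augmented siblings of one follicle cannot leak
  across the split.
* Border patches are padded with the section median intensity to keep
  frames constant-size.

### Classifier (`cnn_classifier`)

A VGG-style stack: blocks of 3×3 convolutions (same padding) + ReLU, a
max-pool per block, one fully-connected ReLU layer with dropout, and a
2-way softmax head. Two presets ship:

| preset | blocks (n_conv, kernel, filters) | pool | fc | dropout |
| --- | --- | --- | --- | --- |
| `tiny` | (1, 3, 8) | 4 | 32 | 0.25 |
| `vgg-small` | (2,3,32), (2,3,64), (2,3,128) | 2 | 128 | 0.5 |

`tiny` is the workhorse for the synthetic benchmark: the planted objects
are separable by local contrast patterns, and it trains in about a minute
on one CPU. The whole numerical stack — im2col convolution, first-argmax
max-pooling, inverted dropout, backpropagation, and the Adadelta update
(ρ = 0.95, ε = 1e-6, the method's customary values; Adadelta needs no
learning rate) on categorical cross-entropy with mini-batches of 32 — is
implemented in numpy with seeded determinism; gradients are verified
against finite differences in the test suite. Dropout is disabled at
inference, so prediction is a pure function of the weights.

Reference implementations of the two defining equations are exposed
directly: the single-neuron response `σ(Σ wᵢxᵢ − b)` (ReLU or sigmoid) and
the max-subtracted softmax.

### Detection (`detector`)

Windows the size of the training frame are enumerated row-major with
stride = window × (1 − overlap), overlap 0.5 by default; a final
row/column is added flush with the far edge so every pixel is covered
(interior pixels by ≥ 4 windows). Each window is scored by the classifier
in fixed-size chunks (chunking affects memory only; scores agree across
chunkings to the last few ulps). Windows with follicle probability ≥ the
threshold survive; the default threshold 0.15 is intentionally low — the
design favours recall and lets hard-negative mining clean up precision —
and is surfaced in every report. Greedy non-maximum suppression then
repeatedly takes the highest-probability remaining detection (ties broken
by frame (y, x), lexicographic, for reproducibility), keeps it, and
discards every remaining detection adjacent to it. Adjacency defaults to
"shares ≥ 1 pixel" (frames are half-open boxes); an IoU-threshold rule is
available by configuration.

### Hard-negative mining (`hard_negative_mining`)

One round by default. The current detector runs on a dedicated mining
slide set, disjoint from both training and test ovaries; every retained
detection whose frame contains no ground-truth click is collected as a
forced negative (tag `hnm`). Retraining keeps all positives and all mined
negatives, fills the negative budget `ceil(ratio × positives)` with a
seeded subsample of the original negatives (if the mined patches alone
exceed the budget they are all kept and the originals dropped, with a
warning), and **continues from the existing weights** rather than
restarting. Expected behaviour, reproduced on the synthetic benchmark:
precision rises, recall dips slightly.

### Evaluation (`evaluation`)

A retained frame is a true positive (TP) iff it contains ≥ 1 ground-truth
click — point-in-frame containment is the only matching criterion
available when the ground truth is a click per follicle. Recall counts
follicles: a frame holding two follicles contributes two found follicles
(but one TP frame), and a follicle covered by several TP frames counts
once, so found ≤ real always. Precision counts frames: TP/(TP+FP). True
negatives are defined by subtraction, TN = total windows − TP − FP, which
is how the published accounting balances. The operator-focus correction
models the expert re-review of false positives: each confirmed follicle
moves one frame from FP to TP and adds one follicle to both the found and
the real tallies, so recall becomes (found+m)/(real+m) — never a decrease —
and precision strictly increases for m > 0.

Percentages are rounded half-away-from-zero to two decimals. Fed the
published counts (1,667 real follicles; 2,875,160 windows; 14,053 → 949
false positives; 185 reclassified), the module returns the published
metrics: recall 99.46% → 90.40% → 91.36%, %FP 0.49%, %TN 99.45%,
corrected precision 65.69%. Two published figures are *not* reproducible
from the published integer counts and are deliberately not special-cased:
the phase-II/III %FP/%TN (0.044%/0.037%) do not follow from FP = 949/764
over 2,875,160 windows, and no integer TP yields exactly 57.38% precision
with FP = 949 (1,278 — the value consistent with the corrected 65.69% —
gives 57.39%). The module always reports its own self-consistent
percentages.

## The synthetic data and what it does (not) show

`synthetic_data` emulates the geometry and contrast of the real material,
not its histology: 8-bit grayscale slides, background ≈ 230, elliptical
sections of textured stroma ≈ 150 placed on a jittered grid (serial
sections sit in rows on a real slide; the grid guarantees disjointness),
follicles drawn as a pale oocyte disc (≈ 205, diameter 18–30 px) with a
single dark nucleolus dot and a tangential ring of small elongated dark
nuclei (≈ 60), plus three distractor families — solid dark blobs, pale
discs with only a partial granulosa arc, and bare pale discs — none of
which shows the complete template (full ring + interior dot), so ground
truth is unambiguous. Follicle centers keep ≥ 1.5× the maximum diameter
apart (an `allow_pairs` mode plants closer pairs to exercise the
two-follicles-per-frame rule); distractors keep ≥ 1 maximum diameter from
everything. Gaussian noise (σ = 4) is added last. Per-slide seeds derive
from the master seed, and regeneration is byte-identical.

Default study conditions (the "desk scale"): 1024×1024 slides, 4 sections,
5–15 follicles and 10–30 distractors per section; the pipeline default
corpus is 4 training, 2 mining and 2 test slides, `tiny` architecture,
12 training epochs + 6 retraining epochs. A full run takes a few minutes
on one CPU.

Passing the synthetic benchmark shows that the *machinery* is correct —
training converges, the window/NMS bookkeeping balances, mining improves
precision without collapsing recall, everything is seed-reproducible. It
does **not** show field performance: real H&E tissue has stain variation,
touching and atretic follicles, sectioning artifacts and far subtler
distractors (primary follicles differ from primordial only by granulosa
morphology), and real corpora are ~10⁶ windows per ovary, three orders of
magnitude beyond the synthetic test set.

## Numerical choices and edge cases

* Seed fanout: every stage seed derives from the master seed through
  independent `SeedSequence` spawn keys; all seeds stay below 2³¹.
* NMS ties (equal probabilities) and box sorting are resolved
  lexicographically; suppression is greedy (not cluster-transitive),
  matching the three-frame illustration of the method.
* Thresholding uses ≥, so threshold 1.0 keeps only probability-1.0
  detections and 0.0 keeps everything.
* Max-pooling routes gradients to the first maximum in each window;
  dropout uses inverted scaling so inference needs no correction.
* Degenerate inputs raise typed errors rather than propagating NaN:
  empty softmax input, zero metric denominators, frames larger than the
  image, out-of-bounds crop boxes, infeasible negative sampling (the
  error reports the achieved count).
* Zero training epochs return the model unchanged; an empty detection
  list yields a report with zero counts and "undefined" metrics flagged
  in the table.

## Known limitations

* Binary classification only: primary/secondary/antral clicks are carried
  through the annotation schema but used only as exclusion zones for
  negative sampling, never as positive classes.
* Single-scale windows; no multi-resolution pyramid.
* The numpy trainer is CPU-bound and fits desk-scale corpora; the `vgg-
  small` preset on millions of patches would need hours, not minutes.
* The synthetic generator draws no color and no staining gradients, so
  color-normalization questions are out of scope by construction.
* MRXS containers, pyramidal WSI servers and DICOM are not read; slides
  must arrive as plain single-plane TIFF.
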