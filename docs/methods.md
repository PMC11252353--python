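# Methods

## The measurement model

Fluorescence polarization of a stained cell is quantified from a pair of
co-registered emission images, detected parallel (`I_co`) and
perpendicular (`I_cross`) to the excitation polarization:

    Fpol = (I_co − G · I_cross) / (I_co + G · I_cross)

`G` is a dimensionless instrument constant correcting the polarization
bias of the detection path; the default 0.75 matches the confocal system
this pipeline was designed around. Inputs are 8-bit grayscale images
(TIFF or PNG), nominally 1000 × 1000 pixels spanning a 205 µm field, i.e.
0.205 µm/pixel; repeated frames may be averaged (`average_frames`, kept
at floating precision until write time). For each segmented cell the two
channel means are taken over the cell's *valid* pixels — counts within
[3, 254] in **both** channels, excluding background (< 3) and saturation
(> 254) — and Fpol is the ratio of those means ("Fpol of means"). A
per-pixel variant (mean of per-pixel Fpol) is available behind a flag for
sensitivity analysis; the two agree exactly on uniform regions. Validity
is evaluated jointly across channels so both means always use the same
pixel set. A cell whose valid fraction falls below 50% (configurable) is
retained but flagged `excluded`, since its Fpol would rest on too few
pixels. Cell area is `|pixels| · pixel_size²` in µm².

## Segmentation

A standard U-Net with five resolution levels (configurable ≥ 2): per
level two 3×3 same-padded convolutions + ReLU; 2×2 max-pooling between
encoder levels; feature widths 16, 32, 64, 128, 256 by default; a
mirrored decoder with 2×2 stride-2 transposed-convolution upsampling and
skip concatenation; a 1×1 convolution onto three classes with a softmax
head. Input is the co/cross pair scaled by 1/255. The three output
classes mirror the annotation scheme: background, *ambiguous* cell-like
signal (cells the annotator did not select — out of focus or of uncertain
diagnostic relevance), and *high-quality* cells (the diagnostically
relevant ones that feed Fpol). The ambiguous class exists to absorb
cell-like pixels that would otherwise surface as false-positive
high-quality cells.

Training is fully supervised, per-pixel cross-entropy with equal class
weights, Adam (default learning rate 1e-3), batch size 4, with online
augmentations drawn fresh each epoch from a seeded generator: flips,
rotation (±180° by default), scaling (0.8–1.2), shearing (±10°), random
cropping, and optional elastic deformation (off by default — it is not
clearly class-preserving for this imagery). Label masks are always
resampled with nearest-neighbour interpolation. He initialization is
seeded, so two builds with the same seed are parameter-identical and a
training run is exactly reproducible. No normalization layers are used;
for the shallow, low-contrast-variance imagery involved, seeded He
initialization plus Adam trains stably without them. Inference has no
stochastic layers, so prediction is deterministic for a fixed checkpoint.
Checkpoints are self-describing `.npz` files embedding the architecture
config.

The network, backpropagation (verified against central finite differences
to ~1e-9 relative error in float64) and Adam are implemented directly on
NumPy: convolutions are im2col + BLAS matmul in float32, which on the
desk-scale images used here trains in minutes on one CPU core. Input
spatial dimensions must be divisible by 2^(levels−1); other sizes are
rejected with padding guidance rather than silently resized.

## Post-processing

The high-quality probability map is binarized at 0.5 (a pixel exactly at
0.5 is foreground — the tie rule is frozen so tests can be exact), then
cleaned by a fixed morphological chain: dilation with a 3×3 square
element for 3 iterations (closes gaps up to ~6 px), the mirroring erosion
(3×3, 3 iterations) to restore boundaries, and a morphological opening
with a 15×15 elliptical element — the discrete filled ellipse with
semi-axes 7 — which removes spurious clusters smaller than a plausible
cell. Pixels outside the image are background for every operator. Cells
are then labeled by 8-connected component labeling (8-connectivity avoids
splitting cells along diagonal boundaries), with labels assigned in
raster-scan order of each region's first pixel so labeling is
deterministic. The test suite checks the whole chain bit-exactly against
brute-force set-definition implementations (dilation as a union of
translates, erosion via translate intersection, flood-fill labeling).
Touching or overlapping cells merge into one component; no watershed
splitting is attempted — under-segmentation of clusters is a known
limitation of the approach, not a removable artifact of this
implementation.

## Automated-vs-manual comparison

Automated (AU) and manual (MA) label masks of the same field are paired
greedily by descending pixel overlap; a candidate pair must overlap by
more than 50% of the smaller region's area, each id may be used once, and
ties break by smaller AU id then MA id, so the pairing is deterministic.
The threshold and rule are configurable; the defaults favour recall of
genuine correspondences while remaining one-to-one. Matched pairs get
symmetric percent differences `100 (x_AU − x_MA) / ((x_AU + x_MA)/2)` for
Fpol and area (AU first, so negative area differences mean the automated
region is smaller); the sample summary reports mean ± SD Fpol per method
over *all* cells, not only matched ones, plus the selection excess
`100 (N_AU − N_MA) / N_MA`. Report rounding is one decimal, half away
from zero.

## Statistics

Cells are grouped by diagnosis (malignant / benign / normal) × method
(AU / MA); summaries use the sample SD (n−1). A single-cell group reports
SD 0 with a warning rather than failing, keeping degenerate phantom runs
total. AU-vs-MA comparisons on matched cells use paired two-tailed
Student t-tests; between-diagnosis comparisons, where no correspondence
between cells exists, use unpaired pooled-variance tests — "paired
everywhere" is not well defined across disjoint cell sets, so pairing is
used exactly where a correspondence exists. All comparisons reported in
one run form the Bonferroni family (flag_i = p_i < α/m, α = 0.01, m =
family size, configurable). Normality is assumed, not tested.

## The phantom generator

The generator fabricates what the microscope would produce, with known
ground truth. High-quality cells are elliptical blobs (semi-axes drawn
from `cell_radius_range`, random orientation) with a smooth dome profile
and a brighter nuclear core (MB is a nuclear stain, so nuclei dominate
emission); the co-channel peaks near `base_co_intensity` (default 160
counts, comfortably inside the valid band). The cross channel is derived
pixel-wise by inverting the polarization relation,
`i_cross = i_co (1 − f) / (G (1 + f))`, so each cell's true Fpol is exact
before quantization; because the inversion is a per-cell constant ratio,
Fpol-of-means over the truth mask is exact to machine precision when
quantization is disabled, and within 0.01 after round-half-up 8-bit
quantization. A `cluster_fraction` (default 0.25) of cells is placed
adjacent/overlapping an earlier cell to exercise the merging limitation;
the rest are kept separated so components stay countable. An additional
`round(ambiguous_fraction · n_cells)` ambiguous cells (default fraction
0.25) are rendered dimmer and Gaussian-blurred (σ = 3 px), emulating
out-of-focus cells; they populate only the ambiguous mask. Background
sits at a constant 1 count — inside the < 3 exclusion band, so the
background threshold is exercised — plus optional Gaussian noise
(default SD 2 counts). Per-cell Fpol targets default to uniform draws
from 0.10–0.33, the range observed for thyroid cells; class-conditional
draws use malignant ≈ 0.28, benign ≈ 0.17, normal ≈ 0.18 (SD 0.02).
No published intensity statistics exist for the real images, so these
levels are realistic choices, not calibrations.

What the phantoms do **not** emulate: chromatin texture, the microscope's
point-spread function, polarized-optics physics, uneven illumination, or
annotation disagreement between experts. Passing phantom tests therefore
demonstrates that the pipeline's machinery is correct and self-consistent,
not that the trained network would reach the same accuracy on clinical
images.

## Problem sizes and numerical choices

The test suite trains the default 5-level, base-16 network once on twenty
128 × 128 phantoms (five cells each, noise SD 2) for 15 epochs with mild
augmentation (±15° rotation, 0.9–1.1 scale, ±5° shear, flips) — a
desk-scale stand-in for the full-resolution experiment — and requires
mean Dice ≥ 0.8 for the high-quality class on held-out noiseless
phantoms; in practice it reaches ≈ 0.9. Morphology equivalence is checked
on 100 random 64 × 64 masks; type-I-error calibration of the unpaired
test uses 1000 null simulations. 1000 × 1000 inputs are supported
throughout (inference plus post-processing plus quantification for one
such pair takes seconds on one CPU core); only training at that
resolution is out of scope for the test suite.

Degenerate inputs are handled explicitly: zero valid pixels or a zero
intensity sum → cell excluded (Fpol NaN); empty label mask → empty cell
list; empty training set, empty manifest, empty frame list, empty p-value
list → rejected; paired t-test with zero-variance differences → degenerate
result with a warning (t = 0, p = 1 when the sequences are identical).

## Known limitations

* Touching cells merge (no instance splitting).
* The quality of trained models on real cytology is untested here; the
  phantom domain is much easier than FNA imagery.
* The NumPy trainer is single-process and CPU-bound; full-resolution
  training is possible but slow.
* Group-level tests treat cells as independent, ignoring patient
  clustering (Fpol has been reported not to be patient-specific, but the
  assumption is inherited, not verified).
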