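# Methods

## Problem setting

Brain metastases treated with stereotactic radiosurgery (SRS) are monitored on
serial MRI: a contrast-enhanced T1-weighted (T1c) and a T2-FLAIR volume at
baseline and at each follow-up. Response assessment follows the RANO-BM
criteria, which act on each lesion's longest diameter (LD): shrinkage (CR/PR)
when the LD drops by more than 30% versus baseline, enlargement (PD) when it
rises by more than 20% versus the nadir (the smallest LD recorded so far,
baseline included), steady (SD) otherwise. A lesion with no enlargement is
locally controlled (LC); a first enlargement is arbitrated by the next scan —
a further increase of more than 1 mm (absorbing measurement error) confirms
local failure (LF), while stabilisation or shrinkage flags an adverse
radiation effect (ARE) with the lesion remaining LC. LC/LF and ARE are
tracked independently, so an ARE lesion can convert to LF later.

`metseg` implements this monitoring pipeline end to end: a two-stage
segmentation cascade (a whole-volume *locator* followed by a lesion-centred
*segmenter*), the rule-based outcome automaton, the evaluation metrics, and a
synthetic longitudinal phantom generator that makes every stage testable at
desk scale.

## Segmentation network

Both cascade networks share one U-shaped architecture. The encoder embeds
non-overlapping 2x2x2 voxel patches into an E-dimensional token space
(default E = 72) and runs four stages of pre-norm transformer blocks; each
stage ends in a 3x3x3 stride-2 convolution that halves every grid axis and
doubles the channel count, so stage t carries E*2^t channels on a grid of
ceil(H / 2^(t+1)) per axis. Inside each block, self-attention is restricted
to a sliding M x M x M neighborhood (default M = 7): for a token at (i,j,k)
the attention scores are the dot products of its query with the keys of its
n = M^3 neighbors plus a learnable relative-position bias indexed by the 3D
offset, scaled by 1/sqrt(d) with d the per-head dimension, softmax-normalised
and applied to the stacked neighbor values. Near the grid border the window
is shifted (clamped) to stay in-grid so every token has exactly n neighbors;
where a deep stage's grid is smaller than M the window shrinks to the grid
(attention becomes global there). Because neighborhoods are defined by
relative offsets, the operator is translationally equivariant away from
borders — the property the test suite checks directly against an
explicit-loop oracle.

The decoder mirrors the hierarchy with residual blocks (depthwise 3x3x3
convolution, instance normalisation, pointwise projection, residual
shortcut), kernel-2 stride-2 deconvolution upsampling, and concatenation with
the earlier-stage skip at every level, including a full-resolution 3x3x3
convolutional projection of the raw input; a 1x1x1 convolution with softmax
produces per-voxel class probabilities. The Dice loss is computed on the
tumor probability channel: L = 1 - 2*sum(G*P)/(sum(G^2)+sum(P^2)).

Choices the architecture description leaves open, fixed here: two transformer
blocks per stage (configurable), pre-norm block composition with an MLP of
expansion 4 and GELU, per-head dimension fixed at 24 (so heads = stage dim /
24 and the softmax scale is constant across stages), and d in the 1/sqrt(d)
scale read as the per-head dimension, as in standard multi-head practice.
Odd deep-stage grids use ceiling division (the stride-2 pad-1 convolution's
natural behaviour) and the decoder crops each upsampled map to its skip's
shape, so any even input size is legal.

### Numerical substrate

No deep-learning framework ships with this package's environment, so the
network runs on a small reverse-mode automatic-differentiation core written
for the purpose (`metseg.nn.tensor`): a define-by-run graph over float32
NumPy arrays with the operators the architecture needs. The hot inner loops
(depthwise convolution, fused norm+affine, GELU, the per-neighbor score and
output contractions) are JIT-compiled with numba; dense contractions go
through BLAS, and neighbor gathers through sparse matrices. Gradients of
every composite operator are verified against central differences in the
test suite, and the attention operator against a brute-force evaluation.

## Two-stage cascade

Per session, the locator's tumor probability map (oracle or network) is
binarized at 0.5; 26-connected components with at least `min_voxels` voxels
(default 2, rejecting single-voxel noise) become lesion ROIs ordered by
component size. Each ROI defines a fixed-size crop (128^3 at full scale,
configurable; shifted inward at borders) over (T1c, FLAIR, probability map),
which the segmenter refines. Within a crop, the segmenter's output is
restricted to the connected component at the ROI's seed so co-cropped lesions
stay independent; per-lesion masks are fused into the full grid by logical
OR. Lesions are cross-checked against the previous session by greedy
nearest-first one-to-one matching of ROI centers within 10 mm (ties to the
lower id); unmatched previous lesions are carried forward at their old
coordinates and still segmented, so a vanished tumor is reported with LD 0 —
the distinction between complete disappearance (CR) and shrinkage to a small
remnant (PR). A carried-forward ROI segments after the detected ones and may
not claim voxels already assigned to another lesion, which prevents a
vanished lesion from inheriting a neighbor's mask. The continuous probability
map (not the binarized mask) is the third segmenter channel.

## Metrics

Per-lesion evaluation reports the Dice similarity coefficient (percent; 100
when both masks are empty), the full symmetric Hausdorff distance between
surface-voxel sets in mm (undefined, hence an error, for empty masks), the
volume estimation error in cc, and the longest diameter. LD is measured
in-plane: the maximum over the three orthogonal slice families of the maximum
pairwise voxel-center distance within a single slice, matching the clinical
plane-based measurement; an empty mask has LD 0 (the CR convention) and so
does a single voxel, which is flagged. Size strata (small <= 1 cm, medium
1-2 cm, large > 2 cm) are assigned from the baseline LD.

## Synthetic phantoms

The generator emulates the serial-MRI setting, not anatomy: a smooth
low-frequency background on an ellipsoidal "brain" support (zero outside,
as after skull-stripping), Gaussian noise (sd 0.05 of the unit background),
and 1-10 axis-aligned ellipsoidal enhancing lesions (contrast 2.0 on T1c)
with axis ratios in [0.7, 1] and longest diameters of 2-56 mm following
prescribed per-session scale factors. Geometry derives deterministically from
the spec seed, so repeated calls are bit-identical and sessions are mutually
co-registered; only noise varies between sessions.

Lesion centers snap to voxel centers and the semi-axis along the longest axis
snaps to a whole voxel count, so the rendered in-plane LD is exactly twice
the snapped semi-axis and within one voxel spacing of the prescribed
diameter, while the mask never extends beyond the realized ellipsoid. The
series' ground-truth LDs are measured from the rendered truth masks (the
prescribed values are kept alongside): the rendered lesion is what any
segmenter — oracle included — can recover, so labelling from it keeps the
end-to-end recovery experiment well-posed rather than hostage to sub-voxel
rounding at the 30%/20% thresholds. Ground-truth status/outcome labels come
from the same automaton applied to that noiseless series.

Cohort trajectories are drawn from clinically-shaped patterns (sustained
shrinkage, disappearance, stability, confirmed progression, transient
ARE-like enlargement) with progression steps sized so the 1 mm confirmation
is satisfied in absolute terms. A margin statistic reports how close a
series sits to the 30%/20%/1 mm decision boundaries; threshold-adjacent
series are scored separately since sub-voxel error can legitimately flip
them.

What passing desk-scale tests does **not** show: robustness to anatomy,
registration error, scanner drift, cystic or resected lesions, or realistic
lesion texture — the phantoms have none of these by design.

## Training

The optimisation recipe: AdamW with initial learning rate 1e-4, weight decay
1e-5 and second-moment coefficient 0.99 (the recipe's "momentum", read as
beta2 with beta1 left at 0.9), batch size 1, up to 300 epochs with a linear
warm-up (5 epochs by default; the warm-up length is not prescribed) into
cosine annealing to zero, early stopping on validation Dice loss, and
flip/rotation/intensity augmentations applied identically to channels and
mask (spatial) or channels only (intensity). Training is bit-reproducible
given the config seed on one device.

The desk-scale learning experiment trains a tiny configuration (E = 24, one
head, depth 1 per stage, M = 3) on 20 synthetic 48^3 phantoms with 5 held
out, for at most 60 epochs at learning rate 1e-3 — scaled up from the
full-size recipe in proportion to the far smaller model — and stops once
held-out DSC reaches its target. It typically exceeds 90% DSC within 3-5
epochs; problem sizes throughout (48-64^3 grids, 32-48^3 crops, cohorts of
100-200 lesions) are chosen so the whole study runs on a single CPU in
minutes.

## Time-to-event comparison

Per-lesion LF (and ARE) detection times — follow-up indices, or calendar
days when a manifest provides them — feed Kaplan-Meier product-limit
estimates via lifelines, with non-events censored at the last follow-up. The
log-rank test compares the automated and reference assessments' curves; in
the synthetic study the two assessments coincide, so the statistic is 0 and
p = 1 by construction, which the acceptance script recomputes.

## Degenerate inputs and tie-breaks

Empty probability maps yield empty ROI lists (not errors); empty masks yield
DSC 100 (both empty) or 0 (one empty), LD 0, and an error for the Hausdorff
distance. Status thresholds are strict inequalities ("more than"), and
"stable" after an enlargement means an increase of at most 1 mm. An
enlargement on the final scan cannot be arbitrated and leaves the LC/LF
outcome indeterminate — forcing it into either class would fabricate a
confirmation the data does not contain. Equidistant lesion matches go to the
lower previous id; equal-size components order by first label.

## Known limitations

The full-scale configuration (512x512x200 grids, E = 72, M = 7, 128^3
crops) is supported by the same code paths but is not exercised by the test
suite, which runs everything at desk scale. The CPU autodiff core is
single-device; there is no mixed precision or multi-GPU path. Registration,
skull stripping and DICOM ingestion are out of scope — inputs are assumed
co-registered, skull-stripped NIfTI volumes. Patient-level composite
response (multi-lesion RANO) and volumetric response criteria are not
implemented.
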