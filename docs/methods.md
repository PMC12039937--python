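# Methods

## Problem and pipeline

Fractured pelves are segmented from CT in three steps. Step 1 isolates the
three target bones (sacrum, left and right hipbone) with a coarse-to-fine
cascade of two 3D UNets: the first runs on a low-resolution copy of the scan
(2x the working spacing) for context, the second refines at full resolution
with the coarse one-hot labels concatenated to the CT as extra input
channels. Step 2 crops each detected bone to its bounding box (default
margin 8 voxels), replaces voxels of *other* bones with a soft-tissue
baseline (0 HU by default), z-scores the crop, and runs the fracture
network, which assigns each voxel to background, the *main* fragment (the
large central piece a reduction robot would manipulate) or *minor*
fragments (everything else). Step 3 removes the main fragment, enumerates
the now-isolated minor pieces by 26-connected component analysis, drops
components smaller than 1 cm^3 (volume = voxel count x voxel volume from
the spacing), and pastes everything back into a full-grid instance map.
The 1 cm^3 filter applies only to minor components; the main fragment is
never removed. Ids are assigned after enumeration, in decreasing volume
order, and re-compacted after the filter.

## The fracture distance map and the weighted loss

The contact fracture surface (CFS) is where voxels of different fragment
labels meet within one structuring-element neighbourhood (26-connectivity
by default, reach one voxel, `contact_radius_mm` configurable). The
fracture distance map gives every foreground voxel its distance to the
nearest CFS voxel,

    D(v)  = 1[Y_v >= 1] * min_{u in CFS} ||v - u||_2,
    D^(v) = D(v) / max_V D(v),

and the loss weight follows a reversed logistic ramp,

    W(v)  = lambda_back + 1[Y_v >= 1] * (1 - lambda_back) / (1 + exp(lambda_FDM * D^(v) - 5)),
    W^(v) = W(v) * |V| / sum_V W(v),

so the CFS neighbourhood carries weight close to 1, far-away foreground
decays toward `lambda_back = 0.2`, and normalization keeps the mean weight
at 1 so loss magnitudes are comparable across samples. The constant 5 in
the exponent is a fixed offset (it centres the ramp at D^ = 5/lambda_FDM);
it does not scale with lambda_FDM.

Both loss terms consume the same weights:

    L_dice  = 1 - (2/|L|) sum_l (sum_v W^ P Y) / (sum_v W^ P + sum_v W^ Y)
    L_ce    = -(1/(|V||L|)) sum_v sum_l W^ Y log P
    L_total = lambda_dice * L_dice + lambda_ce * L_ce        (both 1 by default)

with probabilities clipped at 1e-7 before the log and an additive 1e-5
smoothing both the Dice numerator and denominator (guards the 0/0 of
absent classes; the value is small enough to move a loss by < 1e-4).
The Dice average runs over *all* classes including background by default
(`class_set` restricts it if needed).

Deep supervision attaches a softmax head to every decoder level except the
bottleneck. Level n is supervised with 2x-downsampled (nearest-neighbour)
labels, weights recomputed from those downsampled labels — the ramp is
nonlinear in D^, so averaging full-resolution weights would be wrong — and
lambda_FDM halved per level (16, 8, 4, 2 at four heads). Per-level losses
combine with nnU-Net-style coefficients 2^-n normalized to sum 1.

The smooth transition blends the all-ones weight matrix J into W^ as
training proceeds:

    W_st = J                                      t < tau_begin
         = J/(1+delta) + W^ delta/(1+delta)       tau_begin <= t <= tau_begin + tau_smooth
         = W^                                     t > tau_begin + tau_smooth
    delta = -ln(1 - (t - tau_begin)/tau_smooth + eps),   eps = 1e-6

so early training sees the plain loss (global shape) and late training the
FDM-weighted loss (fracture surface). `t` counts epochs by default
(iterations configurable); the defaults tau_begin = 0, tau_smooth = 1000
suit a 2000-epoch schedule, and the desk-scale profile rescales tau_smooth
to half its epoch count so the hand-over still completes. The transition
applies identically at every supervision level.

Open conventions resolved here: distances are measured in physical mm
(`units="voxel"` switches to index space — with anisotropic spacing the mm
form keeps the CFS band isotropic); the weight-normalization domain is the
whole patch (background carries lambda_back and the cross-entropy needs
it; `domain="foreground"` is available).

## Network and training

The backbone is a plain 3D UNet: per level two (3^3 conv, instance norm,
leaky ReLU) stages, 2x max-pooling down, nearest-neighbour upsampling and
skip concatenation up, channel width doubling from `base_channels` (cap
128). It is implemented in numpy with hand-written backpropagation; the
3^3 convolutions run as numba-compiled direct loops (the gradient w.r.t.
the input is computed as a forward convolution with the channel-swapped,
spatially flipped kernel). Training uses Adam (lr 1e-4 full-scale profile,
exponential decay 0.99/epoch, batch 2) and is bit-reproducible given the
seed in single-threaded execution.

Augmentation applies one shared spatial transform to image and labels
(rotation up to +-30 degrees, translation +-20 mm, anisotropic scaling
80-120 %, image interpolated linearly, labels nearest) and image-only
intensity transforms (Gaussian blur 0.5-1.0 with probability 0.15,
brightness and contrast 75-125 %, gamma 0.7-1.5). The fracture network
additionally mirrors along all three axes, and — on isotropic grids — may
apply exact axis-permutation rotations, which cheaply cover the full
octahedral symmetry group. Augmented copies are generated on the fly
rather than materialized (equivalent in distribution, cheaper on disk).

Two profiles exist. `full`: five levels, 2000 epochs, five-fold
cross-validation — the full-scale configuration for clinical data; not
exercised by the test-suite. `tiny`: four levels, 8 base channels, 24^3
patches, tens of epochs, lr 3e-3 — the desk-scale configuration used for
phantoms throughout the tests and the verification script.

Patch sampling centres a patch on a foreground voxel with probability
`foreground_oversample_p` (default 0.5; the desk-scale fracture study uses
1.0 so the whole bone stays in view) and uniformly otherwise. Inference
slides a Gaussian-blended window, optionally averaging over all eight
mirror flips (test-time augmentation); the anatomical cascade runs stage 1
at 2x spacing and feeds its upsampled one-hot output to stage 2. The
stage-2 cascade network trains teacher-forced: the coarse-label channels
come from the ground-truth labels (one-hot, following the same spatial
augmentation), not from a trained stage 1.

## The phantom generator

Phantoms stand in for fractured-pelvis CT at desk scale. A scene holds 1-3
axis-aligned ellipsoidal bones (semi-axis defaults 14/11/12 mm, jittered
+-20 % per bone) with a 2 mm cortical shell (distance-to-surface band)
around a trabecular interior, placed without overlap in a sacrum-centre /
hipbones-left-right layout. Intensities: cortical 1200+-100 HU, trabecular
300+-80 HU, soft tissue 40+-20 HU, global noise sd 15 HU — plausible adult
CT values. Each bone is cut by a plane through a random orientation, bent
by 2-3 low-frequency sinusoidal harmonics (amplitude 2 mm) so the fracture
surface is irregular; the minor side targets 15-35 % of the bone volume.
Four appearances map to what fractured pelves show:

- `displaced_gap`: the minor fragment translates >= 3 mm (3-6 mm, with a
  small rotation) — a wide empty gap;
- `stable_gap`: the minor-side contact layer is carved away — a one-voxel
  dark gap, fragments disjoint but close;
- `crease`: no label gap; a dark crease line is rendered over only 40-80 %
  of the cut cross-section (fragments stay connected, part of the surface
  is invisible — the hardest appearance);
- `compression`: the minor fragment moves 1-3 mm *into* the main one;
  overlap voxels belong to the main fragment (the central piece) and
  render brighter (maximum of two draws — density pile-up).

Every instance is kept 26-connected: slivers split off by displacement
trimming are merged back into the main fragment (crushed material), or
dropped for displaced fragments; a displaced fragment colliding with
another bone is trimmed in scene composition (earlier bones keep their
voxels). All outputs are pure functions of (spec, seed); minor fragments
respect a 0.5 cm^3 floor so the 1 cm^3 post-processing filter can be
exercised from both sides.

What the phantoms do *not* model: real pelvic anatomy (ring topology,
cortical thickness variation), scanner physics (beam hardening, metal,
slice profiles), soft-tissue organs, osteoporotic texture. Passing the
desk-scale studies therefore shows the *machinery* — losses, weighting,
training loop, post-processing, metrics — behaves correctly and that the
training system can learn fracture appearances from images; it does not
certify clinical accuracy.

## Evaluation suite

DSC is 2|A∩B|/(|A|+|B|) with the both-empty convention 1. Surfaces are
border voxels (6-connectivity to the complement); distances are
centre-to-centre in mm. HD95 is the 95th percentile (linear interpolation)
of the *pooled* symmetric distance multiset — the directed-max variant is
config-switchable; ASSD is its mean. A label present in ground truth but
missing from the prediction scores the diameter (HD95) and radius (ASSD)
of the ground truth's circumscribed sphere: maximum pairwise distance
between border voxels plus one voxel footprint (`max(spacing)`), so a
single voxel has diameter `max(spacing)` — exact up to 5000 border voxels,
convex-hull-reduced above. LDSC restricts both masks to within 10 mm
(physical) of the *ground-truth* CFS before computing Dice; with no CFS it
falls back to the global DSC. Minor instances are matched to ground truth
by maximal voxel overlap, larger ground-truth instances first. Reports
aggregate mean +- sd per metric plus the median HD95; paired two-tailed
t-tests compare methods (identical samples return t = 0, p = 1; a
zero-variance non-zero difference is flagged as degenerate).

## Desk-scale verification studies

The verification script and the acceptance tests train real networks, but
at problem sizes a single CPU can handle:

- *End-to-end fracture study*: single-bone phantoms on a 40^3 grid at
  1.4 mm isotropic spacing (the bone then fits a 24^3 patch, so the
  network always sees the whole bone and the main-vs-minor size cue stays
  decidable), 16 training and 4 held-out bones drawn from crease and
  compression scenes, `tiny` nets trained 40 epochs with mirror +
  axis-permutation augmentation, mirror test-time augmentation at
  evaluation, three seeds, an FDM-weighted and a uniform-weighted arm per
  seed. Reported: per-seed held-out mean foreground DSC (mean of the main
  and minor Dice, the nnU-Net convention) for the FDM arm, and the
  per-seed LDSC comparison between arms. At this training scale the
  networks resolve the bone-versus-background boundary essentially
  perfectly but underfit the exact cut-surface placement, which bounds the
  per-class foreground Dice well below what full-scale training reaches;
  the FDM-versus-uniform comparison is the informative readout.
- All other checks (distance/metric oracles, normalization identities,
  constants, schedule contract, ground-truth post-processing) are exact
  and run in seconds.

## Known limitations

- The numpy/numba backbone is single-threaded and CPU-bound; the `full`
  profile is structurally faithful but not practical without porting the
  layer kernels to a GPU framework.
- Ellipsoid phantoms lack the thin, curved cortical plates where real
  anatomical networks fail; anatomical-stage results on phantoms are
  easier than on clinical data.
- The crease appearance leaves 20-60 % of the cut surface invisible by
  construction; segmentation across the invisible part is genuinely
  ambiguous and bounds achievable held-out minor-fragment Dice on
  phantoms.
- Geodesic (within-bone) distances are not implemented; the FDM uses
  Euclidean distance, which can cross the background between fragments.
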