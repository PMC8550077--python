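# Methods

## Problem and model

`ppaseg` segments parapapillary atrophy (PPA) — the crescent- or ring-shaped
chorioretinal thinning adjacent to the optic disc seen in high myopia — in
fundus photographs. The segmenter is an encoder–decoder network with three
feature-expression-enhancement blocks around a five-level encoder pyramid
f1..f5 (level *i* at 1/2^i of the input resolution):

- **Edge attention** on f2 (stride 4): two 3×3 conv+BN+ReLU stages reduce f2
  to a 32-channel contour feature `e_att`; a 1×1 projection yields an edge
  logit map S_e supervised by the lesion-boundary map with binary
  cross-entropy. f2 is used rather than f1 because it still carries fine
  contours at a quarter of the compute.
- **Parallel partial decoder** over f3–f5: each level is reduced to 32
  channels (1×1 conv+BN) and fused top-down multiplicatively — coarser maps
  are convolved (3×3 conv+BN), bilinearly upsampled, and multiplied into the
  finer ones — then the three maps are upsampled to the f3 grid, concatenated
  and projected to the global logit map S_g. Low-level features are excluded
  from this fusion on purpose: they are expensive and add little to a coarse
  localization map.
- **Cascaded reverse attention**, three stages at levels 5 → 4 → 3. Each
  stage forms A_i = 1 − σ(resize(S_higher)) — attention on what the coarser
  prediction has *not* yet claimed — multiplies it into the 1×1-reduced
  encoder feature, concatenates the mean-pooled `e_att`, and adds a
  1-channel correction (two 3×3 conv+BN+ReLU stages, 1×1 projection) onto
  the resized coarser logits. The stage-5 input map is S_g; the final
  probability map is σ(upsample(S_3)).

The identity A_i + σ(resize(S_higher)) = 1 holds exactly by construction and
is asserted in the tests at every stage.

### Backbones

Three encoder families are interchangeable behind `BackboneSpec`:

- `vgg`: plain 3×3 conv stacks (with batch normalization) tapped at the five
  max-pool outputs, canonical widths (64, 128, 256, 512, 512), VGG-16 stage
  depths (2, 2, 3, 3, 3);
- `resnet`: 7×7/2 stem + max pool + four stages of two basic residual
  blocks, widths (64, 64, 128, 256, 512);
- `res2net`: same layout with hierarchical-residual bottlenecks, widths
  (64, 256, 512, 1024, 2048), scale 4, base group width 26.

Level strides are fixed to /2…/32 (the standard pretrained-stem convention);
this puts f2 at /4, where the edge branch operates. Grayscale input is
replicated to three channels before the stem. In the res2 block, group 1
passes through unchanged (the cheaper published convention; `group1_conv`
switches it), and a stride-2 block mean-pools the mid feature before the
split so the hierarchical additions stay aligned; `scale=1` degenerates to a
plain 1×1/3×3/1×1 bottleneck. Stage depth is two blocks per stage — enough
to express the hierarchy while keeping CPU forward passes cheap — and is
configurable (`blocks_per_stage`).

Pretrained weights are an optional load from a local `.npz` state dict;
nothing is downloaded, and all shipped defaults use seeded random
initialization, so results are reproducible offline. Encoder weights are
fine-tuned (not frozen) during training.

### Numerical core

The network runs on a small reverse-mode automatic-differentiation engine
over NumPy float32 arrays (`ppaseg.nn`): convolution is computed as a sum of
k² strided GEMMs (one per kernel offset), which keeps peak memory at one
feature map instead of a full im2col buffer; bilinear resampling uses the
align-corners=false convention with an exact scatter-add adjoint; batch
normalization keeps running statistics (unbiased variance in the buffers);
max pooling backpropagates through stored argmax indices. All gradients are
verified against central finite differences in the test suite. Everything is
CPU-only and bit-reproducible for a fixed seed.

## Loss

Per side output the segmentation loss is a boundary-weighted soft IoU plus a
boundary-weighted BCE, with per-pixel weights

    weight = 1 + 5 · |AVG(B) − B| ∈ [1, 6],

where AVG is a same-size sliding-window average of the ground-truth mask B
(kernel 31×31, stride 1, padding 15, zero padding counted in the mean; the
kernel is configurable but must satisfy k = 2p + 1 so the output size is
unchanged). The weight is large in a band around the lesion boundary — the
"complex" pixels. The gain 5 is a fixed default (`weight_gain`).

Two conventions required a decision:

- **Weighted IoU.** A literal weighted Jaccard with denominator
  |A∪B|·w − |A∩B|·w is zero at a perfect prediction, so the ratio is
  undefined exactly where the loss should vanish. We use the structure-loss
  convention: with inter = ΣW·P·B and total = ΣW·(P+B),
  L = 1 − (inter+1)/(total−inter+1), which is bounded, smooth, and exactly 0
  for a perfect binary prediction. The +1 smoothing terms match this
  reading.
- **Weighted BCE.** The "divide by weight" normalization is read as the
  weighted mean Σ(W·ℓ)/ΣW; an element-wise division would cancel the
  weighting entirely. With W ≡ 1 it reduces bit-for-bit to plain mean BCE.

BCE terms clamp probabilities to [1e−7, 1 − 1e−7] before logarithms. BCE
reduction is the mean over pixels by default (keeping the five total-loss
terms at commensurate scale across resolutions); the summed form is
available via `reduction="sum"`.

The total training objective upsamples every side output to ground-truth
resolution and sums

    L_total = L_seg(G_s, S_g↑) + L_edge(G_e, S_e↑) + Σ_{i∈{3,4,5}} L_seg(G_s, S_i↑),

i.e. deep supervision of the global map, the edge branch, and the three
reverse-attention outputs. The three cascade stages are indexed by pyramid
level (S_5, S_4, S_3) so the sum over i = 3..5 is literal; the finest
refined map S_3 provides the final prediction.

Exhaustive small-grid checks (all 256 binary 2×2 pairs; all 3×3 masks with
every single-pixel corruption) confirm the weighted IoU vanishes iff the
prediction equals the mask and that the segmentation loss is monotone under
corrupting a correct pixel.

## Synthetic data

The generator (`ppaseg.synth`) emulates the screening-relevant appearance
cues of myopic fundi: a bright circular disc (radius drawn from
`disc_radius_range`), an adjacent crescent of intermediate brightness whose
radial width tapers cosinusoidally to zero at the ends of a
`crescent_angular_span` arc and peaks at `fraction × papilla diameter`
(fraction from `ppa_width_fraction_range`), dark quadratic vessel curves
radiating from the disc, band-passed "leopard fundus" speckle, a mild
vignette, and a global Gaussian blur. Default fractions (0.12–0.75) straddle
the small/large boundary of one third so both strata are populated; the
canvas default is 352 px, matching the network's native input size.

Ground truth is exact by construction: the lesion mask is the rasterized
crescent (always disjoint from the disc), the edge map is its 1-pixel inner
morphological boundary (mask minus erosion by the 3×3 cross iterated
`thickness` times, border treated as background), `ppa_width` is the
realized maximal radial extent of mask pixels beyond the disc rim, and the
papilla diameter is twice the disc radius (and equals the maximal disc-mask
chord, measured exactly via the convex hull when only the mask is
available). A lesion is "small" iff ppa_width ≤ papilla_diameter/3 —
maximal radial extent is the clinically described crescent width, one
admissible reading of lesion "size" relative to disc diameter.

What the generator does **not** model: photorealistic color and texture,
pigmentation inside the atrophy, camera optics, disease progression, or
annotation noise. Passing tests therefore demonstrate that the pipeline is
implemented correctly and can learn this class of geometry from images —
not clinical-grade performance on real fundus photographs.

Dataset splitting is a seeded uniform permutation at an exact integer ratio
(default 4:1, half-up rounding), so 360 samples give exactly 288/72.

## Training and evaluation

Training minimizes the total loss with Adam (default learning rate 1e−4, no
schedule, 50 epochs, batch 8 — common practice for this architecture family;
all configurable). No augmentation is applied by default. Training aborts
with a per-term diagnostic if the loss goes non-finite. Checkpoints store
the full state dict plus the config and round-trip bit-exactly.

Evaluation reports precision, sensitivity, specificity, pixel-ROC AUC
(midrank Mann–Whitney, via scikit-learn), IoU and DSC, per stratum
{all, small, large}. Defaults: binarization threshold 0.5; per-image (macro)
averaging, with pixel-pooled counts available via `average="pooled"`; AUC is
computed per image and averaged, and single-class images are skipped for
AUC and counted in an exclusion tally. Degenerate denominators are defined
as 1.0 (an all-negative prediction on an all-negative image is vacuously
correct). DSC = 2·IoU/(1+IoU) holds per image by construction.

## Problem sizes used in tests and the acceptance script

Unit and acceptance tests run tiny configurations: 64×64 images, pyramid
widths (8, 8, 16, 24, 32), batches ≤ 4. The acceptance script additionally
runs one 352×352 forward for each backbone at canonical widths, a
200-step single-image overfit (reaching DSC ≥ 0.95), and a 25-image
train/evaluate cycle (100 epochs). At that data scale a generalization gap
is expected and observed (train DSC ≈ 0.86 vs test DSC ≈ 0.62 at seed 1);
the per-stratum numbers reproduce the qualitative pattern that large
lesions are segmented better than small ones. These sizes are the package's
own desk-scale defaults; larger runs only require changing the config.

## Known limitations

- CPU-only NumPy execution: throughput is far below a GPU framework;
  the design favors correctness, determinism and zero heavy dependencies.
- The adaptive mean pooling used to inject the edge feature into the
  cascade supports integer isotropic factors only (always the case for the
  /4 → /8, /16, /32 pyramid).
- The final prediction is upsampled from the 1/8-resolution S_3 grid, so
  boundary precision is bounded by that grid: very thin lesions (a few
  pixels of radial width at a 64×64 canvas) cannot be delineated to high
  Dice no matter how long the model trains. The overfit check therefore
  uses a lesion thick enough for the output grid to express (disc radius
  13 px, width fraction 0.7 at 64×64).
- Convolution depth inside each enhancement block is two 3×3 stages — an
  inventory-faithful minimal choice; deeper blocks are not exposed.
- The synthetic generator's realism limits (above) bound what test metrics
  say about clinical data.
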