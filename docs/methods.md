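# Methods

`aecvision` simulates an active binocular vision system in which a
perceptual representation, a vergence controller, and a saccade generator
develop jointly under a single objective: encode the binocular input as
well as possible.  This note documents the model, its parameters, the
synthetic environment, and the numerical and design choices a maintainer
would want to know.

## The model

**Environment.**  Eye movements are emulated in 2-D on a rectified stereo
pair.  A fixation is a point `(x, y)` in the left image plus a horizontal
shift `d` (the analogue of the vergence angle); the right fovea sits at
`(x − d, y)`.  Scenes are stacks of textured fronto-parallel planes at
integer disparities over a full-frame background; the renderer shifts each
plane's texture by its disparity, resolving occlusions near-over-far, and
produces a dense ground-truth disparity map `D(x, y)`.  The *retinal
disparity* at a fixation is `d − D(x, y)`; zero means the two foveal
windows are aligned.  Simulations run in 10-frame fixations separated by
saccades; the shift carries across saccades unchanged; the scene is
regenerated every 30 fixations.

**Perceptual representation (GASSOM).**  Each scale's input window is cut
into 10×10 patches; corresponding left/right patches are normalised to
zero mean/unit variance per eye and concatenated into 200-d binocular
vectors.  A bank of N two-dimensional orthonormal subspaces encodes each
vector; the response of feature n is the squared projection length
`r_n(x) = ‖Φ_nᵀx‖²` — the subspace analogue of a binocular-energy complex
cell.  Learning assigns each patch softly to subspaces,
`h_n ∝ exp(r_n/2σ_e²)·prior`, where the prior puts mass ω on the patch's
previous winner (temporal slowness) and is uniform otherwise, then rotates
every subspace toward its responsible patches:

    ΔΦ_n = Σ_j h_{n,j} · x̃_{j,n} (x_jᵀΦ_n) / (‖x̂_{j,n}‖‖x_j‖),
    Φ_n ← orthonormalize(Φ_n + λ ΔΦ_n)

with `x̂` the projection and `x̃ = x − x̂` the residual.  Columns are
re-orthonormalised by two-column Gram–Schmidt after every step because the
energy reading of `r_n` requires orthonormal bases, which the raw update
does not preserve.

**Vergence control.**  The state is the 3N-vector of per-feature mean
responses over the patch grid at three scales (coarse/medium/fine windows
of 4w/2w/w pixels, each bicubically down-sampled to w×w).  A linear
softmax actor (temperature 1) chooses among the 11 pixel actions
{−16, −8, −4, −2, −1, 0, 1, 2, 4, 8, 16}.  The reward is the negative
cross-scale mean reconstruction error, so verging onto a surface (which
makes the binocular input representable by disparity-tuned features)
is rewarded.  Learning is a natural actor-critic: a linear TD(0) critic
produces the TD error δ; compatible features ψ(a, r) = (1_a − π) ⊗ r; the
natural-gradient weights w are regressed toward δ along ψ; the actor steps
θ ← (1 − κ)θ + α_a w.  The small decay κ bounds the logits: without it the
integrated actor saturates the softmax onto a single action and
exploration dies.  Updates occur only on within-fixation transitions
(9 per fixation), never across saccades.

**Saccade control (BAIM).**  At the coarse scale of the whole-image
aligned pair, every stride-1 patch gets a saliency equal to the summed
Shannon self-information of its feature responses over a random 25-feature
subset: each response map is min-max normalised, a histogram with one bin
per context patch estimates the response law, and
`S_n = −ln(α + (1−α)h_n(bin))` with floor α = 10⁻⁶.  The *global* variant
(GBAIM) estimates histograms over all patches; the *local* variant
(LBAIM) over a 31×31 patch neighbourhood of the current fixation, which
makes salience fixation-dependent: patches unlike the currently fixated
region — in texture or in depth — score high.  The coarse map is
zero-padded, upsampled ×4, multiplied by an inhibition-of-return mask
(Gaussian notches of σ = 20 px and 10 px at the last two fixations) and a
valid-margin mask, normalised, and sampled to pick the next fixation.

## Scales and default parameters

Two geometry profiles exist, differing in one knob, the fine-window side
`window_base` (w):

| profile | frames | w (windows 4w/2w/w) | N | patches/scale |
|---|---|---|---|---|
| desk (default) | 320×240 | 25 (100/50/25) | 64 | 16 |
| full | 640×480 | 55 (220/110/55) | 324 | 100 |

The full profile is the configuration of record (it gives the 972-d
pooled feature vector); the desk profile makes a complete joint-training
comparison run in minutes and is used by the test suite and the
reproduction script.  Note the full-scale windows plus the ±40 px shift
require frames of at least 300×220, which is why the desk profile shrinks
the windows along with the frame.

Key defaults (all in `RunConfig`, all serialised into checkpoints):

- λ = 0.02 with linear decay to 0.1·λ over the run.  Desk runs last
  ~10⁴ frames; slower rates leave the bank immature within that horizon.
- σ_e = 0.2, ω = 0.5 (responsibility sharpness and slowness stickiness).
- γ = 0 (within a 10-frame fixation the task is nearly a contextual
  bandit; a zero horizon cuts TD variance and measurably improves the
  learned policy at desk scale), α_critic = 0.05, α_actor = 0.3, actor
  decay κ = 0.002, all held constant through the run — most policy
  learning happens late, once the representation has matured, so
  annealing the RL rates hurts.  The
  reward passed to the learner is E_avg divided by the patch energy
  2·10² (a monotone rescale keeping TD magnitudes O(1)), and pooled
  features enter the networks as per-feature running z-scores scaled by
  1/√dim; both are required for critic stability at these rates.
- Saliency subset size 25, redrawn per map; histogram bin count equal to
  the number of context patches (configurable — near-singleton bins make
  individual feature maps noisy, which depresses subset-vs-full
  correlations but none of the qualitative results).
- Shift clamped to ±40 px, the support of the truncated-Laplacian
  disparity law P(d) ∝ exp(−|d|/D) used by the controlled-statistics
  training protocol.

## The synthetic environment, and what it does not emulate

Textures come from five families: broadband 1/f noise (`pinknoise`),
oriented sinusoids (`gratings`), overlapping discs (`deadleaves`),
constant (`flat`), and a weak heavily low-passed `smooth` family spanning
few intensity levels.  Scene heterogeneity is essential, not cosmetic:
the saccade mechanism can only matter if informativeness varies across
the image.  In an all-pinknoise world every fixation is equally
informative and random saccades train vergence just as well — we verified
that the saccade-policy ordering disappears in that regime.

Two degenerate regimes bound the choice of background, and they pull in
opposite directions:

- Patch vectors are normalised to unit variance per eye, so feature
  responses — and with them the self-information saliency — are blind to
  texture *contrast*: a weak texture looks identical to a strong one
  after normalisation (measured saliency maps on `smooth` backgrounds
  are flat to within a few percent).  Saliency only sees *degeneracy*:
  patches below the contrast floor map to the zero vector, share one
  histogram bin, and that bin's high probability marks them as boring —
  the mechanism that makes texture-free walls unsalient to an
  information-maximising observer.
- Exactly flat regions, however, have zero reconstruction error at any
  vergence angle, so during reinforcement learning they act as spurious
  reward maxima: a policy can "succeed" by shifting its window onto
  blank ground.  Joint training on flat-background scenes measurably
  corrupts the vergence policy.

The defaults therefore split by protocol: *joint training* uses pinknoise
objects over a `smooth` background (low-information but non-degenerate —
"harder to learn from", not "rewarding to stare at"), while the
*fixation-entropy* and *disparity-difference* protocols, which probe the
saliency map rather than the reward, use textured objects over `flat`
ground where the saliency contrast is well defined.

The generator does not emulate: perspective or 3-D rendering (planes are
fronto-parallel and disparity is constant per plane), vertical disparity,
photometric left/right asymmetries, natural-image statistics beyond
second order, or scene motion.  Passing tests therefore show that the
mechanisms interact as described on scenes with controlled disparity and
entropy statistics — not that the system is robust to natural video.

## Evaluation protocols

- **Policy RMSE**: fronto-parallel test scenes at initial disparities
  −20…20 px, 10 vergence commands, RMS of the residual retinal disparity
  (default 100 textures per disparity; the reproduction script uses
  fewer — see its header — which widens its seed-to-seed spread).
- **V curve**: reconstruction error vs imposed retinal disparity on test
  scenes, fit by f(d) = c − a·exp(−|d−μ|/b); the sharpness a/b is the
  slope at the minimum.  Representation-only training under the
  Laplacian disparity law uses all-pinknoise scenes at zero scene
  disparity so the imposed disparity is exact.
- **Fixation entropy**: 256-bin Shannon entropy of the fine windows at
  policy-chosen fixations, median over fixations, L/R averaged.  This
  protocol runs on 640×480 frames with objects of 0.25–0.4 frame
  fraction: the coarse saliency patches have a 40 px support and the ×4
  upsampling blurs object borders by roughly ±20 px, so object interiors
  must dominate the borders or fixations sampled "onto" an object land
  on texture-free ground next to it and the median collapses.
- **Expected disparity difference**: exact expectation of |D_i − D_j|
  over the IOR-free target distribution, averaged over uniformly drawn
  current fixations (assumed fused, shift = D there), normalised by the
  random-policy value.
- **Within-fixation error decrease**: (E_start − E_end)/E_start per
  fixation, running average; fixations with E_start = 0 are excluded and
  counted.

## Numerical choices and degenerate inputs

- Bicubic interpolation (reflect boundaries) for all down/up-sampling;
  interpolation overshoot in upsampled saliency is clamped at 0.
- Patches whose monocular std is below 10⁻⁶ are flagged low-contrast:
  normalised by a clamped std (a constant patch becomes the zero
  vector), excluded from bank updates, included in error averages.
- A constant response map min-max normalises to all zeros (one occupied
  bin, zero self-information).  A saliency map that is zero everywhere on
  the margin falls back to a uniform target distribution, logged.
- Response ties in best-subspace selection and greedy action ties break
  to the lowest index.  Histogram bin of a response exactly 1.0 is the
  closed top bin.
- All randomness flows from one master seed through named substreams
  (scenes, bank init, action sampling, saccade sampling, feature
  subsets, evaluation), so different saccade variants train on identical
  scene sequences and the whole pipeline is bit-reproducible.

## Known limitations

- The actor-critic details (γ, rates, critic form, decay) are this
  package's instantiation of the cited algorithm family; published values
  do not exist for them.
- Desk-scale runs (~10³ fixations) are two orders of magnitude shorter
  than the developmental simulations they miniaturise; absolute errors do
  not transfer, and the saccade-policy RMSE ordering, while present in
  the mean over replicate seeds, has a seed-to-seed spread of several
  pixels — a single three-seed comparison at an arbitrary seed can fail
  to separate the variants.
- The local-variant entropy advantage depends on scene composition (see
  above); with objects larger than the local context the effect inverts.
- Subset-vs-full saliency correlations with an untrained bank are low
  (~0.3 at 25 features); trained feature banks correlate better but the
  monotone growth with subset size is what is asserted.
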