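# Methods

## Model and procedure

A finger-vein class is represented by binary codes extracted from its
images by a binary-pattern operator. The matching currency is the code, not
the image: similarity between two images is similarity between their codes.

**Operators.** LBP emits, per interior pixel, eight bits s(i_n − i_c) over
the 3×3 neighbours with s(x) = 1 iff x ≥ 0 (the equality case deliberately
maps to 1). The neighbour order is fixed: start at the top-left neighbour,
clockwise. LLBP emits, per pixel whose line fits in the image, N−1 bits
along the horizontal line and N−1 along the vertical line of odd length N
(default 21), comparing each line pixel to the centre; the full LLBP code
is the horizontal code followed by the vertical code. Bits within a line
are ordered by ascending line position, skipping the centre. Both
orderings are arbitrary conventions; Hamming-type distances are invariant
to any fixed choice, and the choice is recorded in each code's
`operator_tag` so codes from different conventions can never be compared.
Pixels whose kernel or line would leave the image are skipped rather than
padded: padding invents intensities and would perturb exactly the per-bit
stability that training measures. The decimal LBP view and the LLBP
magnitude √(LLBPh² + LLBPv²) (with 2^(|offset|−1) positional weights) are
diagnostics only; matching always uses the concatenated binary codes.

**Weight-map training.** With k ≥ 2 training codes and m₁ ones / m₀ zeros
at bit i, the per-bit stability is p_i = (m₁² + m₀²)/k², the average of the
k×k pairwise XNOR matrix *including* self-matches — the closed form only
equals the double sum under that inclusion, which is why the implementation
uses the closed form and the tests validate it against the literal double
sum. The weight is w_i = 2p_i − 1. Consequences worth knowing: weights are
quantized to a finite set determined by k (at k = 2 only {0, 1}; at k = 8
{0, 0.0625, 0.25, 0.5625, 1}), and if a bit is 1 independently with
probability π per capture, its trained weight converges to (2π − 1)² as
k → ∞. A single training code is refused: it carries no stability
information. The best-bit mask (PBBM) marks bits with w_i = 1 exactly; an
all-disagreeing training set yields an empty mask, which is returned with a
warning and refused at match time.

**Matching.** Weighted similarity S = 1 − Σw·xor/Σw uses the *enrolled*
class's map, making the score asymmetric in principle; in verification a
pair (x, y) with x from class A's test set in the enrolled role is scored
with W_A, and in identification each template is scored with its own
class's map. Acceptance is strict (S > threshold). EER computation sweeps
all observed score thresholds, so the strictness convention only fixes
which side of a tie each rate counts.

## Evaluation protocols

Verification: genuine scores are all unordered pairs among each class's
first n_test_all test samples; imposter scores pair each class's first
n_test_imposter test samples with every other class's first n_test_imposter
(ordered class pairs, both directions), giving C·C(n,2) and C(C−1)·m²
scores. FAR(t) is the fraction of imposter scores > t, FRR(t) the fraction
of genuine scores ≤ t, swept over the union of observed scores plus one
anchor below the minimum; EER and the FRR@0.1%FAR / FAR@0.1%FRR operating
points are linear interpolations on that curve. Linear interpolation was
chosen as the conventional, reproducible reduction; the swept ROC is
emitted in full (far, frr, threshold) so any other reduction can be
recomputed from the CSV.

Identification: one template per class (test sample at a configurable
index, default 0 for reproducibility; random choice is available through
the seeded splits), remaining test samples are probes. Ties in similarity
are resolved pessimistically — a probe's rank is the worst position
consistent with ties — which is deterministic and conservative. The CMC is
the cumulative fraction of probes recognized within each rank; the lowest
perfect rank is the first rank at which it reaches 1.

Random-split robustness: each repetition draws an independent uniform
k-subset per class for training (all randomness from one seed via spawned
`SeedSequence` children, so runs are exactly reproducible) and reports
min/max/mean/variance of the EER (sample variance for more than one
repetition). The training-size sweep fixes the last n_test samples as the
test set and trains on the first k, for each k, running all three matchers
over identical score pipelines.

## Synthetic data

**Code populations.** Each class gets a uniform random template; each
sample flips template bit i independently with that bit's flip probability
— q_low for a fraction f_stable of positions, q_high for the rest. Defaults
(20 classes × 16 samples, 384 bits, f_stable = 0.25, q_low = 0.10,
q_high = 0.5) were chosen analytically so the three matchers separate the
way heterogeneous bit stability predicts: a stable bit survives the
all-of-k constancy test of best-bit training with probability
0.9¹⁰ + 0.1¹⁰ ≈ 0.35, which exceeds f_stable — the regime where best-bit
matching beats plain Hamming (the effective signal-to-noise ratio of
best-bit matching relative to plain scales as √(survival/f_stable)) — while
graded weighting beats both; and 384-bit codes give enough per-comparison
variance (σ ≈ 0.026 on the imposter side) that genuine and imposter score
distributions overlap, keeping EERs in a realistic few-percent range
instead of saturating at zero. What this generator does *not* emulate:
spatial correlation between bits (neighbouring pixels share edges),
capture-session effects (all samples are exchangeable), and imposter
structure (templates are independent, so imposter similarity is centred at
0.5); conclusions about absolute error rates on real imagery do not follow
from it — only the relative behaviour of the matchers does.

**Vein images.** A bright elliptical "finger" on a dark background, with
veins rendered as smooth random curves (cubic splines through jittered
control points, stroked via a distance transform and lightly blurred)
darker than the finger by `contrast`; per sample, a random translation
(sd `warp_sd` pixels) and Gaussian pixel noise (sd `noise_sd`) are applied.
This reproduces the two properties the method needs — dark curvilinear
structure and intra-class geometric consistency — and nothing else; it is
not a photometric or anatomical simulation.

## Preprocessing choices

ROI: Otsu threshold, largest connected component, tight bounding box —
deterministic and parameter-free; constant or degenerate frames fall back
to a central 75% crop with a logged warning, so the chain never raises on
pathological input. Resampling is bilinear; gray normalization is a global
min–max stretch to [0, 1] (idempotent, rank-preserving, affine-invariant),
with constant images mapped to 0.5. The normalized size defaults to
height 96 × width 64 and both are configurable, as is skipping ROI
detection entirely for pre-cropped datasets (`--pre-cropped`). No vein
enhancement filtering is applied before encoding.

## Numerical and storage details

Codes are bit-packed (`np.packbits`) with an explicit logical length;
Hamming distances use byte-wise XOR + popcount (pad bits XOR to zero), and
weighted similarity unpacks on demand. Template files (`<class>.pwm` +
JSON sidecar) store the enrollment codes, best-bit data and the weight
vector as little-endian float32; training computes in float64, so saving
rounds weights to float32 — the file round-trip is byte-exact, and the
~1e-8 relative weight perturbation is far below any score resolution the
protocols can detect. Weight training uses exact integer bit counts, so
trained weights are exact rationals in floating point up to a single
division.

## Problem sizes in the default test run

The suite runs entirely on generated data: operator oracle checks up to
30×30 images, the combinatorics check at the full 136-class scale with
16-bit codes, the method-ordering experiment at 20 classes × 16 samples ×
384 bits, and weight-recovery at k = 2000 samples × 512 bits. The whole
suite completes in a few seconds on one CPU; the sizes were picked as the
smallest at which each property is comfortably away from its sampling
noise floor.

## Known limitations

The asymmetric similarity is used as specified, but no score normalization
across classes is applied, so identification across classes with very
different weight-mass totals relies on the raw scores being comparable.
One template per class; multi-template fusion is out of scope. The ROI
procedure is a generic bright-blob detector, adequate for the synthetic
frames and for clean transmitted-light captures, not a tuned finger
segmenter; real datasets with reliable cropping should use
`--pre-cropped`.
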