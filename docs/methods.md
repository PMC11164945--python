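# Methods

## Scope and design

The package is an end-to-end, in-process simulation of a two-site federated
learning (FL) study on ultrasound-based steatosis detection. A networked
deployment (server plus site processes) is replaced by a deterministic round
loop — broadcast, local training at every nonempty site, weighted
aggregation, server update, evaluation — behind the same algorithmic
interfaces, so every quantity of the study (partition arithmetic,
heterogeneity metrics, aggregation algebra, evaluation statistics, and the
qualitative orderings between training setups) is computable and testable on
a laptop-class CPU.

## Synthetic cohort

The cohort generator emulates a dual-center population. Patient counts per
site and steatosis grade are configuration constants, never sampled:
private-like 35/51/29/38 and public-like 17/20/8/10 patients for grades 0-3
(208 patients, 52 S0 / 156 ≥S1). Demographics are sampled per site from
truncated normals (age ≥ 18 years, BMI ≥ 15 kg/m²) with means/SDs of
52±13 / 40±9 years and 30.8±8.0 / 45.9±5.6 kg/m², and sex from
Bernoulli(male fraction 0.49 / 0.20). Demographics exist for manifest
realism only; the classifier never sees them. The whole cohort, images
included, is a pure function of the configuration (including its seed).

## Image model

Each image is synthesized as

    I(r, c) = gain_site · (base + slope_e · grade) · S(r, c) · exp(−(a0 + slope_a · grade) · depth(r))

clipped to [0, 255] and quantized to 8 bits, where `S` is a spatially
correlated Rayleigh speckle field: two independent Gaussian white-noise
fields smoothed with a Gaussian kernel (correlation length `speckle_scale`
pixels), combined as a magnitude, and normalized by the *theoretical*
Rayleigh mean of the smoothed field. Normalizing by the theoretical rather
than the per-image empirical mean is deliberate: it preserves the natural
image-to-image fluctuation of mean brightness, which is the dominant noise
source at the image level and keeps the classification task non-trivial.

Parameter defaults (all configurable):

| parameter | default | rationale |
|---|---|---|
| base echogenicity | 80 intensity units | mid-gray liver parenchyma at grade 0 |
| echogenicity slope | 15 units/grade | fatty liver is hyperechoic; gives a clear but noisy grade signal |
| base attenuation | 0.5 /depth | baseline posterior signal loss |
| attenuation slope | 0.3 /depth/grade | posterior attenuation steepens with steatosis, largely offsetting the brightness gain in the deep half |
| speckle scale | 3 px | speckle cell size at the rendered resolution |
| site gain | 1.0 private-like, 1.2 public-like | different scanners/presets at the two centers produce a brightness domain shift independent of grade |

The attenuation/echogenicity combination is chosen so the *overall* mean
intensity is only weakly grade-dependent while the shallow-half mean rises
clearly with grade: class information lives in the depth profile, not in a
single global brightness value. The per-site gain makes source-based
partitioning a genuine domain-adaptation problem: a model trained on one
site's brightness scale transfers imperfectly to the other, which is what
gives multi-site (federated or centralized) training its advantage over the
single-center baseline — the mechanism the study design is about.

What the generator does *not* model: anatomical structure (organs, vessels,
diaphragm), scanner-specific artifacts, probe geometry (sector vs linear),
operator variability, or biopsy-timing effects. Passing tests therefore
demonstrate correctness of the FL machinery and the *direction* of
distributional effects, not clinical performance levels on real ultrasound.

## Partitioning and heterogeneity

All strategies operate on patients (all of a patient's images move with the
patient) and assert exact multiset conservation of the input pool on every
call. Fractional allocations become integer counts by largest-remainder
(Hamilton) apportionment with ties to the lower site id — order-independent
and total-conserving. Empty sites are structurally allowed (a Dirichlet draw
or a single-origin pool can produce them), flagged in the heterogeneity
report, excluded from the cosine metric (undefined on zero vectors), and
skipped by the round loop.

The imbalance scenario first fixes the global composition (largest-remainder
split of the total between classes at the requested S0 fraction, so 10% of
84 gives 8), then builds per-site class-count targets as a pinned
single-class portion of weight 1−α plus an IID portion apportioned by the
global distribution, reconciling the totals so the global set is conserved
exactly. Counts are deterministic given (α, S0 fraction, total); the seed
only selects which patients fill them. Pinned classes cycle by site index
(site 0 → S0, site 1 → ≥S1, ...), configurable.

## Local training and the model family

Because model weights are the unit of exchange in FL, the classifier is
implemented directly on numpy with manual backpropagation: weights are
ordered named tensors with elementwise algebra, and server algorithms are
pure functions on them. The family has two members with identical structure
conventions: a VGG16-style stack (13 conv layers, 128×128×3 input, sigmoid
scalar output) preserving the full-scale configuration, and a tiny
three-conv-block network (8/16/32 channels, dense head) for desk-scale
experiments. Initial weights are Glorot-uniform per layer from a shared
seed, so every site and the server start from identical weights. A
finite-difference gradient check (relative error ≤ 1e-4 on a small dense
network, float64) guards the backpropagation.

Local training: focal loss (γ = 2, class weight α = 0.25 — the standard
focal-loss defaults, since the study protocol fixes only the loss family),
Adam (β = 0.9/0.999; learning rate 1e-4 at full scale, 1e-3 in the tiny
profile where the parameter count is four orders of magnitude smaller),
batch size 32, horizontal flips (p = 0.5) and ±15° rotations at train time.
FedProx adds μ(ω − ω_global) to every gradient step; μ = 0 reduces exactly
to plain training. The Adam state is fresh per round (each round's local
session is an independent optimization), and per-(trial, round, site) seeds
are derived through a counter-based scheme so runs are bit-reproducible.

## Server algorithms

FedAvg aggregates by sample-size weights n_i/n. FedAvgM maintains server
momentum on the pseudo-gradient Δ_t = ω^{t−1} − ω_FedAvg; FedYogi uses the
opposite sign convention Δ_t = ω_FedAvg − ω^{t−1} with an adaptive second
moment υ^t = υ^{t−1} − (1−β₂)Δ_t²·sign(υ^{t−1} − Δ_t²); both conventions
are implemented exactly as specified per algorithm, with sign(0) = 0. The
FedYogi second moment is initialized to τ² elementwise so √υ + τ is
well-conditioned at the first update. Server hyperparameter defaults follow
the algorithms' originating conventions: FedAvgM β = 0.9, η = 1; FedYogi
β₁ = 0.9, β₂ = 0.99, τ = 1e-3, η = 1e-2; FedProx μ = 0.01. Server
arithmetic runs in float64 and is cast back to the weight dtype, which makes
the algebraic reductions (FedAvgM with β = 0, η = 1; FedProx with μ = 0)
recover FedAvg bitwise.

With an adaptive local optimizer, the FedProx anchor pull saturates for
extreme μ: the distance to the anchor shrinks by orders of magnitude as μ
grows but bottoms out at the optimizer's per-step size rather than at zero.

## Evaluation statistics

AUC is the tie-aware Mann–Whitney statistic. Confusion metrics binarize at
0.5 (the protocol leaves the threshold unstated; it is configurable);
ratios with empty denominators are reported as absent with a warning, never
as 0. Confidence intervals use the leave-one-group-out pseudovalue
jackknife with the **patient** as the resampling unit — images of one
patient are correlated, so image-level resampling would understate the
variance — with the normal 97.5% multiplier. Replicates on which a metric
is incomputable (a left-out patient removing an entire class) are skipped
with a warning. The DeLong test computes per-case placement values, the 2×2
covariance of the paired AUCs, and a two-sided normal p-value; it is
checked against an independent 1e5-resample paired bootstrap in the tests.

## Desk-scale study conditions

The tiny profile keeps the full cohort structure and shrinks only the
numerics: 64×64 rendered images (5 per patient in the directional study),
32×32 network input, the tiny architecture, schedules of 1 epoch × 20
rounds / 5 epochs × 5 rounds (10 rounds for the directional comparisons),
3 trials in the grid and 5 trial seeds in the directional study. These sizes
were chosen as the smallest at which the optimization is stable and the
distributional effects are resolvable above seed-to-seed noise.

The directional study compares mean test AUC of: source-partitioned FedAvg,
the single-site (private-only) baseline, quantity skew (Dirichlet β = 2),
the IID two-site scenario (α = 1 on a balanced 84-patient global subset),
and the one-class-per-site extreme. Expected qualitative pattern: FL over
both sites ≥ single-site; one-class far below IID; CS̄ non-decreasing in α;
quantity skew close to IID. The IID cell trains on 84 of the 188 pool
patients (the imbalance scenario fixes its global size), so a small
data-size offset relative to quantity skew is expected even in the absence
of any skew effect; the tests treat differences within 0.03 AUC as "close".

## Known limitations

- Speckle is smoothed-Gaussian-magnitude, an approximation of fully
  developed speckle statistics; no log-compression or TGC modeling.
- The synthetic task is easier than clinical steatosis grading; absolute
  AUCs in the tiny profile run higher than real-world values and only
  orderings between setups are meaningful.
- Client sampling, stragglers, asynchrony, secure aggregation and
  differential privacy are out of scope.
- The binary task fixes the class vocabulary at two; the partition metrics
  generalize to more classes but the builders assume {S0, ≥S1}.
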