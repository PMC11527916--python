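# Methods

## Overview

`doseret` retrieves previously treated radiotherapy plans whose dose
distributions resemble a new patient's *predicted* (virtual) dose, and
returns their optimization parameters (OPs) as a starting point for plan
optimization. The package contains the retrieval model (encoder, triplet
training, nearest-neighbour search), the dosimetric evaluation layer, and
a synthetic cohort generator used to validate the whole pipeline.

## Dose encoder

A five-stage 3D CNN maps a dose volume to a 32-d feature vector:

| stage | operation | channels |
|---|---|---|
| 0 | conv 3×3×3 stride 1 → ReLU → batch norm | 1 → 4 |
| 1–3 | conv 3×3×3 stride 1 → batch norm → ReLU → max-pool 2×2×2 stride 2 | 4 → 8 → 16 → 32 |
| head | flatten → fully connected → L2 normalize | → 32 |

Input extents must be divisible by 8 (three pooling halvings). The default
desk-scale input is 32³; the spatial resolution is otherwise free (a
96×96×128 input gives a 12×12×16×32 = 73 728-feature flatten). Weights are
Glorot-normal initialized with zero biases; batch-norm statistics start at
identity and are frozen for evaluation, so a single volume can be embedded
deterministically regardless of batching.

Design choices worth stating:

* **Output L2 normalization (default on).** The training distance
  √(2 − 2 a·p) equals the Euclidean distance used at query time only for
  unit vectors; normalizing the encoder output makes the two metrics
  coincide identically, which the acceptance suite verifies to 1e-6. A
  flag preserves the unnormalized variant.
* **ReLU inside the pooling blocks (default on).** Without a nonlinearity
  between them, the three conv–BN–pool blocks compose into a single linear
  map; a flag gives the literal conv→BN→pool reading.
* **One input channel.** Only the dose image enters the model; the first
  stage's "4× the input channels" therefore gives 4.

**Preprocessing.** Dose is divided by the prescription, clipped to
[0, 1.5] (deliverable plans rarely exceed 150 % of prescription), and
resampled to the encoder input shape with trilinear interpolation.

## Triplet training with batch-hard mining

For a mini-batch of k patients, anchors (virtual doses) and positives
(clinical doses of the same patients) are embedded in one forward pass and
the k×k matrix D[i,j] = √(2 − 2 aᵢ·pⱼ) is formed (inner products clamped
to [−1, 1]). The hardest negative for anchor i is the smallest
off-diagonal entry of row i or column i, and

    Loss = (1/k) Σᵢ max(0, margin + D[i,i] − min_{j≠i, q≠i}(D[i,j], D[q,i])).

Defaults: margin 1, batch size 4, Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8),
learning rate lr(t) = 0.001 / (1 + 0.01·t). Notes:

* **Learning-rate policy.** The inverse-time form above is the standard
  "poly"-style decay consistent with the stated constants (half rate after
  100 iterations, strictly decreasing from lr₀). A `literal` policy flag
  implements lr₀·(1 + 1/(0.01·t)), which is not a decay (it diverges at
  t = 1 and approaches lr₀ from above) and exists only for reference.
* **Batch size.** Hard-negative mining needs k ≥ 2 (a 1×1 distance matrix
  has no negatives); k = 1 is allowed only with mining disabled, where the
  loss degenerates to a hinge on margin + D[1,1].
* **Diagonal exclusion.** The row/column minima exclude the diagonal: with
  it included the mined minimum can never exceed D[i,i] and the hinge
  saturates at the margin for every anchor.
* **Sampling.** Patients are drawn without replacement per batch from a
  single seeded generator, reshuffling each epoch; training is
  seed-deterministic end to end.
* The gradient of the batch-hard loss is a subgradient (ties in the argmin
  go to the first candidate); D is floored at 1e-6 in the 1/D factor of
  dD/d(a·p) to keep the derivative finite when anchor and positive
  coincide.

The network and Adam are implemented directly in NumPy (im2col
convolutions with explicit backward passes); gradient correctness is
verified per layer against central finite differences.

## Retrieval

Every stored plan's clinical dose is embedded once into a feature index.
Queries embed the virtual dose and rank all stored features by Euclidean
distance — an exact exhaustive scan (at a few hundred plans, exactness
beats approximate-nearest-neighbour structures), with ties broken by
ascending plan id for determinism. The default depth is 3 (Search 1–3).
OP payloads are returned byte-identical to what was stored; they are never
parsed, since the optimizer that consumes them is outside this package.

## Dosimetry

* **Dx** (dose to the hottest x % of a structure) is the descending-rank
  voxel percentile: value at 1-based rank ⌈x/100·N⌉. No interpolation —
  results match exhaustive counting oracles exactly and are
  bit-reproducible. (Clinical TPS DVHs may interpolate; a DVH-based lookup
  is available via `DVHCurve`.)
* **Vx** uses strictly-greater ("receiving over x Gy"); the prescription
  isodose volume V_ref in CI uses ≥, which keeps "95 % of the PTV receives
  100 % of the prescription" self-consistent under D95 normalization.
* **CI** = (V_T,ref/V_T)·(V_T,ref/V_ref), volumes counted in voxels (the
  voxel volume cancels on an equal-volume grid). V_ref = 0 yields CI = 0
  with a warning.
* **HI** = (D2 − D98)/D_P. HI is linear in D2 and D98, so the cohort-mean
  HI equals HI of the cohort means — the identity behind the published
  two-decimal worked examples (65.63/58.69 → 0.12; 65.43/57.67 → 0.13 at
  60 Gy).
* **DVH** is the cumulative ≥-dose histogram at 0.1 Gy bins by default;
  the trapezoidal integral of the curve recovers the voxel mean to within
  one bin width.

## Ranking and compliance evaluation

NDCG@K uses DCG = Σᵢ (2^rᵢ − 1)/log₂(i+1) with 1-based positions,
normalized by the DCG of the grades sorted descending; an all-zero grade
list is scored 0 (avoiding 0/0). In the synthetic benchmark, grades come
from cohort structure — same patient 3, same beam class 2, otherwise 0 —
under leave-query-out, so a perfect retrieval returns same-class plans.
(Published NDCG values on clinical data used expert relevance judgments;
only the harness, not those numbers, is reproducible here.)

Three criteria sets ship as versioned JSON: RTOG 0623 (6 rules), NCCN
(8 rules), and a departmental standard (7 rules). Comparators are applied
literally (≤ vs <). The departmental mean-heart-dose rule is marked
*advisory* and can be excluded from the overall verdict by flag, default
included. Cohort reports provide pass counts/percentages, 2×2 pass/fail
confusion matrices between aligned cohorts, and mean ± sample-SD summary
tables rendered to two decimals.

## Synthetic phantom cohorts

The generator emulates the statistical structure the retrieval method
relies on, not clinical realism:

* **Anatomy** — parametric thorax on a 48³ grid at 4 mm spacing: body
  ellipsoid, two lung ellipsoids, spherical heart, cylindrical cord; a
  spherical GTV placed in a random lung with ±12 mm positional jitter and
  2–4 voxel radius; PTV = GTV dilated 2 voxels; total lung = lungs minus
  GTV, enforced voxelwise.
* **Clinical dose** — coplanar Gaussian-profile beam slabs crossing at the
  PTV centroid plus a conformal component decaying exponentially
  (2.5-voxel falloff) from the PTV surface, with a 2 % intra-plan ripple;
  renormalized so D95(PTV) equals the 60 Gy prescription exactly. Each
  plan class uses a distinct equiangular beam arrangement of 4–7 beams
  with ±3° per-plan jitter. Beam width (σ = 4.5 voxels, comparable to
  PTV + margin) and the beam share of total dose (0.7) are chosen so
  class-dependent beam-path dose dominates out-of-target dose — as it does
  in coplanar IMRT, where the low-dose bath follows beam entry/exit paths
  — making plan class the dominant similarity factor, which is the premise
  of retrieving OPs by dose similarity.
* **Virtual dose** — the clinical dose degraded the way a dose predictor's
  output differs from delivered dose: Gaussian smoothing (σ = 6 mm, lost
  high-frequency detail), a smooth ±5 % multiplicative field (regional
  bias), 1 Gy voxel noise, clamping at zero and D95 renormalization. The
  scale matches the few-percent errors typical of modern dose-prediction
  models; with all three parameters zero the virtual dose equals the
  clinical one exactly.

What the phantom does **not** emulate: CT-derived anatomy and tissue
heterogeneity, realistic beam attenuation and scatter, planner-dependent
trade-offs, or clinically calibrated OAR dose levels (phantom lungs
receive hotter V20/MLD than clinical lung plans because the parametric
thorax is compact). Passing tests therefore demonstrate the correctness
and internal consistency of the pipeline — normalization, metric
definitions, training dynamics, retrieval exactness — not clinical
performance on patient data.

## Problem sizes and determinism

Default experiment scale: 60-plan, 3-class cohorts on a 48³ grid with a
32³ encoder input, 300 training iterations at batch 4 — the scale at
which the pure-NumPy network trains in a few minutes on one CPU while the
class-recovery signal is comfortably measurable (top-1 accuracy ≈ 97 %
and mean NDCG@3 ≈ 0.97 versus a 33 % chance level, in the acceptance
run). All randomness flows from explicit integer seeds through
`numpy.random.Generator`; cohort generation, training, indexing and
benchmarking are reproducible bit-for-bit given the same seeds.

## Known limitations

* OP payloads are opaque: the package retrieves them but cannot optimize a
  plan, so end-to-end plan quality after re-optimization is out of scope.
* The virtual-dose error model is a stand-in for a real dose predictor;
  its parameters are exposed in `VirtualizerSpec` rather than fitted.
* Dx by voxel rank differs from TPS-interpolated DVH statistics by up to
  one voxel's dose; on fine grids the gap is negligible but it is a
  definitional choice.
* Batch-norm running statistics freeze at the end of training; embedding
  quality depends on training batches being representative of the
  database.
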