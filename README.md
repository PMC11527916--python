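# doseret

Knowledge-based plan retrieval for lung IMRT, built on 3D dose-image
embeddings.

## The problem

Designing an intensity-modulated radiotherapy (IMRT) plan means choosing
beam geometry and optimization goals — the *optimization parameters* (OPs)
— that a treatment planning system turns into a deliverable dose. In a
knowledge-based workflow, a new patient's plan is seeded with the OPs of
the most similar plan in a database of previously treated patients.
`doseret` implements the computational core of such a system:

1. **Dose encoder** — a small 3D CNN mapping a prescription-normalized
   dose volume to a unit 32-d feature vector: a 3×3×3 convolution
   quadrupling the channels (ReLU, batch norm), three blocks of 3×3×3
   convolution doubling the channels followed by 2×2×2 max pooling, and a
   fully connected head (channels 1→4→8→16→32).
2. **Triplet training** — the encoder is trained so a patient's
   *predicted* ("virtual") dose image (anchor *a*) embeds close to the same
   patient's *delivered* dose image (positive *p*) and far from the hardest
   other patient's dose in the mini-batch. For batch size *k*, with
   D[i,j] = d(aᵢ, pⱼ) = √(2 − 2 aᵢ·pⱼ),

       Loss = (1/k) Σᵢ max(0, margin + D[i,i] − min_{j,q≠i}(D[i,j], D[q,i]))

   optimized with Adam under inverse-time learning-rate decay
   lr(t) = lr₀ / (1 + decay·t), with margin 1, lr₀ = 0.001, decay = 0.01.
3. **Retrieval** — every stored plan's clinical dose embeds to f_c; a new
   patient's virtual dose embeds to f_v; plans are ranked by the Euclidean
   distance ‖f_v − f_c‖ (which equals d(·,·) on the unit sphere), and the
   OP payloads of the three nearest plans (Search 1–3) are returned.
4. **Dosimetry & evaluation** — DVH, Dx/Vx, Dmean/Dmax, MLD/MHD, the
   conformity index CI = (V_T,ref/V_T)·(V_T,ref/V_ref), the homogeneity
   index HI = (D2 − D98)/D_P, NDCG ranking quality, and compliance against
   RTOG 0623 / NCCN / departmental dose-constraint sets.
5. **Synthetic phantom cohorts** — parametric thorax anatomy with
   class-dependent coplanar beam doses normalized to D95 = prescription and
   paired noisy virtual doses, so the whole pipeline can be exercised and
   validated without clinical data.

## Worked example

```bash
python examples/03_train_and_retrieve.py
```

prints (12 plans, 3 beam classes, 60 training iterations):

```
loss: first 10 iters 0.663 -> last 10 iters 0.142
query: plan_005 (class 2)
  Search 1: plan_005  distance 0.1565  class 2  beams [66.0, 126.0, 186.0, 246.0, 306.0, 6.0]
  Search 2: plan_011  distance 0.7108  class 2  beams [66.0, 126.0, 186.0, 246.0, 306.0, 6.0]
  Search 3: plan_001  distance 0.7828  class 1  beams [37.0, 109.0, 181.0, 253.0, 325.0]
```

The triplet loss falls as anchors approach their positives; the query's
own plan is Search 1 (its virtual dose is nearest its own clinical dose),
and the next hit shares the query's beam-geometry class — the behavior
that makes the retrieved OPs a useful starting point. The other examples
cover cohort simulation (`01`), DVH metrics and criteria compliance
(`02`), and NDCG ranking quality (`04`).

A thin CLI wraps the same library calls:

```bash
doseret simulate --n-plans 20 --n-classes 3 --seed 1 --out cohort/
doseret validate cohort/manifest.json
doseret train --manifest cohort/manifest.json --iters 100 --out weights.npz
doseret index --weights weights.npz --manifest cohort/manifest.json --out index.json
doseret metrics --manifest cohort/manifest.json --out metrics.csv
doseret check --metrics metrics.csv --criteria rtog0623
```

## Layout

```
src/doseret/      core.py (types & NIfTI/manifest I/O) · phantom.py (synthetic cohorts)
                  encoder.py (3D CNN) · _nn.py (layers) · training.py (triplet loss)
                  retrieval.py (index & query) · dosimetry.py (DVH metrics)
                  evaluation.py (NDCG, criteria, reports) · cli.py
docs/methods.md   model, parameters, numerical choices, limitations
examples/         one narrative script per capability
tests/            unit, property and acceptance suites
```
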