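# Methods

## Problem

Transcriptome-wide association studies (TWAS) yield signed z-scores linking
genes to phenotypes: a positive score suggests the gene up-regulates the
trait, a negative one down-regulation. In crops the assayed sample sizes are
small, so the resulting signed bipartite graph (genes on one side,
phenotypes on the other, edges labelled ±1) is sparse and noisy. The package
predicts the sign of unobserved gene–phenotype associations — up (+1), down
(−1), or none (0) — from that graph plus a gene–gene sequence-similarity
matrix (e.g. BLAST percent identity), exploiting the empirical observation
that similar genes tend to share association signs.

## Model

**Signed diffusion.** A signed random walk with restart (SRWR) densifies the
graph. A surfer starts positive at a seed node; crossing a negative edge
flips its sign. Balance theory is relaxed by attenuation factors β and γ: a
negative surfer crossing a negative edge turns positive with probability β,
and crossing a positive edge stays negative with probability γ. With Ã₊/Ã₋
the positive/negative parts of the semi-row-normalised adjacency D⁻¹A and q
the one-hot seed, the stationary visiting probabilities satisfy

    r⁺ = (1−c)(Ã₊ᵀ r⁺ + β Ã₋ᵀ r⁻ + (1−γ) Ã₊ᵀ r⁻) + c·q
    r⁻ = (1−c)(Ã₋ᵀ r⁺ + γ Ã₊ᵀ r⁻ + (1−β) Ã₋ᵀ r⁻)

iterated simultaneously (Jacobi style) until the L1 change of the stacked
iterate falls below ε. Running all seeds gives row matrices r_p, r_n, and
the symmetric signed diffusion matrix r_d = max(r_p, r_pᵀ) − max(r_n, r_nᵀ).
The top-|ℰ| entries of |r_d| in the gene×phenotype block (ties broken by
ascending index) become the diffusion graph 𝒮, preserving the original edge
density. A dense 2N-dimensional linear solve of the same fixed point serves
as an exact cross-check of the iterative solver.

**Contrastive views.** Each training epoch draws one uniform value per edge
and deletes edges below the mask ratio, twice on the original graph and
twice on 𝒮, giving views G₁–G₄. Each view splits into positive-only and
negative-only subgraphs.

**Encoder.** One two-layer single-head graph-attention (GAT) stack encodes
all positive subgraphs, a second all negative subgraphs (parameters shared
within a sign, never across). Self-loops keep isolated nodes defined;
attention logits use a leaky rectifier (slope 0.2) and aggregation an ELU.
Per view k and sign ζ the layer outputs are concatenated
[h⁽⁰⁾‖h⁽¹⁾‖h⁽²⁾] and projected by a view-and-sign-specific matrix W_k^ζ to
dimension d. A two-layer MLP fuses the eight per-view embeddings
(positives of views 1–4, then negatives) into the final z_i ∈ ℝ^d.

**Objectives.** With cosine similarity and temperature τ:
inter-view InfoNCE aligns the same node across views of the same sign
(the denominator sums over j ≠ i only, so the loss can be negative);
the intra-view loss pulls z_i toward its positive-view embeddings and away
from its negative-view ones, −log(Σ_m exp(sim(z_i, z_{i,m}⁺)/τ) /
Σ_m exp(sim(z_i, z_{i,m}⁻)/τ)). They combine as
L_CL = (1−α)·L_inter + α·L_intra. A 2-layer MLP on (z_u ‖ z_v) produces
three logits normalised to a probability triple (P_down, P_none, P_up);
3-class cross-entropy over train edges plus an equal number of sampled
non-edges ("none" class) gives L_label, and the total loss is
L_label + β·L_CL. The "none" pairs are sampled outside the complete known
edge set — including held-out edges — so no evaluated pair is ever trained
toward the undefined class.

**Genes without TWAS associations.** After training, a projection MLP is
fitted to map each trained gene's raw feature row h⁽⁰⁾ to its final
embedding z (mean-squared-error objective); genes absent from training are
embedded through this projection at prediction time.

## Node features

Gene i's initial feature is row i of the similarity matrix (zero-padded
over phenotype columns); phenotypes get one-hot indicator rows. The
similarity matrix defines the gene universe: edge lists are re-indexed onto
its gene order, so genes with no TWAS edge are still present as nodes.

## Initial gene similarity inputs

BLAST tabular (outfmt 6) input is reduced to best-hit percent identity /
100 per ordered pair, symmetrised by elementwise max, diagonal forced to 1.
A dense labelled TSV matrix is accepted as an alternative.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| c | 0.15 | SRWR restart probability (common RWR practice) |
| β, γ | 0.5 | balance attenuation factors (neutral midpoint) |
| ε / max_iter | 1e−9 / 200 | SRWR stop rule; at c = 0.15 the contraction is 0.85 per step, so ~135 iterations reach 1e−9 (100 would not) |
| τ | 0.05 | contrastive temperature |
| α | 0.8 | intra- vs inter-view weight |
| β (loss) | 0.01 | contrastive weight in the total loss |
| d ("feature") | 64 | embedding dimension |
| mask | 0.4 | edge-deletion ratio (flagship preset) |
| predictor | 2 layers | sign predictor depth (1–4 supported) |
| optimizer | Adam, lr 1e−3, weight decay 5e−4, 300 epochs | standard for this model family |

Dataset presets: `gossypium` (α 0.8, β 0.01, d 64, mask 0.4, 2-layer
predictor), `brassica` (α 0.2, β 0.1, d 32, mask 0.8, 1-layer), `triticum`
(= gossypium), and `synthetic` (= gossypium but mask 0.8 and lr 3e−3,
calibrated on the latent-factor benchmark below: its graphs are far denser
than the crop data, and aggressive masking regularises against edge
memorisation — consistent with the mask value the dense rapeseed preset
uses).

## Numerical choices

- Probability triple: softmax over the 3 logits (the literal elementwise
  sigmoid, renormalised, is available via `output_normalization="sigmoid"`);
  tables of published triples sum to 1, which the softmax guarantees.
- Prediction call tie-break on exact ties: none > up > down (conservative).
- Log-sum-exp stabilisation in every contrastive term; cross-entropy log
  floored at 1e−12; cosine of a zero vector defined as 0 (ε = 1e−12 in the
  row normaliser).
- MLP hidden activations are leaky rectifiers (slope 0.2): with plain ReLU
  and all-positive similarity inputs, Adam steps can kill every hidden unit
  of the small projection MLP (observed as a loss plateau at target
  variance).
- Zero-degree rows stay zero under semi-row normalisation, so probability
  mass leaks at isolated nodes; the conservation property is stated for
  graphs without them.
- All floating point is float64; training is deterministic given the seed
  (single-threaded numpy).
- Inference embeddings average the fused encoder output over 8 seeded mask
  draws: the predictor is trained against masked-view embeddings, and
  encoding the unmasked graph at test time is out-of-distribution for it
  (measurably lower AUC); averaging keeps inference in-distribution while
  removing single-draw noise.

## Synthetic benchmark

The generator plants latent factors: genes and phenotypes draw
standard-normal vectors u_g, v_p ∈ ℝ^L; the true sign of (g, p) is
sign(⟨u_g, v_p⟩). Observed edges are a uniform sample of distinct pairs
with signs flipped independently with probability `flip_noise`; the
similarity matrix is clamp₀₁((1 + cos(u_i, u_j))/2 + symmetric noise),
diagonal 1. This makes similar genes genuinely share association signs —
the assumption the architecture exploits — and gives an inner-product
oracle that upper-bounds achievable recovery.

Reference conditions: 200 genes, 8 phenotypes, 1000 edges, L = 4,
flip_noise 0.1, sim_noise 0.1, 8:2 edge split, 5 replicate seeds, the
`synthetic` preset. With 10% of observed labels flipped, a perfect scorer
reaches only ≈ 0.87–0.90 AUC against the observed held-out signs, so
recovery is scored against the planted true signs (`truth_auc`); the
observed-sign AUC is reported alongside. An optional power-law phenotype
degree option mirrors the extreme imbalance of real TWAS tables (one
phenotype can carry most associations); it is off by default.

What the benchmark does *not* emulate: real sequence-similarity structure
(BLAST identities are not cosines of low-rank factors), realistic edge
sparsity patterns, z-score magnitudes, or linkage between genes, so passing
it shows the pipeline recovers plantable low-rank sign structure under
noise — not that crop-scale accuracy is guaranteed.

## Evaluation protocol

Edges are split 8:2; diffusion, view building, class-0 sampling and all
losses see only the train split. Held-out evaluation is binary over the two
sign classes: score = P_up / (P_up + P_down), positive class = up; AUC,
AUPR, F1, precision, micro-/macro-F1 (scikit-learn). A test set with a
single class reports AUC 0.5 with a warning. Robustness runs flip a fixed
fraction of signs on the full graph before splitting; subsampling keeps a
fixed fraction of edges.

Problem sizes used by the test suite and the acceptance script — the
benchmark above for recovery/robustness, a 60-gene reduced fixture for
ablation wiring, N ≤ 20 random graphs for the solver-equivalence sweeps —
were chosen so the whole protocol runs on a laptop-class single core in
well under half an hour.

## Known limitations

- The encoder is dense (N×N attention masks); fine for graphs of a few
  thousand nodes, not for genome-scale similarity graphs.
- "Parameters shared in the same perspective" is read as one encoder per
  sign; the alternative reading (one per source graph) is not implemented.
- Diffusion edge weights are binarised to signs when building 𝒮; the
  attention does not see |r_d|.
- The contrastive batch is all nodes (full batch); no mini-batching.
- The 3-class training target conflates "unobserved" with "no association";
  on the synthetic benchmark every pair has a latent sign, so the "none"
  class is purely a modelling device there.
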