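# Methods

## Problem and data model

The package predicts unobserved gene–disease associations from a
heterogeneous network with node types gene (G), disease (D), Gene
Ontology term (O) and disease symptom (S), and undirected relations G–G
(protein interactions), G–D (known associations), G–O (annotations) and
D–S (symptom links).  Only these four relations are admitted (the
metagraph); edge weights of the input network are 1 and duplicate rows
collapse on load.  Internally every type is indexed densely; original
string IDs are kept in the id maps and restored in all outputs.

Metapaths are typed path patterns with equal endpoint types.  The default
registry is GG, GDG, GOG over genes and DGD, DSD over diseases.  Each
metapath induces a homogeneous graph on its endpoint type whose edge
weight counts distinct path instances (computed by chained sparse
incidence products; the diagonal is removed, as length-2 "self paths"
only retrace an edge).  The model consumes connectivity only; instance
counts are retained in the data structure because they are cheap and
useful for inspection.

## Model

1. **Common-space projection.** Per-type linear maps `M_a ∈ R^{d'×d_a}`
   give `h'_v = M_a x_v`.  When the input network carries no features,
   one-hot identity features are used (`d_a = n_a`; a Gaussian random
   feature mode of configurable dimension is available).  `d'` equals
   `hidden_dim`.
2. **Factorization.** Per metapath, `N` scorers produce edge weights
   `W_e[v,u] = σ((S_e(v,u)+S_e(u,v))/2)` where `S_e` is an affine map on
   the concatenated pair features.  Averaging the two argument orders
   makes weights symmetric, as required on an undirected graph.  All
   factors share the edge support and the node features.
3. **Factor discrimination.** Each factor graph is encoded by one round
   of `W_e`-weighted neighbor averaging followed by global mean pooling
   over nodes with at least one edge (an empty graph falls back to the
   global feature mean) — the simplest permutation-invariant encoder that
   uses both `W_e` and `h'`.  A single fully-connected layer classifies
   the encoding into `N` labels (label = factor index, shared across
   metapaths), and `L_Factor` is the mean cross-entropy, `ln N` at the
   uninformative plateau.
4. **Intra-metapath attention.** GAT-style per-(factor, head) attention:
   logit `LeakyReLU(a_src·Wh'_i + a_dst·Wh'_j)` (slope 0.2) plus
   `log W_e[i,j]` — equivalently the softmax numerator is multiplied by
   the factor's edge weight, which is how the factor graphs influence
   aggregation without breaking normalization; the self edge has weight
   1.  Coefficients are softmax-normalized over the sampled neighborhood
   (which always contains the node itself), outputs pass through an ELU
   (disable with `apply_elu=False`; the aggregation is otherwise linear),
   and heads × factors are concatenated into `Z^m` of width
   `N · hidden_dim`.
5. **Semantic fusion.** `P_m = mean_v tanh(W_a Z^m_v + ε_a)`,
   `ω = softmax(⟨Q, P_m⟩)` over the type's metapaths, `H_v = Σ ω_m Z^m_v`.
   `ω` is metapath-level: identical for every node of the type and
   computed over the full node set each pass, even under neighbor
   sampling.
6. **Decoder and objective.** `Score_gd = σ(⟨H_g, H_d⟩)`;
   `L_Pred = −Σ_pos log s − Σ_neg log(1−s)` with scores clamped to
   `[1e-7, 1−1e-7]`; total loss `L_Pred + γ·L_Factor`.

## Training protocol

Full-batch Adam (lr 0.005, L2 penalty 0.001 added to the gradient),
default 200 epochs, γ = 1, at most 100 neighbors per node resampled every
epoch from a per-epoch seed; 10% of the training pairs form a validation
slice for early stopping (patience 30) with best-validation-AUC parameter
restoration.  Test positives are removed from the graph before metapath
construction so held-out links cannot leak through GDG/DGD instances; the
removed edges are stored in checkpoints so a reloaded model rebuilds the
identical training context.  Splitting defaults to 20% test positives and
a balanced 1:1 negative ratio, negatives drawn uniformly from non-edges
of the original positive set (the real network's published test pool does
not state its proportions, so both are configuration, and no claim is
made to match that split).  All randomness flows from integer seeds;
identical configuration gives bit-identical traces.

Gradients come from HIPS `autograd` over a pure-numpy forward pass (no
deep-learning framework is required); the optimizer is hand-written.
Dense per-metapath adjacency masks are used, which is exact and fast for
networks up to a few thousand nodes per type; larger networks would need
a sparse attention kernel, a known limitation.

## Architecture defaults

`hidden_dim` 128 (performance peaks there in the reference setting),
`num_heads` 8 (concatenated; head width = hidden/heads), `num_factor_graphs`
16 (best reported factor count), `sem_dim` 128, γ = 1.  Benchmark and test
runs use a scaled-down 32/2-head/4-factor model purely for CPU time; this
changes capacity, not mechanism.

## Synthetic benchmark: what it does and does not establish

The generator plants `B` latent communities shared by all four types and
draws every relation from a stochastic block model (within-community
probability `p_in`, across `p_out`).  GO and symptom nodes receive their
community label before their edges are sampled, so GOG and DSD metapaths
carry the same planted signal.  Defaults are the benchmark world: 200
genes, 100 diseases, 130 GO terms and 45 symptoms (intermediate-type
counts scale the real network's type ratios), B = 2, `p_in` = 0.3,
`p_out` = 0.02.  It does *not* emulate real degree heterogeneity, edge
weight structure, or relation-specific densities.

A consequence worth stating precisely: in an SBM, held-out edges are
conditionally i.i.d. given community memberships, so no predictor can
rank better than block co-membership.  For the default parameters,
positives are within-block with probability 0.9375 while 0.4167 of
non-edge negatives are also within-block, giving an analytic AUC ceiling
of 0.7604; the ground-truth-label oracle measures 0.74–0.77 across seeds
and the trained model reaches ≈0.745–0.78, i.e. it recovers the planted
structure essentially perfectly.  Green tests on this benchmark therefore
establish that the pipeline learns the recoverable structure and that a
signal-free control (`p_in = p_out`) stays at AUC ≈ 0.5 — not that any
fixed AUC above the ceiling is reachable, and not real-data performance.
For the same reason the factor-discrimination loss has no measurable AUC
effect here (γ = 1 and γ = 0 agree to ~2e-5): with a single planted
semantic dimension there are no extra relations for the factor graphs to
mine.  Its mechanism is instead verified directly (discrimination
training drives `L_Factor` below the `ln N` plateau; gradients reach
every scorer; factor blocks collapse when parameters are tied).

## Numerical choices

- Sigmoid computed via tanh for tail stability; scores clamped before logs.
- Masked attention uses additive −1e30 logits; `log W_e` is clipped at
  1e-30 (off-support entries are masked anyway).
- Ranking and top-K metrics break ties by stable sort (original pool or
  gene-index order); AUC uses the tie-averaged rank convention.
- Metric routines delegate AUC/AP to scikit-learn; tests cross-check them
  against brute-force pair enumeration and stepwise PR summation.
- Glorot-uniform initialization everywhere, from a single seeded
  generator per model.

## Known limitations

- Dense masks bound scalability (~10^3–10^4 nodes/type on one CPU).
- Transductive: embeddings exist only for nodes present at training.
- Whether factor labels should be shared across metapaths or
  per-metapath, and whether the attention output nonlinearity belongs in
  the aggregation, are genuinely open choices; the package picks shared
  labels and ELU-on, both flagged in configuration.
- `W_e` is used raw (no row normalization) — the factor weights bias
  attention multiplicatively.
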