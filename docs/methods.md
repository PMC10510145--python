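# Methods

This note documents the model implemented by `dtakit`, the choices made
where the architecture leaves details open, what the synthetic data
does and does not emulate, and the numerical conventions the code
commits to.

## Problem setting

Drug–target binding affinity (DTA) prediction is a regression task:
given a small molecule (as a SMILES string) and a protein (as an
amino-acid sequence), predict a real-valued affinity such as a pKi or
pKd. The package encodes the two modalities separately, fuses them
with an attention mechanism, and regresses the affinity with an MLP.

## Molecule encoder: undirected communicative message passing

A SMILES string is parsed (RDKit) into a heavy-atom graph with
undirected bonds stored once. Atom descriptor rows x_v are one-hot
blocks for element (10 common elements + "other"), degree 0–5, formal
charge −2…+2, attached hydrogens 0–4, hybridisation, plus one
aromaticity bit (34 columns). Bond rows x_e are a one-hot block for
bond order {single, double, triple, aromatic} plus conjugation and
ring-membership bits (6 columns). The descriptor sets are the
conventional ones for message-passing chemistry models; their exact
composition is a documented convention of this package.

Initial hidden states are h_v⁰ = ReLU(Linear(x_v)) and
h_e⁰ = ReLU(Linear(x_e)), both of width d. Each of L layers exchanges
messages along three undirected routes, each pooling a neighbourhood N
as

    F(N) = max_{i∈N}(h_i) ⊙ Σ_{i∈N}(h_i)     (elementwise)

with bond→atom using the bonds incident to an atom, atom→atom the
adjacent atoms, and bond→bond the bonds sharing exactly one endpoint
(the bond itself never participates). The pooled message gates the
receiver's current state (h ⊙ F), atoms update additively,

    h_v^l = h_{e→v} + h_{v→v} + h_v^{l−1},

and bonds pass through a learned square map with a residual
connection, ReLU, and dropout:

    h_e^l = Dropout(ReLU(W_l · h_{e→e} + h_e^{l−1})).

After L layers, each atom's [h_v^L, h_{v→v}, h_{e→v}] (the two
aggregated terms from the final layer's update) are concatenated,
passed through a communicate map (affine 3d→d + ReLU), and sum-pooled
over atoms into the molecule embedding E_m.

Conventions this implementation commits to:

* **All hidden widths equal d** so the Hadamard gates are well-formed.
  Default d = 128; tests use d = 8–16.
* **Empty neighbourhoods pool to the zero vector**, the only choice
  that keeps the atom update finite for isolated atoms and makes a
  single-atom molecule's embedding the communicated vector of that
  atom.
* **W_l is a distinct square matrix per layer** (layer-specific
  parameters), with no bias — the residual term carries the state.
* **The readout's aggregated atom terms** are the ones computed during
  the final message-passing layer (i.e. from h^{L−1}); the readout is
  a per-atom affine + ReLU followed by sum pooling, which is
  deterministic and atom-order invariant. This is a deliberate,
  simpler stand-in for a recurrent communicative readout: sum pooling
  is what makes the permutation-invariance guarantee exact.
* **Depth default L = 3** (deeper settings over-smooth, shallower
  under-mix); dropout default 0.1, disabled at evaluation.
* The gated updates are multiplicative, so hidden magnitudes can grow
  roughly cubically with depth. Everything is computed in float64 and
  the final MLP absorbs scale; at the depths used (≤ 3) this is
  numerically benign.

## Protein encoder: masked language model + contrastive predictive coding

Proteins are tokenised over the 20 standard residues plus PAD, MASK
and UNK (V = 23). Two branches are pretrained self-supervised and
their outputs concatenated.

**MLM branch.** A pre-norm transformer encoder with learned token and
position embeddings. Pretraining masks round(0.15 × #non-PAD)
positions (minimum one; PAD is never a candidate), replaces them with
MASK (the BERT 80/10/10 mixture is available behind a flag, off by
default), and minimises mean cross-entropy over the masked positions
only. Uniform scores give the baseline loss ln 23 ≈ 3.135; any
learning pushes below it. The feature extracted for the DTA task is
the mean of final hidden states over non-PAD positions of the
*uncorrupted* sequence. "Base" and "large" presets differ in depth,
heads and width; at the problem sizes used here the base preset is the
default.

**CPC branch.** The sequence is padded with PAD to a fixed total
length L_t and cut into x = L_t/L_s non-overlapping segments;
sequences longer than L_t are discarded. Defaults: L_s = 11 (the
segment length at which local/global information balance is best) and
L_t = 990, the largest multiple of 11 not exceeding the 1000-residue
corpus cap. Each segment passes independently through a shared
embedding + (1-D convolution → layer norm → ReLU) stack and is mean-
pooled to a local feature z_t. A GRU summarises z_1..z_t into a causal
context c_t. The InfoNCE objective scores the true future segment
z_{t+k} (k ≤ K, default K = 1) against negative segments drawn from
other proteins in the batch (default 8) through a per-step bilinear
map, with softmax cross-entropy; contrastive accuracy splits credit
evenly across tied argmax candidates so that all-equal scores measure
exactly chance.

**Combined embedding.** E_p keeps the segment axis: row t is
[z_t, pooled-MLM]. The per-segment layout (rather than a flattened
vector) is what gives the attention mechanism protein positions to
re-weight. Using the pooled MLM vector (not per-position MLM states)
in every row is a deliberate choice; the per-position variant would
multiply the fusion width by L_t/x with no positional alignment
between segments and residues.

**Pretraining loop.** The two objectives are optimised on alternating
batches by default (a joint weighted-sum mode is available). Both
branches' weights and the config serialise into one checkpoint.

## Fusion and regression head

With E_m the molecule embedding and E_p the x×d_p protein matrix:

    Score = tanh( ReLU(E_m W_m) · ReLU(E_p W_p)ᵀ )        (one score per segment)
    E_p'  = (Score · ReLU(E_p W_p)) W_s                   (weighted row sum)
    ŷ     = MLP([E_m, E_p'])

Because the printed form of the re-weighting is dimensionally
ambiguous, the implementation fixes it as the score-weighted sum of
transformed protein rows — the only reading that yields a fixed-width
E_p' for any segment count, matching the narrative of re-weighting
protein positions. Attention runs from molecule to protein only (the
direction found to work best; the reverse and bidirectional variants
are out of scope). With ReLU'd queries and keys, scores lie in [0, 1).

The training objective is

    L = (1/n) Σ (ŷ_i − y_i)² + (∂/2)‖Θ‖²,

with the L2 penalty over all learnable parameters implemented
explicitly in the loss (not as optimizer weight decay) so that
reported loss values equal the objective; ∂ defaults to 1e-4.
Optimisation is mini-batch Adam; the best epoch is selected by
validation MSE when a validation split exists.

## Metrics

MSE is the plain mean of squared differences. The concordance index

    CI = (1/Z) Σ_{δ_i > δ_j} h(b_i − b_j),  h = 1 / 0.5 / 0 for >0 / =0 / <0,

counts only strictly ordered label pairs in Z (label ties contribute
no pair); exact floating-point prediction ties take the 0.5 branch
with no tolerance band. When all labels are tied, CI is undefined and
the package raises rather than returning a number. The vectorised
implementation is tested for exact equality against O(n²) brute-force
enumeration.

## Synthetic data

The generator exists so that every stage is verifiable offline.

* **Molecules** are grown atom-by-atom (C/N/O/S, single/double bonds)
  under valence rules, with optional aliphatic ring closures (sizes
  3–6) and benzene cores, giving chains, branches, rings and
  heteroatoms; every emitted SMILES re-parses. Default 4–12 heavy
  atoms.
* **Proteins** are uniform-random sequences, or exact periodic repeats
  (period 3 by convention in tests) which give the MLM context signal
  and make same-protein segments mutually predictive for CPC. The
  default length range 70–1000 mirrors the pretraining corpus the
  module emulates; pipeline tests use shorter ranges as their toy
  problem size.
* **Labels** are a fixed deterministic function plus optional Gaussian
  noise: 0.25·(heavy atoms) + 0.5·(aromatic rings) + 2.0·(hydrophobic
  fraction, over the residue set AVLIFMWC) + 0.05·(heavy atoms ×
  hydrophobic fraction). The coupling term guarantees neither modality
  alone explains all variance, so end-to-end recovery genuinely
  exercises the fusion. Coefficients were chosen once to put labels on
  a pKd-like scale (≈ 2–5) with the molecule term dominating the
  variance, as in real affinity panels where ligand series vary more
  than targets.

What the synthetic task does **not** emulate: real binding physics,
the label distributions of Ki/Davis-style datasets, realistic residue
composition, or drug-like chemistry. Passing the synthetic recovery
tests demonstrates that the architecture can extract and fuse the two
modalities' signal and that the training loop optimises the stated
objective — not that the model reaches any particular accuracy on
real affinity data.

## Problem sizes and numerical choices

All tensors are float64 on a small reverse-mode autodiff core written
for this package; gradient correctness is verified against central
finite differences (agreement ≤ 1e-4 relative with a small-denominator
floor). Test and acceptance runs use toy dimensions (d = 8–16, MLM
width 16, one transformer layer, L_t = 110 with x = 10 segments),
pretraining runs of 200 steps on 100 period-3 sequences, and DTA runs
of 500 training pairs (100 epochs) and a 64-pair overfit fixture
(early-stopped at training MSE < 0.01). These sizes were chosen so the
whole suite runs on one CPU core in minutes while every claim stays
measurable.

Degenerate inputs are defined, not improvised: single-atom molecules
(no bonds) encode finitely through the empty-neighbourhood convention;
all-PAD sequences are rejected for masking and pooling; CI with no
ordered pair raises; non-finite embeddings or losses raise instead of
propagating NaNs. Ties: the max-pool gradient flows to the first
argmax; prediction ranking breaks ties by input order.

## Known limitations

* The encoders are exact but not fast: the package targets method
  verification and small-scale experimentation, not large-scale
  training (no GPU path, no minibatch graph batching).
* The multiplicative message passing grows hidden magnitudes with
  depth; depths beyond ~5 may need smaller initial scales.
* Pretraining at full scale (tens of thousands of sequences,
  L_t = 990) is supported by the code but not exercised by the test
  suite.
* Cold-drug / cold-protein (entity-disjoint) splitting is out of
  scope; the split is a random row split.
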