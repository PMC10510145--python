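# dtakit

Drug–target binding affinity (DTA) prediction from SMILES strings and
amino-acid sequences, built for researchers who want a fully tested,
CPU-runnable reference implementation of a graph + self-supervised
sequence architecture rather than a black-box benchmark script.

## The model

**Molecule branch — undirected communicative message passing.** A
SMILES string becomes a heavy-atom graph with one-hot atom/bond
descriptors. Hidden atom and bond states of common width d exchange
messages along three undirected routes (bond→atom, atom→atom,
bond→bond), each neighbourhood pooled as

    F(N) = max(h_i) ⊙ Σ(h_i),   i ∈ N        (elementwise)

gating the receiver's state. Atoms update additively
(h_v^l = h_{e→v} + h_{v→v} + h_v^{l−1}); bonds through
Dropout(ReLU(W·h_{e→e} + h_e)). After L layers (default 3) a
communicate map + sum pooling yields the molecule embedding E_m,
invariant to atom renumbering.

**Protein branch — MLM + contrastive predictive coding.** A small
transformer is pretrained with masked-language modelling (15% of
residues masked, cross-entropy on masked positions). In parallel the
sequence is padded and cut into x = L_t/L_s segments (default
L_s = 11), each encoded by shared conv/norm/ReLU blocks to a local
feature z_t; a GRU context c_t is trained with an InfoNCE loss to
tell the protein's true next segment from other proteins' segments.
The protein representation E_p is per-segment: row t = [z_t,
pooled-MLM].

**Fusion and head.** Molecule→protein attention,

    Score = tanh(ReLU(E_m W_m) · ReLU(E_p W_p)ᵀ),
    E_p'  = (Score · ReLU(E_p W_p)) W_s,
    ŷ     = MLP([E_m, E_p']),

trained by minimising (1/n)Σ(ŷ−y)² + (∂/2)‖Θ‖². Evaluation uses MSE
and the concordance index CI = (1/Z)Σ_{δ_i>δ_j} h(b_i − b_j) with the
1 / 0.5 / 0 step function.

Everything runs on a small float64 reverse-mode autodiff core inside
the package; gradients are verified against finite differences in the
test suite. A seeded synthetic generator (valid random molecules,
random or periodic proteins, a documented deterministic label
function) makes every stage testable without downloads. See
`docs/methods.md` for the full model description and design choices.

## Worked example

```python
import numpy as np
from dtakit import (ModelConfig, SyntheticSpec, gen_dataset, make_split,
                    train_dta, predict)
from dtakit.data import DtaDataset

spec = SyntheticSpec(n_pairs=200, mol_atom_range=(4, 10),
                     prot_len_range=(40, 100), noise_sd=0.0, seed=7)
dataset = DtaDataset(gen_dataset(spec))
split = make_split(len(dataset), seed=0)          # 8:1:1
config = ModelConfig.toy(epochs=30, seed=0)
result = train_dta(dataset, split, config)
print(f"best epoch: {result.best_epoch}")
print(f"test MSE = {result.test_mse:.3f}, test CI = {result.test_ci:.3f}")

sequence = dataset.row(0)[1]
table, _ = predict(result.model, ["CCO", "c1ccccc1O", "CC(C)CC1CCC1"], sequence)
for smiles, value, rank in table:
    print(f"{rank}  {smiles:14s} {value:.3f}")
```

prints

```
best epoch: 28
test MSE = 0.131, test CI = 0.837
1  c1ccccc1O      3.481
2  CC(C)CC1CCC1   2.981
3  CCO            1.638
```

The model was trained on 160 synthetic pairs whose labels follow a
known function of molecule size, aromaticity and protein
hydrophobicity: a held-out CI of 0.84 after 30 toy epochs means the
predicted affinities order 84% of strictly ordered test pairs
correctly, and the ranking places the larger/aromatic molecule first
— exactly what the label function rewards. Longer training at these
conditions pushes CI above 0.9 (see the acceptance checks below).

The same workflow is available from a shell:

```bash
dtakit gen-data --n-pairs 200 --n-proteins 50 --noise-sd 0 --out-dir work
dtakit pretrain work/corpus.fasta --steps 200 --out work/prot.npz
dtakit train work/dta.csv --pretrained work/prot.npz --out work/model.npz
dtakit evaluate work/model.npz work/dta.csv
dtakit predict work/model.npz screen.smi MKVAVLDEIR...
```

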