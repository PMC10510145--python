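"""Molecule→protein attention fusion and the MLP regression head.

The molecule embedding E_m queries the per-segment protein embedding
E_p: both are mapped through learnable matrices and ReLU, their dot
product per protein position is squashed by tanh into an attention
score, and the scores re-weight the transformed protein rows into a
single summary vector E_p'. [E_m, E_p'] then feeds a small MLP that
outputs the predicted affinity. The training objective is mean squared
error plus an explicit L2 penalty (coefficient ``l2_coeff``) over all
learnable parameters, so the reported loss value includes the penalty.

Attention runs from molecule to protein only.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat
from ._nn import Linear, ParamModule, glorot
from .errors import ConfigError, NumericError

__all__ = ["FusionPredictor", "training_loss"]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


class FusionPredictor(ParamModule):
    """Attention re-weighting plus the regression MLP.

    Parameters
    ----------
    d_mol : width of the molecule embedding E_m.
    d_prot : width of each protein row of E_p.
    d_att : attention width d_a shared by the W_m / W_p projections.
    mlp_hidden : hidden widths of the regression MLP (output is scalar).
    """

    def __init__(self, rng: np.random.Generator, d_mol: int, d_prot: int,
                 d_att: int = 32, mlp_hidden: tuple[int, ...] = (64, 32)):
        self.d_mol = d_mol
        self.d_prot = d_prot
        self.d_att = d_att
        self.W_m = Tensor(glorot(rng, d_mol, d_att), requires_grad=True)
        self.W_p = Tensor(glorot(rng, d_prot, d_att), requires_grad=True)
        self.W_s = Tensor(glorot(rng, d_att, d_att), requires_grad=True)
        widths = [d_mol + d_att, *mlp_hidden, 1]
        self.mlp_layers = [Linear(rng, a, b)
                           for a, b in zip(widths[:-1], widths[1:])]

    # ------------------------------------------------------------- attention
    def attention_score(self, e_mol, e_prot) -> Tensor:
        """Score = tanh(ReLU(E_m W_m) · ReLU(E_p W_p)^T), one per protein row."""
        e_mol, e_prot = _as_tensor(e_mol), _as_tensor(e_prot)
        if e_mol.shape[-1] != self.d_mol or e_prot.shape[-1] != self.d_prot:
            raise ConfigError(
                f"embedding widths ({e_mol.shape[-1]}, {e_prot.shape[-1]}) do "
                f"not match fusion dims ({self.d_mol}, {self.d_prot})")
        q = (e_mol @ self.W_m).relu()                 # [d_att]
        keys = (e_prot @ self.W_p).relu()             # [x, d_att]
        return (keys @ q).tanh()                      # [x]

    def reweight_protein(self, score, e_prot) -> Tensor:
        """E_p' = W_s · (Score · ReLU(E_p W_p)): score-weighted row sum."""
        score, e_prot = _as_tensor(score), _as_tensor(e_prot)
        if score.shape[0] != e_prot.shape[0]:
            raise ConfigError(
                f"score length {score.shape[0]} does not match protein rows "
                f"{e_prot.shape[0]}")
        keys = (e_prot @ self.W_p).relu()             # [x, d_att]
        return (score @ keys) @ self.W_s              # [d_att]

    # ------------------------------------------------------------ regression
    def predict_affinity(self, e_mol, e_prot_summary) -> Tensor:
        """ŷ = MLP([E_m, E_p']) — a single real number."""
        e_mol, e_prot_summary = _as_tensor(e_mol), _as_tensor(e_prot_summary)
        for t in (e_mol, e_prot_summary):
            if not np.all(np.isfinite(t.data)):
                raise NumericError("non-finite embedding fed to the MLP head")
        h = concat([e_mol, e_prot_summary], axis=0)
        for layer in self.mlp_layers[:-1]:
            h = layer(h).relu()
        return self.mlp_layers[-1](h).reshape(())

    def forward(self, e_mol, e_prot) -> Tensor:
        """Full fusion pass: attention → re-weighting → MLP prediction."""
        score = self.attention_score(e_mol, e_prot)
        summary = self.reweight_protein(score, e_prot)
        return self.predict_affinity(e_mol, summary)

    __call__ = forward


def training_loss(predictions, labels, params: dict | None = None,
                  l2_coeff: float = 0.0) -> Tensor:
    """(1/n) Σ (ŷ_i − y_i)² + (l2/2) ‖Θ‖² with Θ all learnable parameters."""
    if l2_coeff < 0:
        raise ConfigError("l2_coeff must be non-negative")
    preds = (predictions if isinstance(predictions, Tensor)
             else Tensor(predictions))
    y = np.asarray(labels, dtype=np.float64)
    if preds.shape != y.shape:
        raise ConfigError(f"batch shape mismatch: {preds.shape} vs {y.shape}")
    if y.size < 1:
        raise ConfigError("batch must contain at least one sample")
    loss = ((preds - Tensor(y)) ** 2.0).mean()
    if l2_coeff > 0.0 and params:
        penalty = None
        for p in params.values():
            term = (p * p).sum()
            penalty = term if penalty is None else penalty + term
        loss = loss + penalty * (l2_coeff / 2.0)
    return loss
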