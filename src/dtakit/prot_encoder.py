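"""Self-supervised protein sequence encoder: an MLM branch and a CPC branch.

A protein is tokenised over the 20 standard residues plus PAD/MASK/UNK
(vocabulary size 23). Two branches see the same sequence:

* **MLM branch** — a small transformer encoder with learned token and
  position embeddings. For pretraining, 15% of the non-PAD positions
  are replaced by MASK and the encoder is trained to recover them with
  a cross-entropy loss over the masked positions only. For feature
  extraction the pooled embedding is the mean encoder output over
  non-PAD positions of the *uncorrupted* sequence.

* **CPC branch** — the sequence is padded to a fixed total length L_t
  and cut into x = L_t / L_s non-overlapping segments of length L_s.
  Each segment passes independently through a shared stack of
  (1-D convolution → layer norm → ReLU) blocks and is pooled to a
  local feature z_t. A GRU autoregressor summarises z_1..z_t into a
  causal context c_t, trained with an InfoNCE loss to score the true
  future segment of the same protein against segments of other
  proteins.

The combined protein representation E_p keeps the segment axis: row t
is [z_t, pooled-MLM], so downstream attention can re-weight positions
along the protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat
from ._nn import GRU, LayerNorm, Linear, ParamModule, SelfAttentionBlock, glorot
from .errors import ConfigError, DataError

__all__ = [
    "AMINO_ACIDS", "PAD", "MASK", "UNK", "VOCAB_SIZE",
    "ProteinRecord", "SegmentedProtein", "ProteinEmbedding", "DISCARDED",
    "encode_sequence", "length_filter", "segment_protein", "mask_for_mlm",
    "MLMEncoder", "mlm_loss", "CPCEncoder", "InfoNCEHead", "infonce_loss",
    "ProteinEmbedder",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = 20
MASK = 21
UNK = 22
VOCAB_SIZE = 23
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@dataclass
class ProteinRecord:
    """Raw sequence plus its token view (no padding applied yet)."""

    sequence: str
    token_ids: np.ndarray

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SegmentedProtein:
    """Padded, windowed view: `segments[t]` is the t-th length-L_s window."""

    segments: np.ndarray                 # [x, L_s] int token ids
    total_length: int                    # L_t (padded)

    @property
    def n_segments(self) -> int:
        return self.segments.shape[0]


@dataclass
class ProteinEmbedding:
    mlm_part: np.ndarray                 # [d_mlm] pooled MLM output
    cpc_locals: np.ndarray               # [x, d_c] per-segment features
    combined: np.ndarray                 # [x, d_c + d_mlm]


class _Discarded:
    """Sentinel for proteins longer than the configured maximum."""

    def __repr__(self):
        return "DISCARDED"


DISCARDED = _Discarded()


def encode_sequence(sequence: str) -> ProteinRecord:
    """Tokenise; letters outside the 20-residue alphabet map to UNK."""
    if not sequence:
        raise DataError("empty protein sequence")
    ids = np.array([_AA_INDEX.get(aa, UNK) for aa in sequence.upper()],
                   dtype=np.intp)
    return ProteinRecord(sequence=sequence, token_ids=ids)


def length_filter(records, min_len: int, max_len: int):
    """Keep records with min_len <= length <= max_len (inclusive bounds)."""
    if min_len > max_len:
        raise ConfigError("min_len must not exceed max_len")
    for rec in records:
        if min_len <= rec.length <= max_len:
            yield rec


def segment_protein(record: ProteinRecord, segment_length: int,
                    max_total_length: int):
    """Pad to `max_total_length` and cut into x = L_t/L_s windows.

    Returns :data:`DISCARDED` when the protein exceeds the maximum.
    """
    if segment_length < 1:
        raise ConfigError("segment_length must be >= 1")
    if max_total_length % segment_length:
        raise ConfigError(
            f"max_total_length {max_total_length} is not a multiple of "
            f"segment_length {segment_length}")
    if record.length > max_total_length:
        return DISCARDED
    padded = np.full(max_total_length, PAD, dtype=np.intp)
    padded[:record.length] = record.token_ids
    x = max_total_length // segment_length
    return SegmentedProtein(segments=padded.reshape(x, segment_length),
                            total_length=max_total_length)


def mask_for_mlm(token_ids: np.ndarray, mask_rate: float,
                 rng: np.random.Generator | int,
                 bert_mixing: bool = False):
    """Corrupt ``round(mask_rate × #non-PAD)`` positions (at least one).

    Only non-PAD positions are candidates; each selected position is
    replaced with MASK (or, with ``bert_mixing``, the BERT 80/10/10
    MASK / random-residue / keep mixture). Returns the corrupted copy
    and the sorted array of selected positions. Deterministic for a
    fixed seed or generator state.
    """
    if not 0.0 < mask_rate < 1.0:
        raise ConfigError("mask_rate must be in (0, 1)")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    candidates = np.flatnonzero(token_ids != PAD)
    if candidates.size == 0:
        raise DataError("cannot mask an all-PAD sequence")
    n_mask = max(1, int(round(mask_rate * candidates.size)))
    chosen = np.sort(rng.choice(candidates, size=n_mask, replace=False))
    corrupted = token_ids.copy()
    if bert_mixing:
        u = rng.random(n_mask)
        for pos, r in zip(chosen, u):
            if r < 0.8:
                corrupted[pos] = MASK
            elif r < 0.9:
                corrupted[pos] = rng.integers(0, len(AMINO_ACIDS))
            # else keep the original token
    else:
        corrupted[chosen] = MASK
    return corrupted, chosen


class MLMEncoder(ParamModule):
    """Transformer encoder with token + position embeddings and a
    per-position vocabulary head."""

    PRESETS = {
        "base": dict(d_model=32, n_layers=2, n_heads=2, d_ff=64),
        "large": dict(d_model=64, n_layers=4, n_heads=4, d_ff=128),
    }

    def __init__(self, rng: np.random.Generator, d_model: int = 32,
                 n_layers: int = 2, n_heads: int = 2, d_ff: int = 64,
                 max_len: int = 1024, vocab_size: int = VOCAB_SIZE):
        self.d_model = d_model
        self.max_len = max_len
        self.vocab_size = vocab_size
        scale = 1.0 / np.sqrt(d_model)
        self.tok_emb = Tensor(rng.normal(0, scale, (vocab_size, d_model)),
                              requires_grad=True)
        self.pos_emb = Tensor(rng.normal(0, scale, (max_len, d_model)),
                              requires_grad=True)
        self.blocks = [SelfAttentionBlock(rng, d_model, n_heads, d_ff)
                       for _ in range(n_layers)]
        self.final_norm = LayerNorm(d_model)
        self.head_hidden = Linear(rng, d_model, d_model)
        self.head_out = Linear(rng, d_model, vocab_size)

    @classmethod
    def from_preset(cls, rng: np.random.Generator, size: str = "base",
                    max_len: int = 1024) -> "MLMEncoder":
        if size not in cls.PRESETS:
            raise ConfigError(f"unknown MLM size {size!r}; use base or large")
        return cls(rng, max_len=max_len, **cls.PRESETS[size])

    def __call__(self, token_ids: np.ndarray):
        """Returns (vocabulary scores [L, V], pooled embedding [d_model]).

        Pooling averages final hidden states over non-PAD positions.
        """
        L = len(token_ids)
        if L > self.max_len:
            raise ConfigError(
                f"sequence length {L} exceeds position table {self.max_len}")
        x = self.tok_emb.take(np.asarray(token_ids)) + \
            self.pos_emb.take(np.arange(L))
        for block in self.blocks:
            x = block(x)
        x = self.final_norm(x)
        scores = self.head_out(self.head_hidden(x).relu())
        non_pad = np.flatnonzero(np.asarray(token_ids) != PAD)
        if non_pad.size == 0:
            raise DataError("cannot pool an all-PAD sequence")
        pooled = x.take(non_pad).mean(axis=0)
        return scores, pooled


def mlm_loss(scores: Tensor, masked_positions: np.ndarray,
             true_ids: np.ndarray) -> Tensor:
    """Mean cross-entropy over the masked positions only."""
    pos = np.asarray(masked_positions)
    if pos.size == 0:
        raise DataError("empty masked-position set")
    logp = scores.take(pos).log_softmax(axis=-1)
    targets = np.asarray(true_ids)[pos]
    picked = logp * Tensor(np.eye(scores.shape[1])[targets])
    return -(picked.sum(axis=1).mean())


class CPCEncoder(ParamModule):
    """Shared per-segment encoder: embedding, conv/norm/ReLU blocks, pooling."""

    def __init__(self, rng: np.random.Generator, d_emb: int = 16,
                 channels: tuple[int, ...] = (32, 32), kernel_size: int = 3,
                 d_out: int = 16, vocab_size: int = VOCAB_SIZE):
        self.kernel_size = kernel_size
        self.d_out = d_out
        scale = 1.0 / np.sqrt(d_emb)
        self.emb = Tensor(rng.normal(0, scale, (vocab_size, d_emb)),
                          requires_grad=True)
        self.conv_w: list[Tensor] = []
        self.conv_b: list[Tensor] = []
        self.norms: list[LayerNorm] = []
        c_in = d_emb
        for c_out in channels:
            self.conv_w.append(Tensor(glorot(rng, kernel_size * c_in, c_out),
                                      requires_grad=True))
            self.conv_b.append(Tensor(np.zeros(c_out), requires_grad=True))
            self.norms.append(LayerNorm(c_out))
            c_in = c_out
        self.proj = Linear(rng, c_in, d_out)

    def _conv(self, x: Tensor, w: Tensor, b: Tensor) -> Tensor:
        """Valid 1-D convolution along axis 1 of x: [x, L, c] → [x, L', c_out]."""
        n_seg, L, c = x.shape
        k = self.kernel_size
        L_out = L - k + 1
        if L_out < 1:
            raise ConfigError(
                f"segment length {L} too short for kernel size {k}")
        win = np.arange(L_out)[:, None] + np.arange(k)[None, :]
        # [x, L, c] -> [L, x, c] -> gather windows -> [x, L', k*c]
        t = x.transpose(1, 0, 2)
        unfolded = t.take(win).transpose(2, 0, 1, 3).reshape(n_seg, L_out, k * c)
        return unfolded @ w + b

    def __call__(self, seg: SegmentedProtein) -> Tensor:
        """Encode every segment independently → z matrix [x, d_out]."""
        x = self.emb.take(seg.segments)          # [x, L_s, d_emb]
        for w, b, norm in zip(self.conv_w, self.conv_b, self.norms):
            x = norm(self._conv(x, w, b)).relu()
        return self.proj(x.mean(axis=1))


class InfoNCEHead(ParamModule):
    """Per-step bilinear scorers mapping context to predicted future segments."""

    def __init__(self, rng: np.random.Generator, d_ctx: int, d_c: int,
                 n_steps: int = 1):
        if n_steps < 1:
            raise ConfigError("prediction steps K must be >= 1")
        self.n_steps = n_steps
        self.maps = [Tensor(glorot(rng, d_ctx, d_c), requires_grad=True)
                     for _ in range(n_steps)]


def infonce_loss(c: Tensor, z: Tensor, head: InfoNCEHead,
                 negatives: Tensor):
    """InfoNCE over future-segment prediction.

    For every anchor position t <= x−K and step k <= K the true future
    segment z_{t+k} is scored against the negative rows through the
    bilinear map c_t W_k z. Returns (mean softmax cross-entropy of
    identifying the true segment, contrastive accuracy). Ties in the
    argmax split their credit evenly among the tied candidates.
    """
    x = z.shape[0]
    K = head.n_steps
    if x <= K:
        raise DataError(
            f"need more than K={K} segments for a positive pair, got {x}")
    if negatives.shape[0] < 1:
        raise DataError("at least one negative row is required")
    losses = []
    acc_credit = []
    for k in range(1, K + 1):
        W = head.maps[k - 1]
        pred = c.take(np.arange(x - k)) @ W           # [x-k, d_c]
        cands = concat([z.take(np.arange(k, x)).reshape(x - k, 1, -1),
                        _tile(negatives, x - k)], axis=1)  # [x-k, 1+N, d_c]
        logits = (cands * pred.reshape(x - k, 1, -1)).sum(axis=2)
        logp = logits.log_softmax(axis=1)
        # the true segment sits at candidate index 0
        losses.append(-(logp * Tensor(
            np.eye(logits.shape[1])[np.zeros(x - k, dtype=int)])).sum(axis=1))
        row = logits.data
        mx = row.max(axis=1, keepdims=True)
        ties = (row == mx)
        acc_credit.extend(ties[:, 0] / ties.sum(axis=1))
    loss = concat(losses, axis=0).mean()
    accuracy = float(np.mean(acc_credit))
    return loss, accuracy


def _tile(t: Tensor, n: int) -> Tensor:
    """Repeat a [N, d] tensor into [n, N, d] keeping gradients."""
    return concat([t.reshape(1, *t.shape)] * n, axis=0)


class ProteinEmbedder(ParamModule):
    """Both branches plus segmentation config; produces E_p for fusion."""

    def __init__(self, rng: np.random.Generator, segment_length: int = 11,
                 max_total_length: int = 990, mlm_size: str = "base",
                 mlm_kwargs: dict | None = None,
                 cpc_kwargs: dict | None = None, cpc_steps: int = 1):
        if max_total_length % segment_length:
            raise ConfigError("max_total_length must be a multiple of "
                              "segment_length")
        self.segment_length = segment_length
        self.max_total_length = max_total_length
        if mlm_kwargs is not None:
            self.mlm = MLMEncoder(rng, max_len=max_total_length, **mlm_kwargs)
        else:
            self.mlm = MLMEncoder.from_preset(rng, mlm_size,
                                              max_len=max_total_length)
        self.cpc = CPCEncoder(rng, **(cpc_kwargs or {}))
        self.gru = GRU(rng, self.cpc.d_out, self.cpc.d_out)
        self.nce = InfoNCEHead(rng, self.cpc.d_out, self.cpc.d_out,
                               n_steps=cpc_steps)

    @property
    def n_segments(self) -> int:
        return self.max_total_length // self.segment_length

    @property
    def embed_dim(self) -> int:
        return self.cpc.d_out + self.mlm.d_model

    def segment(self, record: ProteinRecord):
        return segment_protein(record, self.segment_length,
                               self.max_total_length)

    def embed_tensors(self, record: ProteinRecord):
        """Differentiable E_p: per-segment [z_t, pooled-MLM] rows.

        Returns (E_p Tensor [x, d_c + d_mlm], z, pooled) or raises
        :class:`DataError` for proteins longer than the configured
        maximum.
        """
        seg = self.segment(record)
        if seg is DISCARDED:
            raise DataError(
                f"protein of length {record.length} exceeds the configured "
                f"maximum {self.max_total_length}")
        padded = seg.segments.reshape(-1)
        _, pooled = self.mlm(padded)
        z = self.cpc(seg)
        x = z.shape[0]
        mlm_rows = _tile(pooled.reshape(1, -1), x).reshape(x, -1)
        return concat([z, mlm_rows], axis=1), z, pooled

    def protein_embedding(self, record: ProteinRecord) -> ProteinEmbedding:
        """Deterministic numpy view of the combined representation."""
        combined, z, pooled = self.embed_tensors(record)
        return ProteinEmbedding(mlm_part=pooled.data.copy(),
                                cpc_locals=z.data.copy(),
                                combined=combined.data.copy())
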