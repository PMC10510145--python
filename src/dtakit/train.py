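"""Pretraining and affinity-training loops, checkpointing and inference.

The composite model glues the three encoders together:

    SMILES ──MolEncoder──► E_m ─┐
                                ├─ attention fusion ──► MLP ──► ŷ
    sequence ─ProteinEmbedder─► E_p ┘

Checkpoints are single ``.npz`` archives holding every parameter array
plus the JSON-encoded config and a format version, so a reload is
bit-exact. All loops draw randomness from generators derived from the
config seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._autodiff import Tensor, no_grad, stack
from ._nn import Adam, ParamModule
from .chem import ATOM_FEATURE_DIM, BOND_FEATURE_DIM, smiles_to_graph
from .config import ModelConfig
from .data import DtaDataset, SplitIndices
from .errors import ConfigError, DataError, NumericError, SmilesParseError
from .fusion import FusionPredictor, training_loss
from .metrics import concordance_index, mse
from .mol_encoder import MolEncoder
from .prot_encoder import (DISCARDED, ProteinEmbedder, encode_sequence,
                           infonce_loss, length_filter, mask_for_mlm, mlm_loss)

__all__ = [
    "DTAModel", "save_checkpoint", "load_checkpoint", "pretrain_protein",
    "train_dta", "evaluate", "predict", "TrainResult",
]

CHECKPOINT_VERSION = 1


class DTAModel(ParamModule):
    """Molecule encoder + protein embedder + attention fusion head."""

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.mol = MolEncoder(rng, ATOM_FEATURE_DIM, BOND_FEATURE_DIM,
                              hidden_dim=config.hidden_dim, depth=config.depth,
                              dropout_rate=config.dropout_rate)
        self.prot = ProteinEmbedder(
            rng, segment_length=config.segment_length,
            max_total_length=config.max_total_length,
            mlm_size=config.mlm_size, mlm_kwargs=config.mlm_overrides,
            cpc_kwargs=config.cpc_kwargs, cpc_steps=config.cpc_steps)
        self.fusion = FusionPredictor(
            rng, d_mol=config.hidden_dim, d_prot=self.prot.embed_dim,
            d_att=config.attention_dim, mlp_hidden=config.mlp_hidden)
        self._graph_cache: dict[str, object] = {}
        self._record_cache: dict[str, object] = {}

    # ---------------------------------------------------------------- lookup
    def graph(self, smiles: str):
        if smiles not in self._graph_cache:
            self._graph_cache[smiles] = smiles_to_graph(smiles)
        return self._graph_cache[smiles]

    def record(self, sequence: str):
        if sequence not in self._record_cache:
            self._record_cache[sequence] = encode_sequence(sequence)
        return self._record_cache[sequence]

    # --------------------------------------------------------------- forward
    def predict_pair(self, smiles: str, sequence: str, training: bool = False,
                     rng: np.random.Generator | None = None) -> Tensor:
        e_mol = self.mol.encode(self.graph(smiles), training=training, rng=rng)
        e_prot, _, _ = self.prot.embed_tensors(self.record(sequence))
        return self.fusion(e_mol, e_prot)


# ------------------------------------------------------------- checkpointing
def save_checkpoint(path: str | Path, module: ParamModule,
                    config: ModelConfig) -> Path:
    path = Path(path)
    arrays = module.state_dict()
    meta = json.dumps({"version": CHECKPOINT_VERSION,
                       "config": config.to_dict()})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path: str | Path):
    """Returns (state dict name→array, ModelConfig)."""
    with np.load(Path(path)) as archive:
        if "__meta__" not in archive:
            raise ConfigError(f"{path} is not a dtakit checkpoint")
        meta = json.loads(archive["__meta__"].tobytes().decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ConfigError(
                f"checkpoint format version {meta.get('version')} is not "
                f"supported (expected {CHECKPOINT_VERSION})")
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    return state, ModelConfig.from_dict(meta["config"])


def load_model(path: str | Path) -> DTAModel:
    state, config = load_checkpoint(path)
    model = DTAModel(config)
    model.load_state(state)
    return model


# ----------------------------------------------------------------- pretraining
def _read_fasta(path: str | Path) -> list[str]:
    from Bio import SeqIO

    return [str(r.seq) for r in SeqIO.parse(str(path), "fasta")]


def pretrain_protein(corpus: str | Path | list[str], config: ModelConfig,
                     steps: int | None = None, out_path: str | Path | None = None,
                     log=lambda msg: None):
    """Self-supervised pretraining of both protein branches.

    ``corpus`` is a FASTA path or a list of sequences; records outside
    the [pretrain_min_len, pretrain_max_len] window are dropped, and
    longer-than-L_t proteins are discarded by segmentation. MLM and
    InfoNCE objectives are optimised on alternating batches (or summed
    each batch with ``pretrain_objective='joint'``). Returns the
    embedder and the per-step loss history.
    """
    seqs = _read_fasta(corpus) if isinstance(corpus, (str, Path)) else list(corpus)
    records = list(length_filter((encode_sequence(s) for s in seqs),
                                 config.pretrain_min_len, config.pretrain_max_len))
    records = [r for r in records
               if r.length <= config.max_total_length]
    if not records:
        raise DataError("pretraining corpus is empty after length filtering")

    rng = np.random.default_rng(config.seed)
    embedder = ProteinEmbedder(
        rng, segment_length=config.segment_length,
        max_total_length=config.max_total_length, mlm_size=config.mlm_size,
        mlm_kwargs=config.mlm_overrides, cpc_kwargs=config.cpc_kwargs,
        cpc_steps=config.cpc_steps)
    opt = Adam(embedder.parameters(), lr=config.learning_rate)
    n_steps = steps if steps is not None else config.epochs * max(
        1, len(records) // config.batch_size)

    history = {"mlm": [], "cpc": [], "cpc_accuracy": []}

    def mlm_batch(batch):
        losses = []
        for rec in batch:
            seg = embedder.segment(rec)
            ids = seg.segments.reshape(-1)
            corrupted, positions = mask_for_mlm(ids, config.mask_rate, rng,
                                                bert_mixing=config.bert_mixing)
            scores, _ = embedder.mlm(corrupted)
            losses.append(mlm_loss(scores, positions, ids))
        return sum(losses[1:], start=losses[0]) * (1.0 / len(losses))

    def cpc_batch(batch):
        zs = []
        for rec in batch:
            zs.append(embedder.cpc(embedder.segment(rec)))
        losses, accs = [], []
        for i, z in enumerate(zs):
            others = [zs[j] for j in range(len(zs)) if j != i]
            if not others:
                raise DataError("CPC needs at least two proteins per batch")
            pool = np.concatenate([z.data for z in others], axis=0)
            take = rng.choice(len(pool), size=min(config.n_negatives, len(pool)),
                              replace=False)
            # negatives are scored but not backpropagated through, which
            # keeps each protein's graph independent
            negatives = Tensor(pool[take])
            c = embedder.gru(z)
            loss, acc = infonce_loss(c, z, embedder.nce, negatives)
            losses.append(loss)
            accs.append(acc)
        return (sum(losses[1:], start=losses[0]) * (1.0 / len(losses)),
                float(np.mean(accs)))

    for step in range(n_steps):
        batch_idx = rng.choice(len(records),
                               size=min(config.batch_size, len(records)),
                               replace=False)
        batch = [records[i] for i in batch_idx]
        opt.zero_grad()
        if config.pretrain_objective == "joint":
            l_mlm = mlm_batch(batch)
            l_cpc, acc = cpc_batch(batch)
            total = l_mlm + l_cpc
            total.backward()
            history["mlm"].append(l_mlm.item())
            history["cpc"].append(l_cpc.item())
            history["cpc_accuracy"].append(acc)
        elif step % 2 == 0:
            l_mlm = mlm_batch(batch)
            l_mlm.backward()
            history["mlm"].append(l_mlm.item())
        else:
            l_cpc, acc = cpc_batch(batch)
            l_cpc.backward()
            history["cpc"].append(l_cpc.item())
            history["cpc_accuracy"].append(acc)
        opt.step()
        if (step + 1) % 10 == 0:
            log(f"pretrain step={step + 1} "
                f"mlm={history['mlm'][-1] if history['mlm'] else float('nan'):.4f} "
                f"cpc={history['cpc'][-1] if history['cpc'] else float('nan'):.4f}")

    if out_path is not None:
        save_checkpoint(out_path, embedder, config)
    return embedder, history


# ------------------------------------------------------------------ DTA loop
@dataclass
class TrainResult:
    model: DTAModel
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    test_mse: float = float("nan")
    test_ci: float = float("nan")


def _usable_rows(dataset: DtaDataset, indices, model: DTAModel,
                 log=lambda m: None):
    rows = []
    dropped = 0
    for i in indices:
        s, q, y = dataset.row(int(i))
        if len(q) > model.config.max_total_length:
            dropped += 1
            continue
        rows.append((s, q, y))
    if dropped:
        log(f"dropped {dropped} row(s) with proteins longer than "
            f"{model.config.max_total_length}")
    if not rows:
        raise DataError("no usable rows after length filtering")
    return rows


def _batch_predictions(model: DTAModel, rows, training=False, rng=None) -> Tensor:
    return stack([model.predict_pair(s, q, training=training, rng=rng)
                  for s, q, _ in rows])


def train_dta(dataset: DtaDataset, split: SplitIndices, config: ModelConfig,
              pretrained: str | Path | None = None,
              freeze_protein: bool | None = None,
              target_train_mse: float | None = None,
              log=lambda msg: None) -> TrainResult:
    """Mini-batch training of the full affinity model.

    Minimises the MSE + L2 objective, tracks validation MSE per epoch,
    restores the best-validation parameters, and reports test MSE/CI.
    Optionally warm-starts the protein branches from a pretraining
    checkpoint and/or freezes them. ``target_train_mse`` stops early
    once the running training MSE drops below it.
    """
    model = DTAModel(config)
    if pretrained is not None:
        state, pre_cfg = load_checkpoint(pretrained)
        if (pre_cfg.segment_length != config.segment_length
                or pre_cfg.max_total_length != config.max_total_length):
            raise ConfigError("pretrained checkpoint segmentation does not "
                              "match the model config")
        model.prot.load_state(state)
    freeze = config.freeze_protein if freeze_protein is None else freeze_protein
    params = model.parameters()
    if freeze:
        params = {k: v for k, v in params.items() if not k.startswith("prot.")}
    opt = Adam(params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)

    train_rows = _usable_rows(dataset, split.train, model, log)
    valid_rows = _usable_rows(dataset, split.valid, model, log) \
        if len(split.valid) else []
    test_rows = _usable_rows(dataset, split.test, model, log) \
        if len(split.test) else []

    result = TrainResult(model=model)
    best_val = np.inf
    best_state = model.state_dict()
    stop = False
    for epoch in range(config.epochs):
        order = rng.permutation(len(train_rows))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            rows = [train_rows[i] for i in order[start:start + config.batch_size]]
            opt.zero_grad()
            preds = _batch_predictions(model, rows, training=True, rng=rng)
            loss = training_loss(preds, [y for *_, y in rows],
                                 params=model.parameters(),
                                 l2_coeff=config.l2_coeff)
            value = loss.item()
            if not np.isfinite(value):
                raise NumericError(
                    f"training diverged: loss={value} at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        train_loss = float(np.mean(epoch_losses))
        entry = {"epoch": epoch, "train_loss": train_loss}
        if valid_rows:
            val_mse = _eval_rows(model, valid_rows)["mse"]
            entry["valid_mse"] = val_mse
            if val_mse < best_val:
                best_val = val_mse
                best_state = model.state_dict()
                result.best_epoch = epoch
        result.history.append(entry)
        log(f"epoch={epoch} train_loss={train_loss:.5f}"
            + (f" valid_mse={entry['valid_mse']:.5f}" if valid_rows else ""))
        if target_train_mse is not None:
            train_mse = _eval_rows(model, train_rows)["mse"]
            entry["train_mse"] = train_mse
            if train_mse < target_train_mse:
                stop = True
        if stop:
            break
    if valid_rows:
        model.load_state(best_state)
    if test_rows:
        m = _eval_rows(model, test_rows)
        result.test_mse, result.test_ci = m["mse"], m["ci"]
        log(f"test mse={result.test_mse:.5f} ci={result.test_ci:.5f}")
    return result


def _eval_rows(model: DTAModel, rows) -> dict:
    with no_grad():
        preds = np.array([model.predict_pair(s, q).item() for s, q, _ in rows])
    labels = np.array([y for *_, y in rows])
    out = {"mse": mse(preds, labels)}
    try:
        out["ci"] = concordance_index(preds, labels)
    except Exception:
        out["ci"] = float("nan")
    return out


def evaluate(model: DTAModel | str | Path, rows) -> dict:
    """Deterministic test-time metrics {mse, ci} for (smiles, seq, label) rows."""
    if not isinstance(model, DTAModel):
        model = load_model(model)
    rows = list(rows)
    if not rows:
        raise DataError("nothing to evaluate")
    with no_grad():
        preds = np.array([model.predict_pair(s, q).item() for s, q, _ in rows])
    labels = np.array([y for *_, y in rows])
    return {"mse": mse(preds, labels), "ci": concordance_index(preds, labels)}


def predict(model: DTAModel | str | Path, smiles_list: list[str],
            sequence: str):
    """Rank molecules against one protein by predicted affinity.

    Returns (table, rejects): the table rows are (smiles, prediction,
    rank) sorted by descending prediction with input-order tie-breaks;
    unparseable SMILES land in rejects with their error message.
    """
    if not isinstance(model, DTAModel):
        model = load_model(model)
    scored, rejects = [], []
    with no_grad():
        for pos, s in enumerate(smiles_list):
            try:
                val = model.predict_pair(s, sequence).item()
            except (SmilesParseError, DataError) as exc:
                rejects.append((s, str(exc)))
                continue
            scored.append((pos, s, val))
    scored.sort(key=lambda t: (-t[2], t[0]))
    table = [(s, v, rank + 1) for rank, (_, s, v) in enumerate(scored)]
    return table, rejects
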