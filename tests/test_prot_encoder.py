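"""Protein tokenisation, segmentation, masking, and both branch objectives."""

import math

import numpy as np
import pytest

from dtakit._autodiff import Tensor
from dtakit.errors import ConfigError, DataError
from dtakit.prot_encoder import (AMINO_ACIDS, DISCARDED, MASK, PAD, VOCAB_SIZE,
                                 CPCEncoder, InfoNCEHead, MLMEncoder,
                                 ProteinEmbedder, encode_sequence,
                                 infonce_loss, length_filter, mask_for_mlm,
                                 mlm_loss, segment_protein)

from oracles import (conv1d_scalar, gru_scalar, max_relative_error,
                     softmax_xent_scalar)


def _random_seq(rng, length):
    return "".join(rng.choice(list(AMINO_ACIDS), size=length))


def _toy_embedder(rng, **kw):
    defaults = dict(segment_length=11, max_total_length=66,
                    mlm_kwargs=dict(d_model=16, n_layers=1, n_heads=2, d_ff=32),
                    cpc_kwargs=dict(d_emb=8, channels=(16,), kernel_size=3,
                                    d_out=8))
    defaults.update(kw)
    return ProteinEmbedder(rng, **defaults)


# ----------------------------------------------------------- tokens & filter
def test_tokenisation_roundtrip_and_unk():
    rec = encode_sequence("ACDX")
    assert rec.token_ids.tolist() == [0, 1, 2, 22]
    assert rec.length == 4
    with pytest.raises(DataError):
        encode_sequence("")


def test_length_filter_inclusive_bounds(rng):
    seqs = {69: None, 70: None, 1000: None, 1001: None}
    records = [encode_sequence(_random_seq(rng, n)) for n in seqs]
    kept = list(length_filter(records, 70, 1000))
    assert sorted(r.length for r in kept) == [70, 1000]
    assert list(length_filter([], 70, 1000)) == []


def test_length_filter_count_matches_hand_count(rng):
    lengths = rng.integers(50, 1051, size=100)
    records = [encode_sequence(_random_seq(rng, n)) for n in lengths]
    kept = list(length_filter(records, 70, 1000))
    assert len(kept) == int(np.sum((lengths >= 70) & (lengths <= 1000)))


# -------------------------------------------------------------- segmentation
def test_segmentation_arithmetic(rng):
    rec = encode_sequence(_random_seq(rng, 110))
    seg = segment_protein(rec, 11, 110)
    assert seg.n_segments == 10 and seg.segments.shape == (10, 11)

    too_long = encode_sequence(_random_seq(rng, 111))
    assert segment_protein(too_long, 11, 110) is DISCARDED

    short = encode_sequence(_random_seq(rng, 95))
    seg = segment_protein(short, 11, 110)
    padded = seg.segments.reshape(-1)
    assert (padded == PAD).sum() == 15
    np.testing.assert_array_equal(padded[:95], short.token_ids)
    assert np.all(padded[95:] == PAD)
    assert seg.n_segments == 10


def test_segmentation_config_errors(rng):
    rec = encode_sequence(_random_seq(rng, 10))
    with pytest.raises(ConfigError):
        segment_protein(rec, 7, 110)          # 110 not a multiple of 7


# ------------------------------------------------------------------- masking
def test_masking_budget_length_1000(rng):
    ids = encode_sequence(_random_seq(rng, 1000)).token_ids
    corrupted, pos = mask_for_mlm(ids, 0.15, 7)
    assert len(pos) == 150
    assert np.all(corrupted[pos] == MASK)
    untouched = np.setdiff1d(np.arange(1000), pos)
    np.testing.assert_array_equal(corrupted[untouched], ids[untouched])


def test_masking_minimum_one_position(rng):
    ids = encode_sequence("A").token_ids
    _, pos = mask_for_mlm(ids, 0.15, 0)
    assert len(pos) == 1


def test_masking_skips_pad_and_rejects_all_pad(rng):
    ids = np.concatenate([encode_sequence(_random_seq(rng, 20)).token_ids,
                          np.full(20, PAD)])
    _, pos = mask_for_mlm(ids, 0.15, 3)
    assert np.all(pos < 20) and len(pos) == 3   # round(0.15 * 20)
    with pytest.raises(DataError):
        mask_for_mlm(np.full(5, PAD), 0.15, 0)


def test_masking_deterministic_per_seed_and_overlap_across_seeds(rng):
    ids = encode_sequence(_random_seq(rng, 1000)).token_ids
    _, a = mask_for_mlm(ids, 0.15, 11)
    _, b = mask_for_mlm(ids, 0.15, 11)
    np.testing.assert_array_equal(a, b)
    # for independent draws, |overlap| is hypergeometric with mean
    # 150·150/1000 = 22.5; average over 40 pairs stays well inside ±4σ/√40
    overlaps = []
    for s in range(40):
        _, c = mask_for_mlm(ids, 0.15, 1000 + s)
        _, d = mask_for_mlm(ids, 0.15, 2000 + s)
        overlaps.append(len(np.intersect1d(c, d)))
    assert 19.0 < np.mean(overlaps) < 26.0


def test_masking_budget_property(rng):
    for _ in range(200):
        n = int(rng.integers(1, 400))
        ids = encode_sequence(_random_seq(rng, n)).token_ids
        _, pos = mask_for_mlm(ids, 0.15, rng)
        assert len(pos) == max(1, round(0.15 * n))


# ---------------------------------------------------------------- MLM branch
def test_zero_head_gives_uniform_scores_and_lnV_loss(rng):
    enc = MLMEncoder(rng, d_model=16, n_layers=1, n_heads=2, d_ff=32,
                     max_len=64)
    enc.head_out.W.data[...] = 0.0
    enc.head_out.b.data[...] = 0.0
    ids = encode_sequence(_random_seq(rng, 30)).token_ids
    corrupted, pos = mask_for_mlm(ids, 0.15, 0)
    scores, _ = enc(corrupted)
    assert np.ptp(scores.data) == 0.0           # uniform scores
    loss = mlm_loss(scores, pos, ids)
    assert loss.item() == pytest.approx(math.log(VOCAB_SIZE), rel=1e-12)


def test_mlm_loss_perfect_scores_and_scalar_oracle():
    ids = np.array([0, 3, 5, 2])
    # perfect (near-one-hot) scores at the masked positions
    scores = Tensor(np.eye(VOCAB_SIZE)[ids] * 1e4)
    assert mlm_loss(scores, np.array([1, 2]), ids).item() == pytest.approx(0.0, abs=1e-12)
    rng = np.random.default_rng(4)
    raw = rng.normal(size=(2, VOCAB_SIZE))
    got = mlm_loss(Tensor(raw), np.array([0, 1]), np.array([7, 9])).item()
    want = np.mean([softmax_xent_scalar(raw[0].tolist(), 7),
                    softmax_xent_scalar(raw[1].tolist(), 9)])
    assert got == pytest.approx(want, rel=1e-12)
    with pytest.raises(DataError):
        mlm_loss(Tensor(raw), np.array([]), ids)


def test_mlm_pooling_excludes_pad(rng):
    enc = MLMEncoder(rng, d_model=16, n_layers=1, n_heads=2, d_ff=32,
                     max_len=64)
    ids = encode_sequence(_random_seq(rng, 20)).token_ids
    padded = np.concatenate([ids, np.full(10, PAD)])
    _, pooled = enc(padded)
    assert pooled.shape == (16,)
    with pytest.raises(DataError):
        enc(np.full(10, PAD))


def test_mlm_position_table_overflow(rng):
    enc = MLMEncoder(rng, d_model=16, n_layers=1, n_heads=2, d_ff=32,
                     max_len=8)
    with pytest.raises(ConfigError):
        enc(np.zeros(9, dtype=int))


# ---------------------------------------------------------------- CPC branch
def test_identical_segments_encode_identically(rng):
    emb = _toy_embedder(rng)
    rec = encode_sequence("ACDEFGHIKLM" * 6)     # 6 identical segments
    z = emb.cpc(emb.segment(rec)).data
    for row in z[1:]:
        np.testing.assert_allclose(row, z[0], atol=1e-12)


def test_all_pad_segment_is_finite(rng):
    emb = _toy_embedder(rng)
    rec = encode_sequence(_random_seq(rng, 11))  # 5 of 6 segments all-PAD
    z = emb.cpc(emb.segment(rec)).data
    assert np.all(np.isfinite(z))


def test_cpc_convolution_matches_scalar_oracle(rng):
    enc = CPCEncoder(rng, d_emb=4, channels=(5,), kernel_size=3, d_out=3)
    seg_ids = rng.integers(0, 20, size=(2, 7))
    x = enc.emb.data[seg_ids]                    # [2, 7, 4]
    got = enc._conv(Tensor(x), enc.conv_w[0], enc.conv_b[0]).data
    for s in range(2):
        want = conv1d_scalar(x[s].tolist(), enc.conv_w[0].data.tolist(),
                             enc.conv_b[0].data.tolist(), 3)
        assert max_relative_error(got[s], np.array(want)) < 1e-10


def test_autoregressor_is_causal_and_matches_recurrence(rng):
    emb = _toy_embedder(rng)
    z = rng.normal(size=(6, 8))
    c = emb.gru(Tensor(z)).data
    # causality: perturbing the last input leaves earlier contexts unchanged
    z2 = z.copy()
    z2[-1] += 1.0
    c2 = emb.gru(Tensor(z2)).data
    np.testing.assert_array_equal(c[:-1], c2[:-1])
    assert not np.array_equal(c[-1], c2[-1])
    # x = 1: context depends only on the single input
    c1 = emb.gru(Tensor(z[:1])).data
    np.testing.assert_allclose(c1[0], c[0], atol=1e-12)
    # unrolled scalar recurrence oracle
    weights = {k: v.data.tolist() for k, v in emb.gru.parameters().items()}
    want = gru_scalar(z.tolist(), weights)
    assert max_relative_error(c, np.array(want)) < 1e-5


# ----------------------------------------------------------------- InfoNCE
def test_infonce_chance_level_with_equal_scores(rng):
    head = InfoNCEHead(rng, 4, 4, n_steps=1)
    head.maps[0].data[...] = 0.0                # all logits equal
    c = Tensor(rng.normal(size=(2, 4)))
    z = Tensor(rng.normal(size=(2, 4)))
    negatives = Tensor(rng.normal(size=(1, 4)))
    loss, acc = infonce_loss(c, z, head, negatives)
    assert loss.item() == pytest.approx(math.log(2), rel=1e-12)
    assert acc == pytest.approx(0.5)


def test_infonce_separable_limit(rng):
    head = InfoNCEHead(rng, 2, 2, n_steps=1)
    head.maps[0].data[...] = np.eye(2) * 50.0
    z = Tensor(np.array([[1.0, 0.0], [1.0, 0.0]]))
    c = Tensor(np.array([[1.0, 0.0], [1.0, 0.0]]))
    negatives = Tensor(np.array([[-1.0, 0.0]]))
    loss, acc = infonce_loss(c, z, head, negatives)
    assert loss.item() == pytest.approx(0.0, abs=1e-12)
    assert acc == 1.0


def test_infonce_matches_hand_computed_softmax(rng):
    head = InfoNCEHead(rng, 3, 3, n_steps=1)
    c = Tensor(rng.normal(size=(4, 3)))
    z = Tensor(rng.normal(size=(4, 3)))
    negatives = Tensor(rng.normal(size=(3, 3)))
    loss, _ = infonce_loss(c, z, head, negatives)
    W = head.maps[0].data
    per_anchor = []
    for t in range(3):
        pred = c.data[t] @ W
        logits = [float(pred @ z.data[t + 1])] + \
            [float(pred @ n) for n in negatives.data]
        per_anchor.append(softmax_xent_scalar(logits, 0))
    assert loss.item() == pytest.approx(np.mean(per_anchor), rel=1e-10)


def test_infonce_requires_a_positive_pair(rng):
    head = InfoNCEHead(rng, 3, 3, n_steps=2)
    with pytest.raises(DataError):
        infonce_loss(Tensor(rng.normal(size=(2, 3))),
                     Tensor(rng.normal(size=(2, 3))), head,
                     Tensor(rng.normal(size=(1, 3))))


# -------------------------------------------------------- combined embedding
def test_embedding_shape_is_segments_by_concat_width(rng):
    emb = ProteinEmbedder(np.random.default_rng(0), segment_length=11,
                          max_total_length=110,
                          mlm_kwargs=dict(d_model=8, n_layers=1, n_heads=2,
                                          d_ff=16),
                          cpc_kwargs=dict(d_emb=8, channels=(8,),
                                          kernel_size=3, d_out=8))
    e = emb.protein_embedding(encode_sequence(_random_seq(rng, 90)))
    assert e.combined.shape == (10, 16)
    assert e.cpc_locals.shape == (10, 8)
    assert e.mlm_part.shape == (8,)
    np.testing.assert_array_equal(e.combined[:, 8:],
                                  np.tile(e.mlm_part, (10, 1)))


def test_embedding_deterministic_and_pad_invariant(rng):
    emb = _toy_embedder(rng)
    seq = _random_seq(rng, 40)
    a = emb.protein_embedding(encode_sequence(seq))
    b = emb.protein_embedding(encode_sequence(seq))
    np.testing.assert_array_equal(a.combined, b.combined)


def test_zero_cpc_parameters_make_locals_constant(rng):
    emb = _toy_embedder(rng)
    for p in emb.cpc.parameters().values():
        p.data[...] = 0.0
    e = emb.protein_embedding(encode_sequence(_random_seq(rng, 50)))
    for row in e.combined[1:]:
        np.testing.assert_allclose(row, e.combined[0], atol=1e-12)


def test_too_long_protein_is_rejected_for_embedding(rng):
    emb = _toy_embedder(rng)
    with pytest.raises(DataError):
        emb.embed_tensors(encode_sequence(_random_seq(rng, 67)))
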