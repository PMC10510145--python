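"""Dataset reading, validation and deterministic splitting."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = ["DtaDataset", "SplitIndices", "read_dta", "make_split"]

_REQUIRED = ("smiles", "sequence", "affinity")


@dataclass
class DtaDataset:
    """Validated (smiles, sequence, affinity) rows plus their origin."""

    frame: pd.DataFrame
    provenance: str = ""

    def __len__(self):
        return len(self.frame)

    def row(self, i: int) -> tuple[str, str, float]:
        r = self.frame.iloc[i]
        return str(r["smiles"]), str(r["sequence"]), float(r["affinity"])


@dataclass
class SplitIndices:
    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray
    ratio: tuple[float, float, float]
    seed: int


def read_dta(path: str | Path, delimiter: str = ",",
             columns: tuple[str, str, str] = _REQUIRED) -> DtaDataset:
    """Read a delimited DTA table with a header row.

    Raises :class:`DataError` naming missing columns, or listing every
    malformed row (empty fields / non-numeric or non-finite affinity)
    with its 1-based file line number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")
    smiles_col, seq_col, aff_col = columns
    bad: list[str] = []
    affinities = []
    for i, r in df.iterrows():
        line = i + 2  # header on line 1
        if not str(r[smiles_col]).strip():
            bad.append(f"line {line}: empty SMILES")
            affinities.append(np.nan)
            continue
        if not str(r[seq_col]).strip():
            bad.append(f"line {line}: empty sequence")
            affinities.append(np.nan)
            continue
        try:
            a = float(r[aff_col])
        except ValueError:
            bad.append(f"line {line}: non-numeric affinity {r[aff_col]!r}")
            affinities.append(np.nan)
            continue
        if not np.isfinite(a):
            bad.append(f"line {line}: non-finite affinity {a}")
        affinities.append(a)
    if bad:
        raise DataError(f"{path}: {len(bad)} malformed row(s): " + "; ".join(bad))
    out = pd.DataFrame({
        "smiles": df[smiles_col].astype(str),
        "sequence": df[seq_col].astype(str),
        "affinity": np.asarray(affinities, dtype=np.float64),
    })
    return DtaDataset(frame=out, provenance=str(path))


def make_split(n: int, ratio: tuple[float, float, float] = (0.8, 0.1, 0.1),
               seed: int = 0) -> SplitIndices:
    """Shuffle then partition indices 0..n-1.

    Rounding rule: |train| = round(r_train·n); the remainder is divided
    between valid and test proportionally (floored), and any leftover
    samples go back to train.
    """
    if abs(sum(ratio) - 1.0) > 1e-9:
        raise ConfigError(f"split ratio must sum to 1, got {ratio}")
    if n < 1:
        raise DataError("cannot split an empty dataset")
    r_train, r_valid, r_test = ratio
    n_train = int(round(r_train * n))
    rem = n - n_train
    tail = r_valid + r_test
    n_valid = int(rem * r_valid / tail) if tail > 0 else 0
    n_test = int(rem * r_test / tail) if tail > 0 else 0
    n_train = n - n_valid - n_test
    perm = np.random.default_rng(seed).permutation(n)
    return SplitIndices(
        train=perm[:n_train],
        valid=perm[n_train:n_train + n_valid],
        test=perm[n_train + n_valid:],
        ratio=tuple(ratio), seed=seed,
    )
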