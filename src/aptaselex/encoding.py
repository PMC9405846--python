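"""Input encodings for the binding model.

Aptamer sequences become padded one-hot matrices: A, C, G and U map to the
rows {1000}, {0100}, {0010} and {0001}, and sequences shorter than the pad
length (default 100, the longest aptamer the model is designed for) are
completed with all-zero pad rows.  The pad row is deliberately {0000} rather
than a fifth channel: it keeps the channel dimension at four and is inert
under convolution.

Target molecules are encoded as MACCS structural keys — a fixed catalogue of
166 substructure queries — giving a 166-bit presence/absence vector from the
molecule's SMILES.  SMILES are canonicalised first so any two notations of
the same structure yield the same fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from sklearn.model_selection import train_test_split

from aptaselex.library import RNA_ALPHABET, RnaSequence

DEFAULT_PAD_LENGTH = 100
MACCS_BITS = 166

_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}


@dataclass(frozen=True)
class OneHotSequence:
    """A pad_length x 4 binary matrix encoding one aptamer sequence."""

    matrix: np.ndarray
    source_id: str

    @property
    def pad_length(self) -> int:
        return self.matrix.shape[0]

    @property
    def seq_length(self) -> int:
        return int(self.matrix.sum())


@dataclass(frozen=True)
class TargetFingerprint:
    """166-bit MACCS structural-key vector plus the canonical SMILES."""

    bits: np.ndarray
    smiles: str

    def __post_init__(self) -> None:
        if self.bits.shape != (MACCS_BITS,):
            raise ValueError(
                f"MACCS fingerprint must have {MACCS_BITS} bits, "
                f"got shape {self.bits.shape}"
            )


@dataclass(frozen=True)
class EncodedPair:
    """One model input record: encoded aptamer, encoded target, optional label."""

    aptamer: OneHotSequence
    target: TargetFingerprint
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")


def one_hot_encode(
    seq: RnaSequence | str, pad_length: int = DEFAULT_PAD_LENGTH
) -> OneHotSequence:
    """Encode a sequence as a ``pad_length x 4`` one-hot matrix.

    Rows beyond the sequence length are all-zero pad rows.  A sequence longer
    than ``pad_length`` is rejected.
    """
    if isinstance(seq, str):
        seq = RnaSequence(id="", bases=seq)
    if len(seq) > pad_length:
        raise ValueError(
            f"sequence {seq.id!r} of length {len(seq)} exceeds pad length "
            f"{pad_length}"
        )
    mat = np.zeros((pad_length, 4), dtype=np.float32)
    for i, b in enumerate(seq.bases):
        mat[i, _BASE_INDEX[b]] = 1.0
    return OneHotSequence(matrix=mat, source_id=seq.id)


def one_hot_decode(enc: OneHotSequence) -> str:
    """Invert :func:`one_hot_encode` on the non-pad prefix."""
    out = []
    for row in enc.matrix:
        if row.sum() == 0:
            break
        out.append(RNA_ALPHABET[int(np.argmax(row))])
    return "".join(out)


def maccs_fingerprint(smiles: str) -> TargetFingerprint:
    """MACCS structural keys of a molecule as a 166-bit vector.

    The SMILES is canonicalised before key generation, so all equivalent
    notations of a structure map to the identical fingerprint.  The key
    catalogue's unused leading bit is dropped, leaving exactly the 166
    defined structural keys.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"could not parse SMILES {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    keys = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 always unset
    bits = np.zeros(MACCS_BITS, dtype=np.float32)
    for b in keys.GetOnBits():
        bits[b - 1] = 1.0
    return TargetFingerprint(bits=bits, smiles=canonical)


def encode_pair(
    sequence: str | RnaSequence,
    smiles: str,
    label: Optional[int] = None,
    pad_length: int = DEFAULT_PAD_LENGTH,
) -> EncodedPair:
    return EncodedPair(
        aptamer=one_hot_encode(sequence, pad_length),
        target=maccs_fingerprint(smiles),
        label=None if label is None else int(label),
    )


def assemble_dataset(
    pairs: pd.DataFrame,
    train_fraction: float = 0.8,
    seed: int = 0,
    pad_length: int = DEFAULT_PAD_LENGTH,
) -> tuple[list[EncodedPair], list[EncodedPair]]:
    """Encode a (sequence, smiles, label) table and split it 80/20.

    The split is stratified by label so both classes appear in the training
    set whenever both are present overall, and is reproducible from ``seed``.
    Distinct SMILES are fingerprinted once and the result reused.
    """
    required = {"sequence", "smiles", "label"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"dataset table missing columns: {sorted(missing)}")
    n = len(pairs)
    if n < 5:
        raise ValueError(f"dataset too small to split: {n} rows (need >= 5)")
    labels = pairs["label"].to_numpy()
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be 0 or 1")

    fp_cache = {s: maccs_fingerprint(s) for s in pairs["smiles"].unique()}
    encoded = [
        EncodedPair(
            aptamer=one_hot_encode(
                RnaSequence(id=f"row_{i}", bases=row.sequence), pad_length
            ),
            target=fp_cache[row.smiles],
            label=int(row.label),
        )
        for i, row in enumerate(pairs.itertuples(index=False))
    ]
    stratify = labels if len(np.unique(labels)) > 1 else None
    idx_train, idx_test = train_test_split(
        np.arange(n),
        train_size=train_fraction,
        random_state=seed,
        stratify=stratify,
        shuffle=True,
    )
    return [encoded[i] for i in idx_train], [encoded[i] for i in idx_test]


def encode_table(
    pairs: pd.DataFrame, pad_length: int = DEFAULT_PAD_LENGTH
) -> list[EncodedPair]:
    """Encode every row of a (sequence, smiles, label) table, no split."""
    fp_cache = {s: maccs_fingerprint(s) for s in pairs["smiles"].unique()}
    return [
        EncodedPair(
            aptamer=one_hot_encode(
                RnaSequence(id=f"row_{i}", bases=row.sequence), pad_length
            ),
            target=fp_cache[row.smiles],
            label=int(row.label),
        )
        for i, row in enumerate(pairs.itertuples(index=False))
    ]


def stack_pairs(
    pairs: Sequence[EncodedPair],
) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Stack encoded pairs into model-ready arrays (Xseq, Xfp, y).

    ``y`` is None when any record lacks a label (inference-time input).
    """
    xseq = np.stack([p.aptamer.matrix for p in pairs])
    xfp = np.stack([p.target.bits for p in pairs])
    if any(p.label is None for p in pairs):
        return xseq, xfp, None
    y = np.array([p.label for p in pairs], dtype=np.float32)
    return xseq, xfp, y
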