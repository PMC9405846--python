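"""Synthetic labelled aptamer–target datasets with a planted binding rule.

Curated literature corpora of aptamer–small-molecule pairs are rarely
deposited, so model training and validation here run on synthetic data whose
ground truth is known by construction: a pair is a binder exactly when the
aptamer carries a planted sequence motif AND the target belongs to a
designated binder pool.  The rule is analytic — independent of any folding
engine or physics — which turns the learning test into parameter recovery:
a model that reaches high held-out accuracy has demonstrably recovered the
planted association, no more and no less.

Positives pair a motif-bearing random sequence with a binder-pool target.
Negatives break exactly one arm of the rule, half-and-half: either a
motif-free sequence with a binder target (the sequence branch must notice),
or a non-binder target whose sequence carries the motif with probability
1/2 (the fingerprint branch must notice).  Labels can then be flipped with
a configurable noise probability.

Default pool sizes mirror a realistic literature corpus scale
(621 positives, 835 negatives, ≈43% positive).  The default target pools are
small nitrogenous analytes: ammonium-like binders versus methylated-amine
and alcohol interferents.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from aptaselex.library import RNA_ALPHABET

DEFAULT_MOTIF = "GGAUCC"
DEFAULT_BINDER_POOL = ("[NH4+]", "N", "NCCO")
DEFAULT_NONBINDER_POOL = ("CNC", "CN(C)C", "CO", "CCO")


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the planted-rule dataset generator."""

    n_pos: int = 621
    n_neg: int = 835
    motif: str = DEFAULT_MOTIF
    label_noise: float = 0.0
    binder_pool: tuple[str, ...] = DEFAULT_BINDER_POOL
    nonbinder_pool: tuple[str, ...] = DEFAULT_NONBINDER_POOL
    seq_length_range: tuple[int, int] = (20, 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos <= 0 or self.n_neg <= 0:
            raise ValueError("n_pos and n_neg must be positive")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        lo, hi = self.seq_length_range
        if lo > hi or lo <= 0:
            raise ValueError(f"invalid seq_length_range {self.seq_length_range}")
        if len(self.motif) > lo:
            raise ValueError(
                f"motif of length {len(self.motif)} exceeds minimum sequence "
                f"length {lo}"
            )
        if set(self.motif) - set(RNA_ALPHABET):
            raise ValueError("motif must be over {A,C,G,U}")
        if not self.binder_pool or not self.nonbinder_pool:
            raise ValueError("both target pools must be non-empty")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(RNA_ALPHABET[i] for i in rng.integers(0, 4, size=length))


def _seq_with_motif(rng: np.random.Generator, length: int, motif: str) -> str:
    s = _random_seq(rng, length)
    pos = int(rng.integers(0, length - len(motif) + 1))
    return s[:pos] + motif + s[pos + len(motif):]


def _seq_without_motif(rng: np.random.Generator, length: int, motif: str) -> str:
    # rejection sampling; accidental motifs are rare enough that this terminates fast
    while True:
        s = _random_seq(rng, length)
        if motif not in s:
            return s


def generate_binding_dataset(spec: SynthSpec) -> pd.DataFrame:
    """Generate a (sequence, smiles, label) table under the planted rule.

    Rows are fully determined by the given SynthSpec (including its seed).  Before
    noise, labels follow the rule exactly: label 1 iff the sequence contains
    the motif and the target is in the binder pool.  Noise flips each label
    independently with probability ``label_noise``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.seq_length_range
    rows: list[dict] = []
    for _ in range(spec.n_pos):
        length = int(rng.integers(lo, hi + 1))
        rows.append(
            {
                "sequence": _seq_with_motif(rng, length, spec.motif),
                "smiles": spec.binder_pool[rng.integers(len(spec.binder_pool))],
                "label": 1,
            }
        )
    for i in range(spec.n_neg):
        length = int(rng.integers(lo, hi + 1))
        if i % 2 == 0:  # binder target, motif-free sequence
            seq = _seq_without_motif(rng, length, spec.motif)
            smiles = spec.binder_pool[rng.integers(len(spec.binder_pool))]
        else:  # non-binder target; motif present half the time
            if rng.random() < 0.5:
                seq = _seq_with_motif(rng, length, spec.motif)
            else:
                seq = _seq_without_motif(rng, length, spec.motif)
            smiles = spec.nonbinder_pool[rng.integers(len(spec.nonbinder_pool))]
        rows.append({"sequence": seq, "smiles": smiles, "label": 0})
    df = pd.DataFrame(rows)
    if spec.label_noise > 0:
        flips = rng.random(len(df)) < spec.label_noise
        df.loc[flips, "label"] = 1 - df.loc[flips, "label"]
    return df


def planted_truth(spec: SynthSpec) -> Callable[[str, str], int]:
    """The Bayes-optimal classifier for the planted rule.

    Returns a callable (sequence, smiles) -> {0,1} that answers 1 exactly
    when the motif is present and the target is in the binder pool.  On a
    noise-free dataset it is perfect; under label noise its accuracy is
    1 - label_noise in expectation, the achievable ceiling.
    """
    binders = set(spec.binder_pool)

    def oracle(sequence: str, smiles: str) -> int:
        return int(spec.motif in sequence and smiles in binders)

    return oracle
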