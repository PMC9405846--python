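"""Model-based screening and docking-score selectivity ranking.

The trained binding model is run over every filtered-library candidate
against the positive target; candidates whose predicted binding probability
clears the decision threshold move on.  Survivors are then ranked by their
docking free energies: a candidate is kept only if it binds the positive
target strongly (energy at or below ``pos_energy_max``) while binding every
negative target weakly (energy at or above ``neg_energy_min``), and the kept
set is ordered by positive-target energy, most negative first.  Ties are
broken by the weakest (largest) minimum negative-target energy, then
lexicographically by sequence, so the ranking is fully deterministic.

Docking itself is external: this module ingests tabulated scores (TSV) or
uses a deterministic pseudo-scorer for end-to-end plumbing tests.  Energies
are free energies throughout — more negative means stronger binding.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from aptaselex.encoding import maccs_fingerprint, one_hot_encode, DEFAULT_PAD_LENGTH
from aptaselex.library import RnaSequence
from aptaselex.structure import SecondaryStructure

_SCORE_COLUMNS = ["candidate_id", "target_id", "energy_kcal_mol", "n_runs"]


@dataclass(frozen=True)
class DockingScore:
    """Mean docking energy of one (candidate, target) pair over n_runs runs."""

    candidate_id: str
    target_id: str
    energy_kcal_mol: float
    n_runs: int = 1

    def __post_init__(self) -> None:
        if not np.isfinite(self.energy_kcal_mol):
            raise ValueError(
                f"docking energy for ({self.candidate_id}, {self.target_id}) "
                "is not finite"
            )
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass(frozen=True)
class CandidateRecord:
    """A candidate flowing through the screening funnel."""

    sequence: RnaSequence
    binding_prob: float
    structure: Optional[SecondaryStructure] = None
    pos_energy: Optional[float] = None
    neg_energies: dict = field(default_factory=dict)
    rank: Optional[int] = None


@dataclass(frozen=True)
class SelectivityPolicy:
    """Two-threshold keep rule for the counter-selection step.

    Keep a candidate iff its positive-target energy is <= ``pos_energy_max``
    (binds the analyte at least this strongly) and every negative-target
    energy is >= ``neg_energy_min`` (binds each interferent no more strongly
    than this).  Defaults are read off the published survivor energy range
    for an ammonium target with methylamine interferents.
    """

    pos_energy_max: float = -6.6
    neg_energy_min: float = -5.5

    def __post_init__(self) -> None:
        if self.pos_energy_max >= 0:
            raise ValueError("pos_energy_max must be negative (a free energy)")


def screen_library(
    model,
    survivors: Sequence[RnaSequence | tuple[RnaSequence, SecondaryStructure]],
    target_smiles: str,
    threshold: float = 0.5,
    batch_size: int = 256,
) -> list[CandidateRecord]:
    """Predict binding of every candidate to the target; keep prob >= threshold.

    ``model`` is anything with ``predict_proba(xseq, xfp) -> probs`` over
    stacked one-hot/fingerprint arrays (the trained two-branch CNN, or a stub
    in tests).  Output is sorted by probability descending, ties broken
    lexicographically by sequence, so any partition of the input screened
    separately and merged reproduces the identical result.
    """
    items: list[tuple[RnaSequence, Optional[SecondaryStructure]]] = []
    for entry in survivors:
        if isinstance(entry, tuple):
            items.append((entry[0], entry[1]))
        else:
            items.append((entry, None))
    if not items:
        return []
    pad = getattr(getattr(model, "config", None), "pad_length", DEFAULT_PAD_LENGTH)
    fp = maccs_fingerprint(target_smiles)
    kept: list[CandidateRecord] = []
    for start in range(0, len(items), batch_size):
        chunk = items[start : start + batch_size]
        xseq = np.stack([one_hot_encode(s, pad).matrix for s, _ in chunk])
        xfp = np.tile(fp.bits, (len(chunk), 1))
        probs = model.predict_proba(xseq, xfp)
        for (seq, ss), p in zip(chunk, probs):
            if p >= threshold:
                kept.append(
                    CandidateRecord(sequence=seq, binding_prob=float(p), structure=ss)
                )
    kept.sort(key=lambda r: (-r.binding_prob, r.sequence.bases))
    return kept


def read_scores(path: str | Path) -> list[DockingScore]:
    """Read a docking-score TSV (candidate_id, target_id, energy_kcal_mol, n_runs).

    Duplicate (candidate, target) rows — replicate runs tabulated separately —
    are merged into one score: the run-weighted mean energy with n_runs summed.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"candidate_id": str, "target_id": str})
    missing = set(_SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing score columns {sorted(missing)}")
    energies = pd.to_numeric(df["energy_kcal_mol"], errors="coerce")
    bad = energies.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based incl. header
        raise ValueError(
            f"{path}: non-numeric energy at line {row}: "
            f"{df['energy_kcal_mol'].iloc[row - 2]!r}"
        )
    df = df.assign(energy_kcal_mol=energies, n_runs=df["n_runs"].astype(int))
    out: list[DockingScore] = []
    for (cand, target), grp in df.groupby(["candidate_id", "target_id"], sort=False):
        w = grp["n_runs"].to_numpy()
        out.append(
            DockingScore(
                candidate_id=cand,
                target_id=target,
                energy_kcal_mol=float(np.average(grp["energy_kcal_mol"], weights=w)),
                n_runs=int(w.sum()),
            )
        )
    return out


def mock_docking(
    candidates: Sequence[RnaSequence],
    targets: Sequence[str],
    seed: int = 0,
    n_runs: int = 10,
) -> list[DockingScore]:
    """Deterministic pseudo-docking scores for end-to-end plumbing tests.

    Energies are hash-derived from (sequence, target, seed) — stable across
    runs and platforms — and uniform over a plausible [-12, 0] kcal/mol
    range.  They carry no physics whatsoever.
    """
    out = []
    for seq in candidates:
        for target in targets:
            digest = hashlib.sha256(
                f"{seq.bases}|{target}|{seed}".encode()
            ).digest()
            u = int.from_bytes(digest[:8], "big") / 2**64
            out.append(
                DockingScore(
                    candidate_id=seq.id,
                    target_id=target,
                    energy_kcal_mol=-12.0 * u,
                    n_runs=n_runs,
                )
            )
    return out


def rank_selectivity(
    candidates: Sequence[CandidateRecord],
    pos_scores: Iterable[DockingScore],
    neg_scores: Iterable[DockingScore],
    policy: SelectivityPolicy | None = None,
) -> list[CandidateRecord]:
    """Counter-selection: keep selective candidates and rank by positive energy.

    Every candidate must have a positive-target score (hard error otherwise);
    negative-target scores are optional per target.  Kept candidates satisfy
    the policy thresholds; rank 1 is the most negative positive-target
    energy.  Ties break by the largest minimum negative-target energy (the
    least cross-reactive candidate first), then lexicographically.
    """
    policy = policy or SelectivityPolicy()
    pos_by_cand = {s.candidate_id: s for s in pos_scores}
    neg_by_cand: dict[str, dict[str, float]] = {}
    for s in neg_scores:
        neg_by_cand.setdefault(s.candidate_id, {})[s.target_id] = s.energy_kcal_mol

    kept = []
    for cand in candidates:
        cid = cand.sequence.id
        if cid not in pos_by_cand:
            raise KeyError(
                f"candidate {cid!r} has no positive-target docking score"
            )
        pos_e = pos_by_cand[cid].energy_kcal_mol
        negs = neg_by_cand.get(cid, {})
        if pos_e > policy.pos_energy_max:
            continue
        if any(e < policy.neg_energy_min for e in negs.values()):
            continue
        kept.append(replace(cand, pos_energy=pos_e, neg_energies=dict(negs)))

    def sort_key(rec: CandidateRecord):
        worst_neg = min(rec.neg_energies.values()) if rec.neg_energies else 0.0
        return (rec.pos_energy, -worst_neg, rec.sequence.bases)

    kept.sort(key=sort_key)
    return [replace(rec, rank=i + 1) for i, rec in enumerate(kept)]


def ranked_table(records: Sequence[CandidateRecord]) -> pd.DataFrame:
    """Ranked screening output as a DataFrame (TSV-friendly)."""
    rows = []
    for rec in records:
        worst = min(rec.neg_energies.values()) if rec.neg_energies else np.nan
        rows.append(
            {
                "rank": rec.rank,
                "id": rec.sequence.id,
                "sequence": rec.sequence.bases,
                "binding_prob": rec.binding_prob,
                "pos_energy": rec.pos_energy,
                "worst_neg_energy": worst,
            }
        )
    return pd.DataFrame(rows)
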