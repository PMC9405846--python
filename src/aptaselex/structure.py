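"""Secondary-structure folding and the thermodynamic candidate filter.

Each candidate is folded to its minimum-free-energy (MFE) secondary structure
and kept only if it is stably folded (MFE below a ΔG threshold, default
−5 kcal/mol) while still presenting enough single-stranded, accessible
nucleotides bounded above (default ≤ 20 unpaired positions).  Unpaired
positions are the ``'.'`` characters of the dot-bracket string — loops,
bulges and dangling ends alike, the only definition computable from the
dot-bracket alone.

Two folding engines are provided behind a common interface:

* :class:`ViennaRNAEngine` — the nearest-neighbor thermodynamic model of the
  ViennaRNA package (default 37 °C, Turner parameters).  This is the engine
  the pipeline's energies are meant to come from.
* :class:`MaxPairingEngine` — a Nussinov-style maximum-pairing fallback whose
  "energies" are a fixed pseudo-energy per canonical pair.  It exists so the
  package imports and tests run with zero third-party folding dependency;
  its energies are NOT thermodynamic and it is intended for tests and
  plumbing only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

from aptaselex.library import RnaSequence

# canonical pairs recognised by the fallback engine: Watson-Crick + wobble
_CANONICAL = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


@dataclass(frozen=True)
class SecondaryStructure:
    """Dot-bracket string, MFE in kcal/mol, and the unpaired-position count."""

    dotbracket: str
    mfe_kcal_mol: float
    unpaired_count: int

    def __post_init__(self) -> None:
        if self.unpaired_count != self.dotbracket.count("."):
            raise ValueError(
                "unpaired_count inconsistent with dot-bracket: "
                f"{self.unpaired_count} != {self.dotbracket.count('.')}"
            )
        depth = 0
        for ch in self.dotbracket:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise ValueError(f"unbalanced dot-bracket: {self.dotbracket!r}")
            elif ch != ".":
                raise ValueError(f"invalid dot-bracket character {ch!r}")
        if depth != 0:
            raise ValueError(f"unbalanced dot-bracket: {self.dotbracket!r}")


@dataclass(frozen=True)
class FilterPolicy:
    """The two-condition thermodynamic keep rule.

    A candidate passes iff its MFE is strictly below ``dg_threshold_kcal_mol``
    (stably folded) and it has at most ``max_unpaired`` unpaired nucleotides.
    """

    dg_threshold_kcal_mol: float = -5.0
    max_unpaired: int = 20

    def __post_init__(self) -> None:
        if self.max_unpaired < 0:
            raise ValueError("max_unpaired must be >= 0")


@dataclass(frozen=True)
class FilterStats:
    n_input: int
    n_survivors: int

    @property
    def survival_fraction(self) -> float:
        return self.n_survivors / self.n_input if self.n_input else 0.0


class FoldingEngine(Protocol):
    def fold(self, bases: str) -> tuple[str, float]:
        """Return (dot-bracket, MFE in kcal/mol) for an RNA base string."""
        ...


class ViennaRNAEngine:
    """Nearest-neighbor thermodynamic MFE folding via the ViennaRNA bindings.

    Parameters are ViennaRNA defaults; ``temperature`` is in °C (default 37).
    """

    def __init__(self, temperature: float = 37.0) -> None:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover - environment dependent
            raise RuntimeError(
                "ViennaRNA python bindings are not available; install the "
                "ViennaRNA package or use the 'fallback' MaxPairingEngine "
                "(test-only, non-thermodynamic energies)"
            ) from exc
        self._RNA = RNA
        self.temperature = float(temperature)

    def fold(self, bases: str) -> tuple[str, float]:
        if self.temperature == 37.0:
            db, mfe = self._RNA.fold(bases)
        else:
            md = self._RNA.md()
            md.temperature = self.temperature
            fc = self._RNA.fold_compound(bases, md)
            db, mfe = fc.mfe()
        return db, float(mfe)


class MaxPairingEngine:
    """Nussinov-style maximum base-pairing fallback engine (test-only energies).

    Maximises the number of canonical (Watson-Crick + GU wobble) pairs with a
    minimum hairpin loop of ``min_loop`` unpaired nucleotides, and reports a
    fixed pseudo-energy of ``pair_energy`` kcal/mol per pair.  The structure
    is a legal nested dot-bracket, but the energy scale is NOT thermodynamic:
    use it for plumbing and tests, not for real candidate triage.
    """

    def __init__(self, pair_energy: float = -1.0, min_loop: int = 3) -> None:
        if pair_energy >= 0:
            raise ValueError("pair_energy must be negative")
        self.pair_energy = float(pair_energy)
        self.min_loop = int(min_loop)

    def fold(self, bases: str) -> tuple[str, float]:
        n = len(bases)
        h = self.min_loop
        # best[i][j] = max pairs in bases[i..j]
        best = [[0] * n for _ in range(n)]
        for span in range(h + 1, n):
            for i in range(n - span):
                j = i + span
                cand = best[i][j - 1]
                for k in range(i, j - h):
                    paired = (bases[k], bases[j]) in _CANONICAL
                    if paired:
                        left = best[i][k - 1] if k > i else 0
                        inner = best[k + 1][j - 1] if k + 1 <= j - 1 else 0
                        cand = max(cand, left + inner + 1)
                best[i][j] = cand
        structure = ["."] * n

        def traceback(i: int, j: int) -> None:
            if j - i <= h:
                return
            if best[i][j] == best[i][j - 1]:
                traceback(i, j - 1)
                return
            for k in range(i, j - h):
                if (bases[k], bases[j]) in _CANONICAL:
                    left = best[i][k - 1] if k > i else 0
                    inner = best[k + 1][j - 1] if k + 1 <= j - 1 else 0
                    if best[i][j] == left + inner + 1:
                        structure[k] = "("
                        structure[j] = ")"
                        if k > i:
                            traceback(i, k - 1)
                        if k + 1 <= j - 1:
                            traceback(k + 1, j - 1)
                        return
            raise AssertionError("traceback failed")  # pragma: no cover

        if n > 0:
            traceback(0, n - 1)
        n_pairs = best[0][n - 1] if n > 0 else 0
        return "".join(structure), n_pairs * self.pair_energy


def get_engine(name: str = "vienna", **kwargs) -> FoldingEngine:
    """Engine factory: ``"vienna"`` (thermodynamic) or ``"fallback"``."""
    if name == "vienna":
        return ViennaRNAEngine(**kwargs)
    if name == "fallback":
        return MaxPairingEngine(**kwargs)
    raise ValueError(f"unknown folding engine {name!r}")


def fold(seq: RnaSequence, engine: FoldingEngine) -> SecondaryStructure:
    """Fold one candidate to its MFE structure under the given engine."""
    db, mfe = engine.fold(seq.bases)
    return SecondaryStructure(
        dotbracket=db, mfe_kcal_mol=mfe, unpaired_count=db.count(".")
    )


def passes_filter(ss: SecondaryStructure, policy: FilterPolicy) -> bool:
    """True iff MFE < ΔG threshold and unpaired count ≤ the cap."""
    return (
        ss.mfe_kcal_mol < policy.dg_threshold_kcal_mol
        and ss.unpaired_count <= policy.max_unpaired
    )


def filter_library(
    seqs: Iterable[RnaSequence],
    policy: FilterPolicy | None = None,
    engine: FoldingEngine | None = None,
) -> tuple[list[tuple[RnaSequence, SecondaryStructure]], FilterStats]:
    """Fold every candidate and keep those passing the policy, order preserved.

    Returns the surviving (sequence, structure) pairs and a
    :class:`FilterStats` with input count, survivor count and survival
    fraction.  An empty input yields empty survivors and zero counts.
    """
    policy = policy or FilterPolicy()
    engine = engine or ViennaRNAEngine()
    survivors: list[tuple[RnaSequence, SecondaryStructure]] = []
    n_input = 0
    for seq in seqs:
        n_input += 1
        ss = fold(seq, engine)
        if passes_filter(ss, policy):
            survivors.append((seq, ss))
    return survivors, FilterStats(n_input=n_input, n_survivors=len(survivors))


def structure_table(
    seqs: Sequence[RnaSequence],
    policy: FilterPolicy | None = None,
    engine: FoldingEngine | None = None,
):
    """Per-candidate folding/filter report as a DataFrame (TSV-friendly)."""
    import pandas as pd

    policy = policy or FilterPolicy()
    engine = engine or ViennaRNAEngine()
    rows = []
    for seq in seqs:
        ss = fold(seq, engine)
        rows.append(
            {
                "id": seq.id,
                "sequence": seq.bases,
                "dotbracket": ss.dotbracket,
                "mfe_kcal_mol": ss.mfe_kcal_mol,
                "unpaired": ss.unpaired_count,
                "pass": passes_filter(ss, policy),
            }
        )
    return pd.DataFrame(rows)
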