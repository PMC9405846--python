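"""Random RNA candidate libraries: generation, deduplication and FASTA I/O.

A selection experiment starts from a pool of unique random oligonucleotides.
Candidates are drawn uniformly and i.i.d. over the RNA alphabet {A, C, G, U};
duplicates are discarded and redrawn so the returned pool contains exactly the
requested number of distinct sequences.  The default candidate length is 27
nucleotides (~6 nm), short enough to stay within the Debye screening length of
an electrochemical sensor surface.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

RNA_ALPHABET = "ACGU"
_BASES = np.frombuffer(RNA_ALPHABET.encode(), dtype="S1")


@dataclass(frozen=True)
class RnaSequence:
    """A single RNA candidate: an identifier plus its base string.

    Raises ``ValueError`` for an empty sequence or characters outside {A,C,G,U}.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"RNA sequence {self.id!r} is empty")
        invalid = set(self.bases) - set(RNA_ALPHABET)
        if invalid:
            raise ValueError(
                f"RNA sequence {self.id!r} contains characters outside "
                f"{{A,C,G,U}}: {sorted(invalid)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class LibraryConfig:
    """Parameters of the random library draw.

    n_candidates unique sequences of the given length are generated from the
    seeded uniform distribution.  Uniqueness is impossible when n_candidates
    exceeds 4**length, which is rejected up front.
    """

    n_candidates: int
    length: int = 27
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"length must be positive, got {self.length}")
        if self.n_candidates <= 0:
            raise ValueError(
                f"n_candidates must be positive, got {self.n_candidates}"
            )
        if self.n_candidates > 4 ** self.length:
            raise ValueError(
                f"cannot draw {self.n_candidates} unique sequences of length "
                f"{self.length}: only 4^{self.length} = {4 ** self.length} exist"
            )


def generate_library(config: LibraryConfig) -> list[RnaSequence]:
    """Draw ``config.n_candidates`` unique random RNA sequences.

    Bases are i.i.d. uniform over {A,C,G,U}.  Collisions with already-drawn
    sequences are discarded and redrawn, so the output always holds exactly
    the requested number of distinct base strings, in draw order.  Identifiers
    are zero-padded ordinals (``cand_0000001`` ...), stable sort keys for the
    downstream funnel.  The same config (including seed) reproduces the same
    library exactly.
    """
    rng = np.random.default_rng(config.seed)
    seen: set[str] = set()
    ordered: list[str] = []
    remaining = config.n_candidates
    while remaining > 0:
        # over-draw slightly so a handful of collisions rarely forces a second pass
        batch = max(remaining + 16, int(remaining * 1.05))
        draws = _BASES[rng.integers(0, 4, size=(batch, config.length))]
        for row in draws.view(f"S{config.length}").ravel():
            s = row.decode()
            if s not in seen:
                seen.add(s)
                ordered.append(s)
                remaining -= 1
                if remaining == 0:
                    break
    width = max(7, len(str(config.n_candidates)))
    return [
        RnaSequence(id=f"cand_{i + 1:0{width}d}", bases=s)
        for i, s in enumerate(ordered)
    ]


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    """Write sequences as single-line FASTA records (ids preserved)."""
    with open(path, "w") as fh:
        for seq in seqs:
            rec = SeqRecord(Seq(seq.bases), id=seq.id, description="")
            fh.write(format(rec, "fasta-2line"))


def read_fasta(path: str | Path, t_to_u: bool = False) -> list[RnaSequence]:
    """Read RNA sequences from FASTA, accepting arbitrary line wrapping.

    With ``t_to_u`` set, thymine characters are transliterated to uracil so
    DNA-formatted files of RNA designs can be ingested.  A file whose first
    record is malformed (sequence data before any header) raises a parse
    error with the offending line number; a record containing characters
    outside the alphabet raises a validation error naming the record.
    """
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if not stripped.startswith(">"):
            raise ValueError(
                f"{path}: malformed FASTA at line {lineno}: "
                "sequence data before any '>' header"
            )
        break
    out: list[RnaSequence] = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        bases = str(rec.seq).upper()
        if t_to_u:
            bases = bases.replace("T", "U")
        try:
            out.append(RnaSequence(id=rec.id, bases=bases))
        except ValueError as exc:
            raise ValueError(f"{path}: record {rec.id!r}: {exc}") from exc
    return out


def base_frequencies(seqs: Sequence[RnaSequence]) -> dict[str, float]:
    """Overall per-base frequencies across a pool (composition diagnostic)."""
    counts = dict.fromkeys(RNA_ALPHABET, 0)
    total = 0
    for seq in seqs:
        for b in seq.bases:
            counts[b] += 1
        total += len(seq)
    return {b: c / total for b, c in counts.items()}
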