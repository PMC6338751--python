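"""Reference genome container: the single source of truth for dinucleotide context.

Sequences are held in memory as upper-case strings, which is adequate for the
megabase-scale genomes this package works with. ``GenomeRef`` is the only
object that answers sequence queries; every filter and counter goes through it
so that coordinate conventions (0-based, half-open, + strand storage) are
applied in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

__all__ = ["GenomeRef", "revcomp", "DEFAULT_MITO_NAMES"]

DEFAULT_MITO_NAMES = frozenset({"chrM", "MT"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeRef:
    """Chromosome name -> + strand sequence, with mitochondrial flags."""

    sequences: dict[str, str]
    mito_chroms: frozenset[str] = DEFAULT_MITO_NAMES

    _lengths: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.sequences = {c: s.upper() for c, s in self.sequences.items()}
        self._lengths = {c: len(s) for c, s in self.sequences.items()}

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self._lengths)

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    def is_mito(self, chrom: str) -> bool:
        return chrom in self.mito_chroms

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the + strand sequence of [start, end); strict bounds."""
        if chrom not in self.sequences:
            raise KeyError(f"chromosome {chrom!r} not in genome")
        if start < 0 or end > self._lengths[chrom] or start > end:
            raise ValueError(
                f"interval [{start}, {end}) out of bounds for {chrom} "
                f"(length {self._lengths[chrom]})"
            )
        return self.sequences[chrom][start:end]

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_fasta(cls, path: str | Path, mito_chroms=DEFAULT_MITO_NAMES) -> "GenomeRef":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        seqs = {name: str(fa[name][:]) for name in fa.keys()}
        fa.close()
        return cls(seqs, frozenset(mito_chroms))

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
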