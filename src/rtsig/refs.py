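"""Reference sequence handling.

References are short, single-stranded, template-sense RNA species (tRNA- or
rRNA-scale, at most a few kb).  Sequences are stored DNA-style: uppercase over
{A, C, G, T, N}, with U normalized to T so that they compare directly against
mapped read bases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_ALPHABET = frozenset("ACGTN")


def normalize_sequence(seq: str) -> str:
    """Uppercase, U->T; raise on characters outside {A,C,G,T,N}."""
    s = str(seq).upper().replace("U", "T")
    bad = set(s) - _ALPHABET
    if bad:
        raise ValueError(f"sequence contains invalid characters: {sorted(bad)}")
    if not s:
        raise ValueError("empty reference sequence")
    return s


@dataclass
class ReferenceSet:
    """Ordered collection of named reference sequences.

    Invariants: ids unique, sequences non-empty, alphabet {A,C,G,T,N}.
    """

    sequences: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequences = {rid: normalize_sequence(s) for rid, s in self.sequences.items()}

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSet":
        seqs: Dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate reference id {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise ValueError(f"no sequences found in {path}")
        return cls(seqs)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=rid, description="") for rid, seq in self.sequences.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    def __contains__(self, rid: str) -> bool:
        return rid in self.sequences

    def __getitem__(self, rid: str) -> str:
        return self.sequences[rid]

    def __iter__(self) -> Iterator[Tuple[str, str]]:
        return iter(self.sequences.items())

    def __len__(self) -> int:
        return len(self.sequences)

    def length(self, rid: str) -> int:
        return len(self.sequences[rid])

    def base(self, rid: str, pos: int) -> str:
        """Reference base at 1-based position ``pos``; '-' outside the sequence."""
        seq = self.sequences[rid]
        if 1 <= pos <= len(seq):
            return seq[pos - 1]
        return "-"
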