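"""Species-labelled reference transcriptomes (FASTA-backed)."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .tags import InputError


@dataclass
class ReferenceTranscriptome:
    """Transcript sequences for one species, used for tag attribution."""

    species: str
    ids: list[str] = field(default_factory=list)
    sequences: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.sequences):
            raise InputError("ids and sequences differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("transcript ids must be unique")
        allowed = set("ACGTN")
        for tid, seq in zip(self.ids, self.sequences):
            if set(seq) - allowed:
                raise InputError(f"transcript {tid} has non-ACGTN characters")

    def __len__(self) -> int:
        return len(self.ids)

    def __iter__(self):
        return iter(zip(self.ids, self.sequences))

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=tid, description=self.species)
            for tid, seq in self
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, species: str) -> "ReferenceTranscriptome":
        ids, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            seqs.append(str(rec.seq).upper())
        return cls(species, ids, seqs)
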