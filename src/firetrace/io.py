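"""Sequence records, FASTA I/O and clade configuration.

The unit of data throughout the package is a :class:`SequenceRecord`: a
named nucleotide sequence carrying an optional clade label (e.g.
``"avian"``, ``"snake"``).  Sequences are normalized to uppercase on
construction (soft-masking is ignored) and validated against the IUPAC
alphabet; N is a legal character and is propagated, never stripped —
real inputs such as the Tamar wallaby element are interrupted by Ns.

Coordinates are 0-based half-open internally; all user-facing reports
are 1-based inclusive.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import yaml
from Bio import SeqIO

from firetrace import iupac


@dataclass(frozen=True)
class SequenceRecord:
    """A named IUPAC nucleotide sequence with an optional clade tag."""

    id: str
    seq: str
    clade: str = ""
    source_note: str = ""

    def __post_init__(self) -> None:
        seq = self.seq.upper().replace("U", "T")
        if not seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = iupac.first_invalid(seq)
        if bad is not None:
            raise ValueError(
                f"record {self.id!r}: invalid IUPAC code {seq[bad]!r} "
                f"at position {bad + 1}"
            )
        object.__setattr__(self, "seq", seq)

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return replace(self, seq=iupac.revcomp(self.seq))

    def with_clade(self, clade: str) -> "SequenceRecord":
        return replace(self, clade=clade)


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC string (see :func:`firetrace.iupac.revcomp`)."""
    return iupac.revcomp(seq)


def read_fasta(path: str | os.PathLike, clade: str = "") -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into a list of records, in file order.

    Sequences are uppercased; an empty file or a non-IUPAC character is
    an error naming the record and 1-based position.
    """
    records = []
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            records.append(
                SequenceRecord(id=rec.id, seq=str(rec.seq), clade=clade,
                               source_note=rec.description)
            )
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: list[SequenceRecord] | SequenceRecord,
                path: str | os.PathLike, width: int = 60) -> None:
    """Write records as FASTA, sequence lines wrapped at *width* columns."""
    if isinstance(records, SequenceRecord):
        records = [records]
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                handle.write(rec.seq[i:i + width] + "\n")


@dataclass
class CladeConfig:
    """Assignment of record ids to named clades, with a per-clade query id.

    The query id is the search seed used for element extraction within
    that clade (mouse/human for mammals, chicken/zebra finch for birds,
    alligator/anole for reptiles in the original analysis).
    """

    clades: dict[str, list[str]]
    queries: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for clade, ids in self.clades.items():
            if not ids:
                raise ValueError(f"clade {clade!r} has no members")
            for rid in ids:
                if rid in seen:
                    raise ValueError(
                        f"record {rid!r} assigned to both {seen[rid]!r} and {clade!r}"
                    )
                seen[rid] = clade
        for clade, query in self.queries.items():
            if clade not in self.clades:
                raise ValueError(f"query given for unknown clade {clade!r}")
            if query not in self.clades[clade]:
                raise ValueError(
                    f"query {query!r} is not a member of clade {clade!r}"
                )

    def clade_of(self, record_id: str) -> str:
        for clade, ids in self.clades.items():
            if record_id in ids:
                return clade
        raise KeyError(record_id)


def read_clade_config(path: str | os.PathLike) -> CladeConfig:
    """Parse a clade-assignment config (YAML; JSON is a YAML subset).

    Expected shape::

        clades:
          mammal: [mouse, human, pig]
          avian:  [chicken, zebrafinch]
        queries:
          mammal: mouse
          avian: chicken
    """
    with open(path) as handle:
        data = yaml.safe_load(handle)
    if not isinstance(data, dict) or "clades" not in data:
        raise ValueError(f"{path}: expected a mapping with a 'clades' key")
    return CladeConfig(clades=data["clades"], queries=data.get("queries", {}))
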