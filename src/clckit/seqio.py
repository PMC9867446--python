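"""Sequence I/O, translation, and in-silico point mutagenesis.

Coordinates are 1-based inclusive in every user-facing object (positions in
substitution strings, motif hits, anchor columns); slicing internally is
0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_PROTEIN_ALPHABET = frozenset(AMINO_ACIDS) | {"X"}
_DNA_ALPHABET = frozenset("ACGT")


class SequenceError(ValueError):
    """Malformed sequence data (bad characters, bad length, bad ids)."""


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence.

    ``X`` (unknown residue) is accepted but flagged via :attr:`has_unknown`;
    every other non-standard letter is rejected at construction time.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("protein record must have a non-empty id")
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for offset, ch in enumerate(self.sequence, start=1):
            if ch not in _PROTEIN_ALPHABET:
                raise SequenceError(
                    f"record {self.id!r}: illegal residue {ch!r} at position {offset}"
                )

    @property
    def has_unknown(self) -> bool:
        return "X" in self.sequence

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CdsRecord:
    """A protein-coding nucleotide sequence, frame fixed at 1."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("CDS record must have a non-empty id")
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for offset, ch in enumerate(self.sequence, start=1):
            if ch not in _DNA_ALPHABET:
                raise SequenceError(
                    f"record {self.id!r}: illegal base {ch!r} at position {offset}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


_SUBSTITUTION_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")


@dataclass(frozen=True)
class SubstitutionSpec:
    """A single-nucleotide CDS edit in ``<ref><1-based position><alt>`` form."""

    ref_base: str
    position: int
    alt_base: str

    def __post_init__(self) -> None:
        if self.ref_base not in _DNA_ALPHABET or self.alt_base not in _DNA_ALPHABET:
            raise SequenceError(
                f"substitution bases must be A/C/G/T, got "
                f"{self.ref_base!r}>{self.alt_base!r}"
            )
        if self.position < 1:
            raise SequenceError(f"substitution position must be >= 1, got {self.position}")

    @classmethod
    def parse(cls, text: str) -> "SubstitutionSpec":
        m = _SUBSTITUTION_RE.match(text.strip().upper())
        if m is None:
            raise SequenceError(
                f"cannot parse substitution {text!r}; expected e.g. 'C544T'"
            )
        return cls(ref_base=m.group(1), position=int(m.group(2)), alt_base=m.group(3))

    @property
    def codon_index(self) -> int:
        """1-based index of the codon containing the edited base."""
        return (self.position + 2) // 3

    def __str__(self) -> str:
        return f"{self.ref_base}{self.position}{self.alt_base}"


def _read_raw(path) -> list[SeqRecord]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def _check_unique_ids(records) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise SequenceError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)


def read_protein_fasta(path) -> list[ProteinRecord]:
    """Read a multi-record protein FASTA; order preserved, case normalized."""
    raw = _read_raw(path)
    _check_unique_ids(raw)
    return [
        ProteinRecord(id=r.id, sequence=str(r.seq).upper(), description=r.description)
        for r in raw
    ]


def read_cds_fasta(path) -> list[CdsRecord]:
    """Read a multi-record nucleotide FASTA of coding sequences."""
    raw = _read_raw(path)
    _check_unique_ids(raw)
    return [
        CdsRecord(id=r.id, sequence=str(r.seq).upper(), description=r.description)
        for r in raw
    ]


def write_fasta(records, path, width: int = 60) -> None:
    """Write protein or CDS records as wrapped FASTA."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def translate_cds(cds: CdsRecord) -> ProteinRecord:
    """Translate a CDS with the standard genetic code (NCBI table 1).

    A single trailing stop codon is trimmed silently; internal stops and
    lengths not divisible by 3 are hard errors.
    """
    seq = cds.sequence
    if len(seq) % 3 != 0:
        raise SequenceError(
            f"record {cds.id!r}: CDS length {len(seq)} is not divisible by 3"
        )
    aa = str(Seq(seq).translate(table=1))
    if aa.endswith("*"):
        aa = aa[:-1]
    if not aa:
        raise SequenceError(f"record {cds.id!r}: CDS encodes only a stop codon")
    star = aa.find("*")
    if star != -1:
        raise SequenceError(
            f"record {cds.id!r}: internal stop codon at codon {star + 1}"
        )
    return ProteinRecord(id=cds.id, sequence=aa, description=cds.description)


def apply_substitution(cds: CdsRecord, sub: SubstitutionSpec) -> CdsRecord:
    """Return a copy of ``cds`` with the single-base edit applied.

    The reference base is checked against the CDS to guard against
    coordinate drift; a mismatch is an error, never a silent overwrite.
    """
    if sub.position > len(cds.sequence):
        raise SequenceError(
            f"record {cds.id!r}: substitution position {sub.position} exceeds "
            f"CDS length {len(cds.sequence)}"
        )
    found = cds.sequence[sub.position - 1]
    if found != sub.ref_base:
        raise SequenceError(
            f"record {cds.id!r}: reference mismatch at position {sub.position}: "
            f"substitution says {sub.ref_base!r} but CDS has {found!r}"
        )
    edited = (
        cds.sequence[: sub.position - 1] + sub.alt_base + cds.sequence[sub.position :]
    )
    return replace(cds, sequence=edited)
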