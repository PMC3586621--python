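"""Aligned nucleotide data: reading, validation, frame checks, haplotype collapsing.

An alignment is the substrate of everything downstream: haplotype
identification, distance estimation and source assignment all operate on
equal-length nucleotide sequences.  Sequences are stored uppercase over the
alphabet ``{A,C,G,T}`` plus IUPAC ambiguity codes, ``N`` and the gap ``-``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "AlignmentError",
    "InputError",
    "AlignedSequenceSet",
    "Haplotype",
    "HaplotypeTable",
    "read_alignment",
    "write_alignment",
    "check_reading_frame",
    "collapse_haplotypes",
]

IUPAC_CHARS = set("ACGTRYSWKMBDHVN-")
UNAMBIGUOUS = set("ACGT")


class AlignmentError(ValueError):
    """Sequences violate the equal-length (aligned) invariant."""


class InputError(ValueError):
    """Malformed or empty input data."""


@dataclass(frozen=True)
class AlignedSequenceSet:
    """Equal-length nucleotide sequences with unique identifiers.

    Parameters
    ----------
    records : list of (identifier, sequence)
        Sequences are normalised to uppercase on construction.
    partitions : optional list of (name, start, end)
        Half-open 0-based column ranges annotating gene boundaries in a
        concatenated alignment (e.g. ND2 then ND4).  Used for reporting
        only; no computation is partition-aware.
    """

    records: tuple[tuple[str, str], ...]
    partitions: tuple[tuple[str, int, int], ...] = ()
    length: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        if not self.records:
            raise InputError("alignment contains no sequences")
        normalised = tuple((ident, seq.upper()) for ident, seq in self.records)
        object.__setattr__(self, "records", normalised)
        length = len(normalised[0][1])
        if length < 1:
            raise AlignmentError(f"record {normalised[0][0]!r} is empty")
        seen: set[str] = set()
        for ident, seq in normalised:
            if ident in seen:
                raise InputError(f"duplicate identifier {ident!r}")
            seen.add(ident)
            if len(seq) != length:
                raise AlignmentError(
                    f"record {ident!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - IUPAC_CHARS
            if bad:
                raise InputError(
                    f"record {ident!r} contains non-nucleotide characters {sorted(bad)}"
                )
        object.__setattr__(self, "length", length)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def identifiers(self) -> list[str]:
        return [ident for ident, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    def sequence(self, identifier: str) -> str:
        for ident, seq in self.records:
            if ident == identifier:
                return seq
        raise KeyError(identifier)

    def to_array(self) -> np.ndarray:
        """Byte matrix view (n_sequences x length) for vectorised site work."""
        return np.frombuffer(
            "".join(self.sequences).encode("ascii"), dtype=np.uint8
        ).reshape(len(self), self.length)


@dataclass(frozen=True)
class Haplotype:
    label: str
    sequence: str
    members: tuple[str, ...]


@dataclass(frozen=True)
class HaplotypeTable:
    """Unique sequence variants with the identifiers that carry them."""

    haplotypes: tuple[Haplotype, ...]
    label_prefix: str = "H"

    def __len__(self) -> int:
        return len(self.haplotypes)

    def __iter__(self):
        return iter(self.haplotypes)

    @property
    def labels(self) -> list[str]:
        return [h.label for h in self.haplotypes]

    @property
    def sequences(self) -> list[str]:
        return [h.sequence for h in self.haplotypes]

    def as_alignment(self) -> AlignedSequenceSet:
        return AlignedSequenceSet(tuple((h.label, h.sequence) for h in self.haplotypes))

    def membership(self) -> dict[str, str]:
        """identifier -> haplotype label."""
        out: dict[str, str] = {}
        for h in self.haplotypes:
            for m in h.members:
                out[m] = h.label
        return out


def read_alignment(path: str | Path, format: str = "fasta") -> AlignedSequenceSet:
    """Read an aligned FASTA file into an :class:`AlignedSequenceSet`.

    Wrapped or unwrapped FASTA lines are both accepted.  Raises
    :class:`AlignmentError` if sequences differ in length and
    :class:`InputError` on duplicate identifiers or an empty file.
    """
    if format != "fasta":
        raise InputError(f"unsupported alignment format {format!r}")
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"no FASTA records found in {path}")
    return AlignedSequenceSet(tuple(records))


def write_alignment(aln: AlignedSequenceSet, path: str | Path, width: int = 70) -> None:
    """Write FASTA wrapped at `width` columns."""
    path = Path(path)
    with path.open("w") as fh:
        for ident, seq in aln:
            fh.write(f">{ident}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def check_reading_frame(
    aln: AlignedSequenceSet,
    frame: int = 0,
    code: str = "Vertebrate Mitochondrial",
) -> list[tuple[str, int]]:
    """Scan every sequence for stop codons in the given reading frame.

    Protein-coding mtDNA fragments (here ND2/ND4) must translate without
    stops; a stop indicates a misalignment, a pseudogene (numt) or a
    sequencing error.  Codons containing gaps or ambiguity codes are
    skipped.  Returns ``(identifier, codon_position)`` pairs with 1-based
    codon positions; an empty list means the alignment passes.

    The default genetic code is the vertebrate mitochondrial table, in
    which AGA and AGG are stops in addition to TAA/TAG.
    """
    if frame not in (0, 1, 2):
        raise InputError(f"frame must be 0, 1 or 2, got {frame}")
    try:
        table = CodonTable.unambiguous_dna_by_name[code]
    except KeyError as exc:
        raise InputError(f"unknown genetic code {code!r}") from exc
    stops = set(table.stop_codons)
    violations: list[tuple[str, int]] = []
    for ident, seq in aln:
        for codon_idx, pos in enumerate(range(frame, len(seq) - 2, 3), start=1):
            codon = seq[pos : pos + 3]
            if set(codon) <= UNAMBIGUOUS and codon in stops:
                violations.append((ident, codon_idx))
    return violations


def _comparison_key(seq: str, kept_columns: Sequence[int] | None) -> str:
    if kept_columns is None:
        return seq
    return "".join(seq[i] for i in kept_columns)


def collapse_haplotypes(
    aln: AlignedSequenceSet,
    label_prefix: str = "H",
    ambiguity_policy: str = "strict",
) -> HaplotypeTable:
    """Collapse an alignment to its unique haplotypes.

    Under ``strict`` (the default) two sequences share a haplotype iff they
    are character-identical.  Under ``ignore-ambiguous-sites`` every column
    containing a gap, ``N`` or IUPAC ambiguity code in *any* sequence is
    excluded before comparison, so sequences differing only at such columns
    collapse together.

    Labels are assigned in order of first appearance as
    ``{prefix}{zero-padded index}`` (e.g. ``MAF01``), which makes the
    result deterministic for a fixed input order; permuting the input
    permutes labels but never the partition of identifiers.
    """
    if ambiguity_policy not in ("strict", "ignore-ambiguous-sites"):
        raise InputError(f"unknown ambiguity policy {ambiguity_policy!r}")
    kept: list[int] | None = None
    if ambiguity_policy == "ignore-ambiguous-sites":
        arr = aln.to_array()
        ok = np.ones(aln.length, dtype=bool)
        for ch in IUPAC_CHARS - UNAMBIGUOUS:
            ok &= ~(arr == ord(ch)).any(axis=0)
        kept = [int(i) for i in np.nonzero(ok)[0]]

    groups: dict[str, list[str]] = {}
    first_seq: dict[str, str] = {}
    order: list[str] = []
    for ident, seq in aln:
        key = _comparison_key(seq, kept)
        if key not in groups:
            groups[key] = []
            first_seq[key] = seq
            order.append(key)
        groups[key].append(ident)

    width = max(2, len(str(len(order))))
    haps = tuple(
        Haplotype(
            label=f"{label_prefix}{i + 1:0{width}d}",
            sequence=first_seq[key],
            members=tuple(groups[key]),
        )
        for i, key in enumerate(order)
    )
    return HaplotypeTable(haplotypes=haps, label_prefix=label_prefix)
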