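"""Sequence records and FASTA/FASTQ I/O with UNITE-style taxonomy headers.

A record header on disk looks like::

    >S1.sp003.c0|ACC00003|k__Fungi;p__Ascomycota;c__...;s__Gen01_sp003

i.e. ``id|accession|lineage`` where the lineage carries the six ranks
phylum through species (a constant ``k__Fungi`` prefix is written for
familiarity and ignored on read).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

RANKS = ("phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIX = dict(zip(RANKS, ("p__", "c__", "o__", "f__", "g__", "s__")))
_KINGDOM = "k__Fungi"

VALID_BASES = frozenset("ACGTN")


@dataclass
class SeqRecord:
    """One sequence with optional qualities, taxonomy and source accession."""

    id: str
    sequence: str
    qualities: list[int] | None = None
    lineage: str | None = None
    accession: str | None = None
    #: ground-truth region coordinates when the record was simulated
    features: dict[str, tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"qualities length {len(self.qualities)} != sequence length "
                f"{len(self.sequence)} for record {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def species(self) -> str | None:
        """Species binomial from the lineage, or None."""
        if self.lineage is None:
            return None
        return lineage_ranks(self.lineage)["species"]


def lineage_ranks(lineage: str) -> dict[str, str]:
    """Split a six-rank lineage path into a rank → name mapping.

    Accepts both bare (``Ascomycota;...;Gen01_sp003``) and prefixed
    (``p__Ascomycota;...;s__Gen01_sp003``) forms; a leading kingdom field
    is dropped.
    """
    parts = [p.strip() for p in lineage.split(";") if p.strip()]
    if parts and parts[0].startswith("k__"):
        parts = parts[1:]
    if len(parts) != len(RANKS):
        raise ValueError(f"lineage must have exactly {len(RANKS)} ranks: {lineage!r}")
    out = {}
    for rank, part in zip(RANKS, parts):
        prefix = _RANK_PREFIX[rank]
        out[rank] = part[len(prefix):] if part.startswith(prefix) else part
    return out


def format_lineage(names: Mapping[str, str]) -> str:
    """Inverse of :func:`lineage_ranks`, including the kingdom prefix."""
    fields = [_KINGDOM]
    fields += [_RANK_PREFIX[r] + names[r] for r in RANKS]
    return ";".join(fields)


def _header(rec: SeqRecord) -> str:
    acc = rec.accession or ""
    lin = rec.lineage or ""
    if acc or lin:
        return f"{rec.id}|{acc}|{lin}"
    return rec.id


def _parse_header(header: str) -> tuple[str, str | None, str | None]:
    parts = header.split("|")
    if len(parts) == 3:
        return parts[0], parts[1] or None, parts[2] or None
    return header, None, None


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{_header(rec)}\n{rec.sequence}\n")


def read_fasta(path) -> list[SeqRecord]:
    out = []
    for bio in SeqIO.parse(str(path), "fasta"):
        rid, acc, lin = _parse_header(bio.description)
        out.append(SeqRecord(id=rid, sequence=str(bio.seq).upper(),
                             accession=acc, lineage=lin))
    return out


def write_fastq(records: Iterable[SeqRecord], path) -> None:
    bios = []
    for rec in records:
        if rec.qualities is None:
            raise ValueError(f"record {rec.id!r} has no qualities")
        bio = _BioRecord(Seq(rec.sequence), id=_header(rec), description="")
        bio.letter_annotations["phred_quality"] = list(rec.qualities)
        bios.append(bio)
    SeqIO.write(bios, str(path), "fastq")


def read_fastq(path) -> list[SeqRecord]:
    out = []
    for bio in SeqIO.parse(str(path), "fastq"):
        rid, acc, lin = _parse_header(bio.description)
        out.append(SeqRecord(id=rid, sequence=str(bio.seq).upper(),
                             qualities=list(bio.letter_annotations["phred_quality"]),
                             accession=acc, lineage=lin))
    return out


def region_suffixed(rec: SeqRecord, region: str, sequence: str) -> SeqRecord:
    """A region sub-record whose id keeps the originating read as a shared key."""
    return SeqRecord(id=f"{rec.id}/{region}", sequence=sequence,
                     lineage=rec.lineage, accession=rec.accession)


def shared_key(record_id: str) -> str:
    """Strip a trailing /ITS, /ITS1 or /ITS2 region suffix from an id.

    Region records cut from the same full-length read share this key, which
    is what lets clusterings of different regions be compared read-by-read.
    """
    base, sep, suffix = record_id.rpartition("/")
    if sep and suffix in ("ITS", "ITS1", "ITS2", "5.8S"):
        return base
    return record_id


def revcomp(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())
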