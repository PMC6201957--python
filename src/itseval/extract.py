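"""ITS1/ITS2 extraction from full-length ITS sequences via conserved anchors.

The rDNA cistron is 18S - ITS1 - 5.8S - ITS2 - 28S.  The spacers are
delimited by conserved motifs: the 3' tail of the 18S (SSU), the first and
last bases of the 5.8S gene, and the 5' head of the 28S (LSU).  Locating
those four motifs (allowing a few mismatches) recovers the spacer
boundaries, the role profile-HMM tools such as ITSx play on real data.
Motif anchoring keeps the extraction self-contained and exactly testable on
simulated sequences whose true boundaries are known.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .records import SeqRecord, region_suffixed, revcomp

#: default conserved motifs (fungal-flavoured, matched to the simulator)
DEFAULT_SSU_TAIL = "GGAAGTAAAAGTCGTAACAAGG"   # 18S 3' end (ITS5 primer site)
DEFAULT_58S_HEAD = "CAACTTTCAGCAACGGATCTCTTGG"  # 5.8S 5' end
DEFAULT_58S_TAIL = "GCATCGATGAAGAACGCAGC"     # 5.8S 3' end (ITS3 primer site)
DEFAULT_LSU_HEAD = "TTGACCTCAAATCAGGTAGGA"    # 28S 5' end


@dataclass(frozen=True)
class AnchorSet:
    """The four boundary motifs and the per-motif mismatch tolerance."""

    ssu_tail: str = DEFAULT_SSU_TAIL
    r58s_head: str = DEFAULT_58S_HEAD
    r58s_tail: str = DEFAULT_58S_TAIL
    lsu_head: str = DEFAULT_LSU_HEAD
    max_mismatch: int = 2

    def __post_init__(self) -> None:
        for name in ("ssu_tail", "r58s_head", "r58s_tail", "lsu_head"):
            motif = getattr(self, name)
            if not motif or set(motif) - set("ACGT"):
                raise ValueError(f"{name} must be a non-empty A/C/G/T motif")
            if self.max_mismatch >= len(motif):
                raise ValueError(f"max_mismatch must be < |{name}|")


@dataclass
class ExtractionResult:
    its1: str | None
    its2: str | None
    its_full: str | None
    #: named half-open intervals: ssu_tail, its1, r58s, its2, lsu_head
    coordinates: dict[str, tuple[int, int]] = field(default_factory=dict)
    status: str = "failed"  # full | its1_only | its2_only | failed


def locate_anchor(sequence: str, motif: str, max_mismatch: int) -> int | None:
    """Leftmost position with minimal Hamming distance to the motif.

    Returns None when no window is within ``max_mismatch`` of the motif.
    """
    if not motif:
        raise ValueError("empty motif")
    if len(motif) > len(sequence):
        return None
    seq = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    mot = np.frombuffer(motif.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(seq, len(mot))
    dists = (windows != mot).sum(axis=1)
    pos = int(np.argmin(dists))  # argmin is leftmost on ties
    if dists[pos] > max_mismatch:
        return None
    return pos


def extract_regions(record: SeqRecord, anchors: AnchorSet = AnchorSet(), *,
                    try_reverse_complement: bool = False) -> ExtractionResult:
    """Split a full-length record into ITS1 and ITS2 using the anchors.

    ITS1 spans from the end of the SSU-tail hit to the start of the 5.8S
    head; ITS2 from the end of the 5.8S tail to the start of the LSU head.
    Anchors found out of order give status ``failed``; an empty spacer
    degrades the status on that side only.
    """
    seq = record.sequence
    result = _extract(seq, anchors)
    if result.status == "failed" and try_reverse_complement:
        rc = _extract(revcomp(seq), anchors)
        if rc.status != "failed":
            return rc
    return result


def _extract(seq: str, anchors: AnchorSet) -> ExtractionResult:
    mm = anchors.max_mismatch
    hits: dict[str, tuple[int, int] | None] = {}
    for name, motif in (("ssu_tail", anchors.ssu_tail),
                        ("r58s_head", anchors.r58s_head),
                        ("r58s_tail", anchors.r58s_tail),
                        ("lsu_head", anchors.lsu_head)):
        pos = locate_anchor(seq, motif, mm)
        hits[name] = None if pos is None else (pos, pos + len(motif))

    found = [iv for iv in hits.values() if iv is not None]
    starts = [iv[0] for iv in found]
    if starts != sorted(starts):
        return ExtractionResult(None, None, None, {}, "failed")

    coords: dict[str, tuple[int, int]] = {}
    its1 = its2 = None
    if hits["ssu_tail"] and hits["r58s_head"]:
        lo, hi = hits["ssu_tail"][1], hits["r58s_head"][0]
        if hi > lo:
            its1 = seq[lo:hi]
            coords["its1"] = (lo, hi)
            coords["ssu_tail"] = hits["ssu_tail"]
    if hits["r58s_tail"] and hits["lsu_head"]:
        lo, hi = hits["r58s_tail"][1], hits["lsu_head"][0]
        if hi > lo:
            its2 = seq[lo:hi]
            coords["its2"] = (lo, hi)
            coords["lsu_head"] = hits["lsu_head"]
    if hits["r58s_head"] and hits["r58s_tail"]:
        coords["r58s"] = (hits["r58s_head"][0], hits["r58s_tail"][1])

    its_full = None
    if its1 is not None and its2 is not None and "r58s" in coords:
        its_full = seq[coords["its1"][0]:coords["its2"][1]]
        status = "full"
    elif its1 is not None:
        status = "its1_only"
    elif its2 is not None:
        status = "its2_only"
    else:
        status = "failed"
    return ExtractionResult(its1, its2, its_full, coords, status)


def extract_all(records, anchors: AnchorSet = AnchorSet(), *,
                try_reverse_complement: bool = False):
    """Extract every record; returns (region record lists, per-record table).

    The region records carry the originating read id with ``/ITS``,
    ``/ITS1`` and ``/ITS2`` suffixes so downstream clusterings of different
    regions stay comparable read-by-read.
    """
    regions: dict[str, list[SeqRecord]] = {"ITS": [], "ITS1": [], "ITS2": []}
    table = []
    for rec in records:
        res = extract_regions(rec, anchors,
                              try_reverse_complement=try_reverse_complement)
        if res.its_full:
            regions["ITS"].append(region_suffixed(rec, "ITS", res.its_full))
        if res.its1:
            regions["ITS1"].append(region_suffixed(rec, "ITS1", res.its1))
        if res.its2:
            regions["ITS2"].append(region_suffixed(rec, "ITS2", res.its2))
        table.append({"id": rec.id, "status": res.status,
                      **{f"{k}_start": v[0] for k, v in res.coordinates.items()},
                      **{f"{k}_end": v[1] for k, v in res.coordinates.items()}})
    return regions, table


def write_extraction_table(table, path) -> None:
    cols = ["id", "status"]
    extra = sorted({k for row in table for k in row} - set(cols))
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols + extra, delimiter="\t",
                                restval="")
        writer.writeheader()
        writer.writerows(table)
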