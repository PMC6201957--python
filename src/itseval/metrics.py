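"""Length and GC profiling per region and taxonomic group.

Implements the study's descriptive layer: GC content with ambiguous bases
excluded, the extreme-value filters (<100 bp / >600 bp length, <20% / >80%
GC, all strict inequalities), per-group summaries at a chosen rank, and the
pooled-variance two-sample t test used for length/GC group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .records import RANKS, SeqRecord, lineage_ranks


@dataclass
class GroupSummary:
    group: str
    n: int
    mean_length: float
    min_length: int
    max_length: int
    mean_gc: float
    pct_length_extreme: float
    pct_gc_extreme: float


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T); ambiguous bases are excluded on both sides."""
    up = sequence.upper()
    gc = up.count("G") + up.count("C")
    total = gc + up.count("A") + up.count("T")
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    return gc / total


def length_class_counts(records: Sequence[SeqRecord], low: int = 100,
                        high: int = 600) -> dict[str, int]:
    """Counts strictly below ``low``, within [low, high], strictly above."""
    if not records:
        raise ValueError("no records")
    if low >= high:
        raise ValueError("low must be < high")
    lengths = [len(r.sequence) for r in records]
    below = sum(1 for n in lengths if n < low)
    above = sum(1 for n in lengths if n > high)
    return {"below": below, "within": len(lengths) - below - above,
            "above": above}


def gc_extreme_counts(records: Sequence[SeqRecord], low: float = 0.20,
                      high: float = 0.80) -> dict[str, float]:
    """How many records fall outside the (low, high) GC band (strict)."""
    if not records:
        raise ValueError("no records")
    if low >= high:
        raise ValueError("low must be < high")
    values = [gc_content(r.sequence) for r in records]
    outside = sum(1 for v in values if v < low or v > high)
    return {"outside": outside, "within": len(values) - outside,
            "fraction_outside": outside / len(values)}


def group_summary(records: Sequence[SeqRecord], rank: str, *,
                  len_low: int = 100, len_high: int = 600,
                  gc_low: float = 0.20, gc_high: float = 0.80
                  ) -> list[GroupSummary]:
    """One summary per distinct value of ``rank``; missing names group as
    'unclassified'."""
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    groups: dict[str, list[SeqRecord]] = {}
    for rec in records:
        if rec.lineage is None:
            raise ValueError(f"record {rec.id!r} has no lineage")
        name = lineage_ranks(rec.lineage)[rank] or "unclassified"
        if name.lower().startswith("unclassified"):
            name = "unclassified"
        groups.setdefault(name, []).append(rec)
    out = []
    for name in sorted(groups):
        recs = groups[name]
        lengths = np.array([len(r.sequence) for r in recs])
        gcs = np.array([gc_content(r.sequence) for r in recs])
        out.append(GroupSummary(
            group=name, n=len(recs),
            mean_length=float(lengths.mean()),
            min_length=int(lengths.min()), max_length=int(lengths.max()),
            mean_gc=float(gcs.mean()),
            pct_length_extreme=float(((lengths < len_low) |
                                      (lengths > len_high)).mean()),
            pct_gc_extreme=float(((gcs < gc_low) | (gcs > gc_high)).mean())))
    return out


def two_sample_t(x: Sequence[float], y: Sequence[float], *,
                 welch: bool = False) -> tuple[float, float]:
    """Classical pooled-variance two-sample t (Welch behind a flag).

    Degenerate inputs follow fixed conventions: two identical constant
    samples give (0, 1); zero pooled variance with unequal means gives
    (+/-inf, 0).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        return float(np.sign(x.mean() - y.mean()) * np.inf), 0.0
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)
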