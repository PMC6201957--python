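"""Cross-clustering OTU commonality A and species-per-OTU composition.

Two clusterings of the same reads (e.g. the ITS1 and ITS2 partitions, where
both spacers were cut from the same full-length sequences) are compared OTU
by OTU: for each OTU of the first clustering, look up which OTU of the
second clustering contains its representative sequence, and count the reads
the two OTUs share (m).  The commonality is

    A = (sum over the n OTUs of database 1 of m) / N

with N the number of reads in database 1.  A(c, c) = 1 for any partition;
A is not symmetric, so both directions of every pair are reported.
Matching is by representative containment - the procedure's definition -
not by maximum overlap; a max-overlap mode exists for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .cluster import OTU, Clustering
from .records import shared_key


@dataclass
class CommonalityResult:
    A: float
    N: int
    per_otu: list[tuple[str, str | None, int]]  # (otu1, matched otu2, m)
    threshold_pair: tuple[float, float]
    direction: tuple[str, str]

    @property
    def total_m(self) -> int:
        return sum(m for _, _, m in self.per_otu)


def match_otu(otu1: OTU, clustering2: Clustering,
              key: Callable[[str], str] = shared_key) -> OTU | None:
    """The OTU of clustering2 whose members contain otu1's representative.

    Ids are compared through ``key`` (region suffixes stripped), honouring
    that regions cut from one read share an identity.  None when the
    representative's read is absent from clustering2's universe.
    """
    rep = key(otu1.representative_id)
    for otu2 in clustering2.otus:
        for mid in otu2.member_ids:
            if key(mid) == rep:
                return otu2
    return None


def commonality(c1: Clustering, c2: Clustering, *,
                key: Callable[[str], str] = shared_key,
                restrict_shared: bool = False,
                max_overlap: bool = False) -> CommonalityResult:
    """The commonality A of c1 against c2 (direction c1 -> c2).

    ``restrict_shared`` recomputes on the universe intersection (useful when
    extraction failures make the two universes differ); otherwise N stays
    |c1.universe| and reads absent from c2 simply cannot contribute to m.
    ``max_overlap`` switches the matching rule from representative
    containment to the largest-intersection OTU (sensitivity mode).
    """
    if not c1.universe:
        raise ValueError("empty universe in database 1")
    keys2: dict[str, int] = {}
    for idx, otu2 in enumerate(c2.otus):
        for mid in otu2.member_ids:
            keys2[key(mid)] = idx

    shared = None
    if restrict_shared:
        shared = {key(mid) for mid in c1.universe} & set(keys2)

    per_otu: list[tuple[str, str | None, int]] = []
    n_reads = 0
    for otu1 in c1.otus:
        members = [key(mid) for mid in otu1.member_ids]
        if shared is not None:
            members = [k for k in members if k in shared]
        n_reads += len(members)
        if max_overlap:
            votes: dict[int, int] = {}
            for k in members:
                if k in keys2:
                    votes[keys2[k]] = votes.get(keys2[k], 0) + 1
            idx2 = max(votes, key=lambda i: (votes[i], -i)) if votes else None
        else:
            idx2 = keys2.get(key(otu1.representative_id))
        if idx2 is None:
            per_otu.append((otu1.otu_id, None, 0))
            continue
        members2 = {key(mid) for mid in c2.otus[idx2].member_ids}
        m = sum(1 for k in members if k in members2)
        per_otu.append((otu1.otu_id, c2.otus[idx2].otu_id, m))

    if n_reads == 0:
        raise ValueError("no reads left in database 1 after restriction")
    total = sum(m for _, _, m in per_otu)
    return CommonalityResult(A=total / n_reads, N=n_reads, per_otu=per_otu,
                             threshold_pair=(c1.threshold, c2.threshold),
                             direction=(c1.region_label or "db1",
                                        c2.region_label or "db2"))


def species_per_otu(clustering: Clustering,
                    lineage_of: Mapping[str, str | None]
                    ) -> tuple[float, list[int]]:
    """Distinct species binomials per OTU and their mean over OTUs."""
    from .records import lineage_ranks

    counts = []
    for otu in clustering.otus:
        species = set()
        for mid in otu.member_ids:
            lin = lineage_of.get(mid) or lineage_of.get(shared_key(mid))
            if lin is None:
                raise KeyError(f"no lineage for member {mid!r}")
            species.add(lineage_ranks(lin)["species"])
        counts.append(len(species))
    return sum(counts) / len(counts), counts


def commonality_report(clusterings: Mapping[str, Mapping[float, Clustering]],
                       thresholds: Sequence[float],
                       cross_pairs: Sequence[tuple[float, float]] = ((0.97, 0.98),
                                                                     (0.97, 0.99)),
                       **kwargs) -> list[dict]:
    """All six directed region pairs along the equal-threshold diagonal,
    plus the stated cross-threshold pairs; rows ready for a TSV."""
    rows = []
    labels = sorted(clusterings)
    pairs = [(a, b) for a in labels for b in labels if a != b]
    jobs = [(t, t) for t in thresholds] + [p for p in cross_pairs
                                           if p[0] in thresholds and p[1] in thresholds]
    for la, lb in pairs:
        for t1, t2 in jobs:
            res = commonality(clusterings[la][t1], clusterings[lb][t2], **kwargs)
            rows.append({"db1": la, "db2": lb, "t1": t1, "t2": t2,
                         "N": res.N, "n_otus": len(res.per_otu),
                         "sum_m": res.total_m, "A": res.A})
    return rows
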