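"""Taxonomic resolution of marker regions against a reference database.

Mirrors a best-hit identity search (the role BLAST-against-UNITE plays):
each query is assigned the reference with the highest pairwise identity,
ties broken by longer aligned reference, then smallest accession.  From the
assignments come the two headline resolution measures:

* self-return rate - the fraction of queries whose best hit is their own
  source record (the database includes the query's own entry; regions that
  collapse across species drag this down);
* species-agreement rate - same-species instead of same-accession, never
  below the self-return rate.

Plus rank-level classified/unclassified composition and the small-sample
group tests (exact Mann-Whitney U, Fisher's exact).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from ._align import encode, semi_global_identity
from .cluster import pairwise_identity
from .records import RANKS, SeqRecord, lineage_ranks


@dataclass
class HitResult:
    query_id: str
    hit_accession: str
    identity: float
    same_accession: bool
    same_species: bool


@dataclass
class ReferenceDB:
    records: list[SeqRecord]

    def __post_init__(self) -> None:
        accs = [r.accession for r in self.records]
        if any(a is None for a in accs):
            raise ValueError("every reference needs an accession")
        if len(set(accs)) != len(accs):
            raise ValueError("duplicate accessions in reference database")
        # fixed search order: by accession, so input order never matters
        self.records = sorted(self.records, key=lambda r: r.accession)
        self._encoded = [encode(r.sequence) for r in self.records]


def best_hit(query: SeqRecord, db: ReferenceDB, *,
             exclude_self: bool = False) -> HitResult:
    """Exhaustive best-identity reference for the query.

    Ties go to the longer reference sequence (longer aligned span under
    semi-global identity), then the lexicographically smallest accession.
    ``exclude_self`` enables leave-one-out searches.
    """
    if not db.records:
        raise ValueError("empty reference database")
    if not query.sequence:
        raise ValueError("empty query")
    q = encode(query.sequence)
    best: tuple[float, int, str] | None = None
    best_rec = None
    for rec, enc in zip(db.records, db._encoded):
        if exclude_self and rec.accession == query.accession:
            continue
        if (len(enc), enc.tobytes()) >= (len(q), q.tobytes()):
            ident = semi_global_identity(enc, q)
        else:
            ident = semi_global_identity(q, enc)
        key = (ident, len(rec.sequence))
        if best is None or key > (best[0], best[1]) :
            best = (ident, len(rec.sequence), rec.accession)
            best_rec = rec
    assert best_rec is not None
    same_acc = query.accession is not None and \
        best_rec.accession == query.accession
    qsp = query.species
    same_sp = qsp is not None and best_rec.species == qsp
    return HitResult(query_id=query.id, hit_accession=best_rec.accession,
                     identity=best[0], same_accession=same_acc,
                     same_species=same_sp)


def assign_all(queries: Sequence[SeqRecord], db: ReferenceDB,
               **kwargs) -> list[HitResult]:
    return [best_hit(q, db, **kwargs) for q in queries]


def self_return_rate(queries: Sequence[SeqRecord], db: ReferenceDB, *,
                     hits: Sequence[HitResult] | None = None) -> float:
    """Fraction of queries whose best hit is their own source accession."""
    if hits is None:
        hits = assign_all(queries, db)
    for q in queries:
        if q.accession is None:
            raise ValueError(f"query {q.id!r} lacks a source accession")
    return sum(h.same_accession for h in hits) / len(hits)


def species_agreement_rate(queries: Sequence[SeqRecord], db: ReferenceDB, *,
                           hits: Sequence[HitResult] | None = None) -> float:
    """Fraction of queries whose best hit shares their species binomial."""
    if hits is None:
        hits = assign_all(queries, db)
    for q in queries:
        if q.lineage is None:
            raise ValueError(f"query {q.id!r} lacks a lineage")
    return sum(h.same_species for h in hits) / len(hits)


def rank_composition(assignments: Sequence[tuple[HitResult, str | None]],
                     rank: str, *,
                     identity_floor: float = 0.0) -> dict[str, float]:
    """Taxa count and classified/unclassified percentages at one rank.

    ``assignments`` pairs each hit with its best-hit lineage (None when the
    query found no usable reference).  A query counts as classified iff the
    lineage names the rank (not 'unclassified') and the hit identity
    reaches the rank's floor.
    """
    if rank not in RANKS:
        raise ValueError(f"rank must be one of {RANKS}")
    taxa = set()
    classified = 0
    for hit, lineage in assignments:
        name = None
        if lineage is not None and hit.identity >= identity_floor:
            name = lineage_ranks(lineage)[rank]
            if not name or name.lower().startswith("unclassified"):
                name = None
        if name is not None:
            taxa.add(name)
            classified += 1
    n = len(assignments)
    pct = 100.0 * classified / n if n else 0.0
    return {"taxa": len(taxa), "classified_pct": pct,
            "unclassified_pct": 100.0 - pct}


def differential_taxa(abundance, groups: Mapping[str, str], *,
                      exact_max_n: int = 8) -> list[dict]:
    """Mann-Whitney U per taxon for every group pair.

    ``abundance`` is a taxa x sample DataFrame; ``groups`` maps sample to
    group label.  The exact null distribution is used when both groups have
    at most ``exact_max_n`` samples (the study design has <= 6), the normal
    approximation otherwise.
    """
    import pandas as pd

    if not isinstance(abundance, pd.DataFrame):
        abundance = pd.DataFrame(abundance)
    by_group: dict[str, list[str]] = {}
    for sample, group in groups.items():
        by_group.setdefault(group, []).append(sample)
    if len(by_group) < 2:
        raise ValueError("need at least two groups")
    for group, samples in by_group.items():
        if not samples:
            raise ValueError(f"group {group!r} has no samples")
    rows = []
    for g1, g2 in itertools.combinations(sorted(by_group), 2):
        s1 = sorted(by_group[g1])
        s2 = sorted(by_group[g2])
        method = "exact" if max(len(s1), len(s2)) <= exact_max_n else "asymptotic"
        for taxon in abundance.index:
            x = abundance.loc[taxon, s1].to_numpy(dtype=float)
            y = abundance.loc[taxon, s2].to_numpy(dtype=float)
            if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
                u, p = len(x) * len(y) / 2.0, 1.0
            else:
                use = method
                if method == "exact" and (len(np.unique(np.concatenate([x, y])))
                                          < len(x) + len(y)):
                    use = "asymptotic"  # ties: scipy's exact method disallows
                res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method=use)
                u, p = float(res.statistic), float(res.pvalue)
            rows.append({"taxon": taxon, "group1": g1, "group2": g2,
                         "U": u, "p": p})
    return rows


def rate_difference_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided Fisher's exact p for two success/total rates."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("totals must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("successes must lie in [0, total]")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
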