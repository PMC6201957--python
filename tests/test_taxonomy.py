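import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from itseval.cluster import pairwise_identity
from itseval.records import SeqRecord
from itseval.taxonomy import (HitResult, ReferenceDB, assign_all, best_hit,
                              differential_taxa, rank_composition,
                              rate_difference_test, self_return_rate,
                              species_agreement_rate)

from _oracles import fisher_exact_two_sided, mannwhitney_exact
from conftest import mutate_seq, random_seq


def _rec(rid, seq, sp=None, acc=None):
    lineage = f"p__P;c__C;o__O;f__F;g__G;s__{sp}" if sp else None
    return SeqRecord(id=rid, sequence=seq, accession=acc or rid,
                     lineage=lineage)


class TestBestHit:
    def test_exact_match_found(self, rng):
        refs = [_rec(f"A{i}", random_seq(rng, 80), sp=f"sp{i}")
                for i in range(5)]
        db = ReferenceDB(refs)
        query = _rec("q", refs[2].sequence, sp="sp2", acc="A2")
        hit = best_hit(query, db)
        assert hit.hit_accession == "A2"
        assert hit.identity == 1.0
        assert hit.same_accession and hit.same_species

    def test_tie_broken_by_smallest_accession(self, rng):
        seq = random_seq(rng, 60)
        db = ReferenceDB([_rec("B", seq), _rec("A", seq)])
        hit = best_hit(_rec("q", seq, acc="zzz"), db)
        assert hit.hit_accession == "A"

    def test_agrees_with_exhaustive_scan(self, rng):
        refs = []
        base = random_seq(rng, 70)
        for i in range(20):
            refs.append(_rec(f"R{i:02d}", mutate_seq(rng, base,
                                                     rng.uniform(0, 0.3))))
        db = ReferenceDB(refs)
        for _ in range(10):
            q = _rec("q", mutate_seq(rng, base, rng.uniform(0, 0.2)))
            hit = best_hit(q, db)
            best = max(refs, key=lambda r: (pairwise_identity(r.sequence,
                                                              q.sequence),
                                            len(r.sequence),
                                            [-ord(c) for c in r.accession]))
            assert hit.hit_accession == best.accession

    def test_db_order_does_not_matter(self, rng):
        refs = [_rec(f"R{i}", random_seq(rng, 60)) for i in range(6)]
        q = _rec("q", mutate_seq(rng, refs[3].sequence, 0.05))
        h1 = best_hit(q, ReferenceDB(list(refs)))
        h2 = best_hit(q, ReferenceDB(list(reversed(refs))))
        assert h1.hit_accession == h2.hit_accession

    def test_duplicate_accessions_rejected(self):
        with pytest.raises(ValueError):
            ReferenceDB([_rec("A", "ACGT"), _rec("A", "TTTT")])


class TestResolutionRates:
    def test_unique_db_full_length_queries_self_return_one(self, rng):
        refs = [_rec(f"A{i}", random_seq(rng, 80), sp=f"sp{i}")
                for i in range(6)]
        db = ReferenceDB(refs)
        assert self_return_rate(refs, db) == 1.0
        assert species_agreement_rate(refs, db) == 1.0

    def test_identical_references_halve_self_return(self, rng):
        """Two references sharing one region sequence: the tie policy sends
        one query to the other accession - the mechanism that lowers
        region-level self-return when regions collapse across species."""
        seq = random_seq(rng, 80)
        refs = [_rec("A", seq, sp="sp1"), _rec("B", seq, sp="sp2")]
        db = ReferenceDB(refs)
        rate = self_return_rate(refs, db)
        assert rate == 0.5  # query B hits A by the tie policy

    def test_species_agreement_never_below_self_return(self, rng):
        refs = []
        for i in range(8):
            seq = random_seq(rng, 70)
            refs.append(_rec(f"A{i}", seq, sp=f"sp{i % 4}"))
            refs.append(_rec(f"B{i}", mutate_seq(rng, seq, 0.02),
                             sp=f"sp{i % 4}"))
        db = ReferenceDB(refs)
        hits = assign_all(refs, db)
        assert species_agreement_rate(refs, db, hits=hits) >= \
            self_return_rate(refs, db, hits=hits)

    def test_same_species_other_accession(self, rng):
        seq = random_seq(rng, 80)
        refs = [_rec("A", seq, sp="sp1"), _rec("B", seq, sp="sp1")]
        db = ReferenceDB(refs)
        query = _rec("q", seq, sp="sp1", acc="B")
        hit = best_hit(query, db)
        assert not hit.same_accession and hit.same_species

    def test_collapsed_region_lowers_self_return(self, rng):
        """Species pairs identical in one region but distinct in the other:
        the identical region's self-return rate is lower."""
        its1_rates, its2_rates = [], []
        refs1, refs2 = [], []
        for i in range(10):
            shared = random_seq(rng, 90)
            its2_a = random_seq(rng, 90)
            its2_b = mutate_seq(rng, its2_a, 0.2)
            if i < 3:  # 30% of pairs share ITS1 exactly
                refs1 += [_rec(f"P{i}a", shared), _rec(f"P{i}b", shared)]
            else:
                refs1 += [_rec(f"P{i}a", random_seq(rng, 90)),
                          _rec(f"P{i}b", random_seq(rng, 90))]
            refs2 += [_rec(f"P{i}a", its2_a), _rec(f"P{i}b", its2_b)]
        r1 = self_return_rate(refs1, ReferenceDB(refs1))
        r2 = self_return_rate(refs2, ReferenceDB(refs2))
        assert r1 < r2


class TestRankComposition:
    def _hit(self, ident=1.0):
        return HitResult("q", "A", ident, True, True)

    def test_full_lineages_fully_classified(self):
        lin = "p__P;c__C;o__O;f__F;g__G;s__G_sp"
        out = rank_composition([(self._hit(), lin)] * 4, "genus")
        assert out == {"taxa": 1, "classified_pct": 100.0,
                       "unclassified_pct": 0.0}

    def test_missing_genus_monotone(self):
        lin_nogen = "p__P;c__C;o__O;f__F;g__unclassified;s__x"
        assignments = [(self._hit(), lin_nogen)] * 3
        fam = rank_composition(assignments, "family")
        gen = rank_composition(assignments, "genus")
        assert gen["classified_pct"] < fam["classified_pct"]

    def test_identity_floor_marks_novel_queries_unclassified(self):
        lin = "p__P;c__C;o__O;f__F;g__G;s__s"
        assignments = [(self._hit(0.99), lin)] * 9 + [(self._hit(0.70), lin)]
        out = rank_composition(assignments, "phylum", identity_floor=0.80)
        assert out["unclassified_pct"] == pytest.approx(10.0)


class TestGroupTests:
    def test_identical_abundances_p_one(self):
        table = pd.DataFrame({"s1": [5.0], "s2": [5.0], "s3": [5.0],
                              "s4": [5.0]}, index=["tax"])
        groups = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
        rows = differential_taxa(table, groups)
        assert rows[0]["p"] == 1.0

    def test_separated_ranks_exact_p(self):
        table = pd.DataFrame({f"s{i}": [float(i)] for i in range(6)},
                             index=["tax"])
        groups = {f"s{i}": ("A" if i < 3 else "B") for i in range(6)}
        rows = differential_taxa(table, groups)
        assert rows[0]["U"] == 0.0
        assert rows[0]["p"] == pytest.approx(0.1)  # 2 / C(6,3)

    def test_matches_permutation_enumeration(self, rng):
        for _ in range(10):
            x = list(np.round(rng.normal(size=4), 6))
            y = list(np.round(rng.normal(size=5), 6))
            table = pd.DataFrame(
                {f"s{i}": [v] for i, v in enumerate(x + y)}, index=["t"])
            groups = {f"s{i}": ("A" if i < 4 else "B")
                      for i in range(len(x + y))}
            p_pkg = differential_taxa(table, groups)[0]["p"]
            assert p_pkg == pytest.approx(mannwhitney_exact(x, y), abs=1e-9)

    def test_empty_group_rejected(self):
        table = pd.DataFrame({"s1": [1.0]}, index=["t"])
        with pytest.raises(ValueError):
            differential_taxa(table, {"s1": "A"})


class TestRateDifference:
    def test_identical_rates(self):
        assert rate_difference_test(5, 10, 5, 10) == 1.0

    def test_extreme_table_exact_value(self):
        from math import comb
        p = rate_difference_test(10, 10, 0, 10)
        assert p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 12)), int(rng.integers(2, 12))
            k1 = int(rng.integers(0, n1 + 1))
            k2 = int(rng.integers(0, n2 + 1))
            assert rate_difference_test(k1, n1, k2, n2) == pytest.approx(
                fisher_exact_two_sided(k1, n1, k2, n2), rel=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            rate_difference_test(1, 0, 0, 5)
        with pytest.raises(ValueError):
            rate_difference_test(6, 5, 0, 5)
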