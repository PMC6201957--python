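import numpy as np
import pytest

from itseval.cluster import pairwise_identity
from itseval.metrics import gc_content
from itseval.records import SeqRecord, lineage_ranks
from itseval.simulate import (CommunitySpec, DEFAULT_REGION_PARAMS,
                              RegionParams, build_reference_taxa,
                              default_amplicon_spec, default_community_spec,
                              default_lineages, read_filter,
                              simulate_community, simulate_reads,
                              spec_from_yaml, spec_to_yaml)


def zero_rate_params():
    return {r: RegionParams(mean_length=p.mean_length, sd_length=p.sd_length,
                            gc_target=p.gc_target)
            for r, p in DEFAULT_REGION_PARAMS.items()}


def two_species_spec(**kwargs):
    lineages = default_lineages(2, 1)
    species = [lineage_ranks(l)["species"] for l in lineages]
    return CommunitySpec(lineages=lineages,
                         samples={"S1": {sp: 3 for sp in species}},
                         **kwargs), species


class TestBuildReferenceTaxa:
    def test_zero_rates_give_identical_congeners(self):
        spec, species = two_species_spec(region_params=zero_rate_params())
        refs = build_reference_taxa(spec, seed=1)
        s1, s2 = (refs[sp] for sp in species)
        assert s1.sequence == s2.sequence
        assert s1.accession != s2.accession

    def test_structure_and_anchors(self):
        spec = default_community_spec(n_species=6, n_genera=3, seed=2)
        refs = build_reference_taxa(spec, seed=2)
        for rec in refs.values():
            f = rec.features
            seq = rec.sequence
            a = spec.anchors
            # region layout: flank5 | ITS1 | 5.8S | ITS2 | flank3
            assert seq[:f["ITS1"][0]].endswith(a.ssu_tail)
            assert seq[f["ITS1"][1]:].startswith(a.r58s_head)
            assert seq[:f["ITS2"][0]].endswith(a.r58s_tail)
            assert seq[f["ITS2"][1]:].startswith(a.lsu_head)

    def test_default_lengths_match_marker_averages(self):
        spec = default_community_spec(n_species=40, n_genera=40, seed=3)
        refs = build_reference_taxa(spec, seed=3)
        its1 = np.mean([r.features["ITS1"][1] - r.features["ITS1"][0]
                        for r in refs.values()])
        its2 = np.mean([r.features["ITS2"][1] - r.features["ITS2"][0]
                        for r in refs.values()])
        full = np.mean([r.features["ITS2"][1] - r.features["ITS1"][0]
                        for r in refs.values()])
        assert its1 == pytest.approx(177, abs=15)
        assert its2 == pytest.approx(182, abs=15)
        assert full == pytest.approx(517, abs=25)

    def test_gc_near_target(self):
        spec = default_community_spec(n_species=10, n_genera=5, seed=4)
        refs = build_reference_taxa(spec, seed=4)
        for rec in refs.values():
            for region in ("ITS1", "ITS2"):
                lo, hi = rec.features[region]
                gc = gc_content(rec.sequence[lo:hi])
                target = spec.region_params[region].gc_target
                assert abs(gc - target) <= 0.1

    def test_faster_region_diverges_more(self):
        """With ITS1 at twice the ITS2 rate, congeneric ITS1 identity is
        lower than ITS2 identity in nearly every seed."""
        wins = 0
        for seed in range(20):
            params = {
                "ITS1": RegionParams(177, 10, 0.5, interspecies_rate=0.10),
                "5.8S": DEFAULT_REGION_PARAMS["5.8S"],
                "ITS2": RegionParams(182, 10, 0.5, interspecies_rate=0.05),
            }
            spec = default_community_spec(n_species=10, n_genera=2, seed=seed,
                                          region_params=params)
            refs = build_reference_taxa(spec, seed=seed)
            by_genus = {}
            for sp, rec in refs.items():
                genus = sp.split("_")[0]
                by_genus.setdefault(genus, []).append(rec)
            idents = {"ITS1": [], "ITS2": []}
            for recs in by_genus.values():
                for i in range(len(recs)):
                    for j in range(i + 1, len(recs)):
                        for region in idents:
                            s1 = recs[i].sequence[slice(*recs[i].features[region])]
                            s2 = recs[j].sequence[slice(*recs[j].features[region])]
                            idents[region].append(pairwise_identity(s1, s2))
            if np.mean(idents["ITS1"]) < np.mean(idents["ITS2"]):
                wins += 1
        assert wins >= 18

    def test_determinism(self):
        spec = default_community_spec(n_species=8, n_genera=4, seed=9)
        r1 = build_reference_taxa(spec, seed=9)
        r2 = build_reference_taxa(spec, seed=9)
        assert {k: v.sequence for k, v in r1.items()} == \
            {k: v.sequence for k, v in r2.items()}

    def test_duplicate_lineage_rejected(self):
        lin = default_lineages(2, 1)
        with pytest.raises(ValueError):
            CommunitySpec(lineages=[lin[0], lin[0]], samples={})

    def test_58s_too_short_for_anchors_rejected(self):
        params = dict(DEFAULT_REGION_PARAMS)
        params["5.8S"] = RegionParams(mean_length=20)
        spec, _ = two_species_spec(region_params=params)
        with pytest.raises(ValueError):
            build_reference_taxa(spec, seed=1)


class TestSimulateCommunity:
    def test_zero_intraspecies_rate_copies_equal_reference(self):
        spec, species = two_species_spec(region_params=zero_rate_params())
        refs = build_reference_taxa(spec, seed=5)
        copies = simulate_community(refs, spec, seed=5)
        for rec in copies:
            assert rec.sequence == refs[rec.id.split(".")[1]].sequence

    def test_count_conservation(self):
        lineages = default_lineages(2, 2)
        species = [lineage_ranks(l)["species"] for l in lineages]
        spec = CommunitySpec(lineages=lineages,
                             samples={"S1": {species[0]: 3, species[1]: 2},
                                      "S2": {species[0]: 4}})
        refs = build_reference_taxa(spec, seed=6)
        copies = simulate_community(refs, spec, seed=6)
        assert len(copies) == 9
        assert sum(r.id.startswith("S1.") for r in copies) == 5

    def test_substitution_rate_recovered(self):
        """Observed per-site substitution fraction within 3 binomial SE."""
        rate = 0.02
        params = zero_rate_params()
        params["ITS1"] = RegionParams(500, 0, 0.5, intraspecies_rate=rate)
        lineages = default_lineages(1, 1)
        sp = lineage_ranks(lineages[0])["species"]
        spec = CommunitySpec(lineages=lineages, region_params=params,
                             samples={"S1": {sp: 100}})
        refs = build_reference_taxa(spec, seed=7)
        copies = simulate_community(refs, spec, seed=7)
        ref = refs[sp]
        lo, hi = ref.features["ITS1"]
        n_sites = sum(hi - lo for _ in copies)
        n_diff = sum(sum(x != y for x, y in zip(c.sequence[lo:hi],
                                                ref.sequence[lo:hi]))
                     for c in copies)
        se = np.sqrt(rate * (1 - rate) / n_sites)
        assert abs(n_diff / n_sites - rate) < 3 * se

    def test_unknown_species_rejected(self):
        spec, species = two_species_spec()
        refs = build_reference_taxa(spec, seed=1)
        bad = CommunitySpec(lineages=spec.lineages,
                            samples={"S1": {species[0]: 1}})
        bad.samples["S1"]["Ghost_sp"] = 1  # bypasses the constructor check
        with pytest.raises(KeyError):
            simulate_community(refs, bad, seed=1)


class TestSimulateReads:
    def _records(self):
        spec, species = two_species_spec(region_params=zero_rate_params())
        refs = build_reference_taxa(spec, seed=8)
        return simulate_community(refs, spec, seed=8)

    def test_error_free_reads_equal_template(self):
        recs = self._records()
        reads = simulate_reads(recs, error_rate=0.0, indel_fraction=0.0,
                               barcode="AACCGG", seed=1, tag_error_rate=0.0)
        for rec, read in zip(recs, reads):
            assert read.sequence == "AACCGG" + \
                "GGAAGTAAAAGTCGTAACAAGG" + rec.sequence
            assert len(read.qualities) == len(read.sequence)

    def test_per_sample_barcodes(self):
        recs = self._records()
        barcodes = {"S1": "TTTAAA"}
        reads = simulate_reads(recs, barcode=barcodes, seed=2,
                               tag_error_rate=0.0)
        assert all(r.sequence.startswith("TTTAAA") for r in reads)

    def test_substitution_count_within_binomial_error(self):
        template = SeqRecord(id="S1.sp.c0", sequence="A" * 10_000)
        reads = simulate_reads([template], error_rate=0.01,
                               indel_fraction=0.0, barcode="", primer="",
                               seed=3, tag_error_rate=0.0,
                               ambiguous_fraction=0.0)
        n_err = sum(c != "A" for c in reads[0].sequence)
        se = np.sqrt(10_000 * 0.01 * 0.99)
        assert abs(n_err - 100) < 3 * se

    def test_empty_template_list_rejected(self):
        with pytest.raises(ValueError):
            simulate_reads([], seed=1)


class TestReadFilter:
    def _read(self, seq, qual=35, barcode="AACCGG", primer="GG"):
        full = barcode + primer + seq
        return SeqRecord(id="r", sequence=full,
                         qualities=[qual] * len(full))

    def test_short_read_rejected_for_length(self):
        read = self._read("A" * 51)  # total 59 bp
        kept, rejected = read_filter([read], barcodes={"AACCGG"}, primer="GG")
        assert not kept
        assert rejected[0][1] == ["length"]

    def test_ambiguous_base_rejected(self):
        read = self._read("ACGT" * 20 + "N")
        kept, rejected = read_filter([read], barcodes={"AACCGG"}, primer="GG")
        assert rejected[0][1] == ["ambiguous"]

    def test_low_mean_quality_rejected_boundary(self):
        ok = self._read("ACGT" * 30, qual=31)
        at_threshold = self._read("ACGT" * 30, qual=30)  # <= 30 fails
        kept, rejected = read_filter([ok, at_threshold], barcodes={"AACCGG"},
                                     primer="GG")
        assert [r.id for r in kept] == ["r"]
        assert rejected[0][1] == ["quality"]

    def test_wrong_barcode_rejected(self):
        read = self._read("ACGT" * 30, barcode="CCCCCC")
        kept, rejected = read_filter([read], barcodes={"AACCGG"}, primer="GG")
        assert rejected[0][1] == ["tag"]

    def test_good_read_kept_and_partition(self):
        reads = [self._read("ACGT" * 25),
                 self._read("ACGT" * 25, qual=20),
                 self._read("AN", qual=20, barcode="CCCCCC")]
        kept, rejected = read_filter(reads, barcodes={"AACCGG"}, primer="GG")
        assert len(kept) + len(rejected) == 3
        assert len(kept) == 1
        # all reasons enumerated for the multiply-bad read
        assert set(rejected[1][1]) == {"length", "quality", "ambiguous", "tag"}

    def test_empty_input(self):
        kept, rejected = read_filter([], barcodes={"AACCGG"})
        assert kept == [] and rejected == []


class TestDeterminismAndConfig:
    def test_reads_deterministic_given_seed(self):
        spec = default_community_spec(n_species=4, n_genera=2,
                                      copies_per_species=2, seed=11)
        refs = build_reference_taxa(spec, seed=11)
        com = simulate_community(refs, spec, seed=11)
        r1 = simulate_reads(com, seed=11)
        r2 = simulate_reads(com, seed=11)
        assert [(r.sequence, r.qualities) for r in r1] == \
            [(r.sequence, r.qualities) for r in r2]

    def test_spec_yaml_round_trip(self, tmp_path):
        spec, groups, barcodes = default_amplicon_spec(n_species=6,
                                                       n_genera=3, seed=12)
        path = tmp_path / "spec.yaml"
        spec_to_yaml(spec, path)
        back = spec_from_yaml(path)
        assert back.lineages == spec.lineages
        assert back.samples == spec.samples
        assert back.region_params == spec.region_params
        assert back.anchors == spec.anchors
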