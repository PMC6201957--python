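# itseval

Compare the full-length fungal ITS region against its two spacers, ITS1 and
ITS2, as metabarcoding markers.

Short-read platforms rarely cover the full ITS1–5.8S–ITS2 region, so fungal
community studies sequence one spacer and treat its OTUs as species proxies.
Because ITS1 evolves faster (and varies more in length) than ITS2, the two
spacers can partition the *same* underlying reads into quite different OTUs,
with consequences for richness estimates, cross-study comparability and
taxonomic assignment. `itseval` quantifies those consequences on synthetic
fungal communities whose true taxonomy, region boundaries and per-region
substitution rates are known and controllable.

## What it computes

Given full-length sequences (simulated, or any FASTA with taxonomy-annotated
headers), the pipeline:

1. **extracts** ITS1 and ITS2 via conserved anchor motifs (SSU tail, 5.8S
   termini, LSU head), the role ITSx plays on real data;
2. **clusters** each region with greedy centroid clustering at identity
   thresholds 0.91–0.99 (the UCLUST role), under a semi-global identity with
   free terminal gaps;
3. **profiles** length, GC content and the extreme-value filters
   (<100/>600 bp, <20%/>80% GC) per taxonomic group;
4. **scores diversity** per sample: bias-corrected Chao1
   `S_obs + F1(F1−1)/(2(F2+1))`, Shannon `H = −Σ p_i ln p_i`, and UPGMA
   dendrograms on Bray–Curtis dissimilarities;
5. **measures cross-region commonality**: for each OTU of database 1, find
   the database-2 OTU containing its representative sequence and count the
   shared reads *m*; then

   ```
   A = (Σ over the n OTUs of database 1 of m) / N
   ```

   with *N* the reads in database 1. `A(c, c) = 1`; A is directional and
   both directions are reported;
6. **evaluates taxonomic resolution**: best-hit identity search against a
   reference database — self-return rate (best hit is the query's own
   accession), species-agreement rate, and classified/unclassified
   composition per rank — plus Fisher's exact and exact Mann–Whitney U
   tests for group differences.

The synthetic-community generator is first-class: hierarchical taxonomy
(phylum→species), per-region length/GC/rate parameters (defaults: ITS1
177 bp and twice the ITS2 substitution rate, ITS2 182 bp, conserved 158 bp
5.8S, full ITS ≈ 517 bp), per-lineage rate heterogeneity, multi-sample
abundance profiles, 454-style reads with barcodes, primers, quality mixtures
and the classic trim filter (length < 60, mean quality ≤ 30, ambiguous
bases, inexact tag).

## Worked example

```python
from itseval import (default_community_spec, build_reference_taxa,
                     simulate_community, greedy_cluster, commonality,
                     chao1, shannon)
from itseval.extract import extract_all
from itseval.simulate import sister_species_params

spec = default_community_spec(n_species=30, n_genera=5, copies_per_species=6,
                              seed=7, region_params=sister_species_params())
refs = build_reference_taxa(spec)
community = simulate_community(refs, spec)
regions, _ = extract_all(community, spec.anchors)

clusterings = {label: greedy_cluster(regions[label], 0.97, label)
               for label in ("ITS", "ITS1", "ITS2")}
for label, c in clusterings.items():
    counts = [len(otu.member_ids) for otu in c.otus]
    print(f"{label:5s} {len(c.otus):3d} OTUs  "
          f"Chao1 {chao1(counts):6.1f}  Shannon {shannon(counts):.3f}")

a = commonality(clusterings["ITS"], clusterings["ITS2"])
b = commonality(clusterings["ITS"], clusterings["ITS1"])
print(f"commonality A(ITS vs ITS2) = {a.A:.3f}")
print(f"commonality A(ITS vs ITS1) = {b.A:.3f}")
```

Output:

```
ITS    13 OTUs  Chao1   14.0  Shannon 2.177
ITS1   20 OTUs  Chao1   20.0  Shannon 2.735
ITS2   11 OTUs  Chao1   11.5  Shannon 2.039
commonality A(ITS vs ITS2) = 0.861
commonality A(ITS vs ITS1) = 0.644
```

Reading: 180 reads from 30 species of close relatives. The faster spacer
(ITS1) splits them into 20 OTUs and inflates richness, the slower ITS2 into
11; the full-length clustering agrees far better with ITS2 (A = 0.86) than
with ITS1 (A = 0.64) — the marker contrast the pipeline is built to
quantify.

The same analyses are available from the shell:

```bash
itseval simulate --species 30 --genera 5 --copies 6 --seed 7 --out sim/
itseval extract sim/community.fasta --out regions/
itseval cluster regions/ITS2.fasta --threshold 0.97 --out its2_otus.tsv
itseval commonality its_otus.tsv its2_otus.tsv
itseval run-insilico --species 30 --seed 7 --out run/     # everything above
itseval run-amplicon --samples 10 --seed 7 --out amp/     # read-based study
```

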