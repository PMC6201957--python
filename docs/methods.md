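# Methods

This note documents the models, numerical choices and known limitations of
`itseval`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic community model

The generator replaces real reference databases and sequencing runs with
communities whose ground truth is known exactly.

**Taxonomy and ancestry.** A community is a list of six-rank lineages
(phylum→species). Genera receive independently drawn ancestral spacer
sequences — real ITS spacers are effectively unalignable between genera, so
no deeper homology is modelled. Species are their genus ancestor with
substitutions applied independently per region; copies of a species add
substitutions at a (smaller) intraspecific rate. The 5.8S gene and the
flanking SSU/LSU stubs are drawn once per community and, with the default
zero 5.8S rates, are perfectly conserved — they double as the extraction
anchors.

**Substitutions.** Per region, the number of substitutions is
Binomial(L, rate); sites are chosen without replacement and changed to a
uniformly chosen different base. Indels occur only during read simulation,
so every community sequence inherits its reference's region coordinates
exactly — this is what makes extraction exactly testable. Effective rates
are capped at 0.5/site.

**Rate heterogeneity (`rate_cv`).** Real spacers evolve idiosyncratically:
sister species can be identical in ITS1 yet distinct in ITS2, and vice
versa. A strict molecular clock (same rate on every branch) makes the
ITS1/ITS2/ITS partitions nearly nested, which erases precisely the
cross-cutting disagreement the commonality statistic exists to measure. So
each (species-branch, region) pair scales its substitution rate by an
independent Gamma multiplier with mean 1 and coefficient of variation
`rate_cv` (default 1, i.e. exponential; truncated at 3 to bound composition
drift). Setting `rate_cv = 0` restores the clock.

**Lengths and GC.** Region lengths are truncated-normal draws at the genus
level, rounded to integers (spacers ≥ 10 bp; 5.8S at least its two anchor
motifs). Defaults: ITS1 177 ± 28 bp, 5.8S 158 ± 2 bp, ITS2 182 ± 14 bp, so
full ITS averages ≈ 517 bp, and ITS1 is the more length-variable spacer.
Base composition is drawn with an exact GC count (`round(L·gc_target)`
G/C positions, uniformly placed, G vs C and A vs T equiprobable) rather
than i.i.d. per-site draws, so generated regions sit within ±0.1 of the
target deterministically at any length; defaults put ITS2 (0.55) above ITS1
(0.50). Substitution drift toward 0.5 GC is bounded by the rate cap.

**Default rates.** ITS1 evolves at twice the ITS2 rate throughout
(interspecies 0.06 vs 0.03 substitutions/site/branch, intraspecific 0.02 vs
0.01), with the 5.8S fixed at 0. These defaults put intraspecific ITS1
divergence (~4%) just above a 97% clustering threshold and ITS2 (~2%) just
below it — the regime where the marker choice visibly changes OTU counts. A
second ready-made configuration, `sister_species_params()`, scales
interspecies rates down (0.02/0.01) so congeners sit near the thresholds
and OTUs at 91–97% lump several species, emulating a reference database
dense in close relatives; the threshold sweep and species-per-OTU analyses
use it.

**Reads.** One 454-style read per template: barcode + primer (ITS5/ITS4
sequences are provided as constants) + the template, optionally truncated
by a normal read-length draw. Substitution errors hit the template at
`error_rate` (default 0.005, a twentieth becoming N), indels at
`indel_fraction`; a small `tag_error_rate` corrupts barcodes/primers so the
trim filter has genuine rejects. Qualities come from a good/bad
two-component per-read mixture (phred ≈ N(37,2) vs N(22,5), clipped to
[2, 40], +33 encoding) so that roughly `bad_read_fraction` of reads fail a
mean-quality-30 threshold.

**The trim filter.** A read is rejected iff length < 60, quality score
≤ 30, it contains an ambiguous base, or the barcode+primer prefix is not an
exact match; all applicable reasons are reported. Whether the historical
quality criterion meant the read mean or a sliding window is ambiguous;
mean is the default, `quality_mode="window"` the alternative.

**What the generator does not emulate:** chimeras, PCR amplification bias,
homopolymer-specific 454 error spectra, introns (a real driver of extreme
ITS1 lengths), length variation below the genus level, and reverse-oriented
deposits (extraction offers an optional reverse-complement pre-pass, off by
default). Passing tests therefore demonstrate correctness of the analysis
machinery and recovery of rate-driven contrasts, not robustness to every
artefact of real amplicon data.

## Region extraction

Anchor motifs are located by exact sliding-window Hamming distance:
leftmost position of minimal distance, reported only if within
`max_mismatch` (default 2). ITS1 spans from the end of the SSU-tail hit to
the start of the 5.8S head; ITS2 from the end of the 5.8S tail to the start
of the LSU head; coordinates are 0-based half-open. Anchors out of order
give status `failed` (never an exception); a missing side degrades the
status to `its1_only`/`its2_only`. Profile HMMs would tolerate more anchor
divergence; motif anchoring was chosen because it is self-contained and its
behaviour on simulated data is exactly predictable. No minimum spacer
length is imposed.

## Pairwise identity and clustering

Identity is computed from a semi-global alignment: unit match/mismatch/gap
scoring, terminal gap runs free and excluded from the denominator, so

    identity = matches / (matches + mismatches + internal gap columns)

over the maximum-score path. Ties are deterministic (diagonal over
vertical over horizontal within cells; higher score, then longer alignment
at the end points), and arguments are canonically ordered before alignment
so identity is exactly symmetric. If no alignment scores above zero the
identity is 0.

Greedy centroid clustering processes records in a fixed order — length
descending, then abundance descending (when dereplicated counts are
supplied), then id — and each record joins the **first** centroid at or
above the threshold, else founds a new OTU. First-hit is the classic greedy
rule; `best_hit=True` gives the best-scoring centroid instead for
sensitivity analysis. The partition invariant is validated after every run.
Input order matters for any greedy clusterer, which is why the policy is
part of the contract; no dereplication is performed by default.

Two accelerations keep desk-scale runs fast, both lossless for genuine
hits:

* **k-mer prescreen** — candidate centroids sharing no 12-mer with the
  query are skipped. An alignment of C ≥ 100 columns at ≥ 91% identity must
  contain an exact run of ≥ 12 bases (pigeonhole over at most
  ⌊0.09·C⌋ errors), so the screen cannot drop a real hit; it is disabled
  below 100 bp.
* **banded alignment** — for sequences ≥ 100 bp the DP is restricted to
  diagonals within the length difference plus the gap budget an
  above-threshold alignment could spend (⌈(1−t)·L⌉ + 8). Any path meeting
  the threshold fits in the band, so accept/reject decisions match the full
  kernel; only degenerate short terminal overlaps (which never reach
  clustering thresholds on realistic sequences) could be scored
  differently.

The public `pairwise_identity` always uses the full kernel.

## Diversity and dendrograms

Chao1 uses the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)) (equal to
S_obs when F1 ≤ 1); Shannon uses natural log by default with a `base`
argument for log2/log10. Sample dendrograms: columns are normalised to
relative abundances, Bray–Curtis dissimilarities feed average-linkage
(UPGMA) agglomeration, and the tree is written as newick with ultrametric
branch lengths (leaf-to-node depth = merge height / 2). Columns are sorted
lexicographically first, so the output is independent of input column
order; the distance metric and linkage are arguments because no single
convention is canonical for such figures.

## Commonality

For each OTU of database 1, the matched database-2 OTU is the one
containing the representative sequence (representative containment, the
procedure's published matching rule — not maximum overlap, which is
available behind `max_overlap=True` for sensitivity analysis); m is the
size of the membership intersection, counted through a shared read key that
strips `/ITS`, `/ITS1`, `/ITS2` suffixes, since all three region records
derive from the same full-length read. A = Σm/N with N the database-1 read
count. Consequences worth knowing: A(c, c) = 1 exactly; A is directional
(if c1 refines c2, A(c1→c2) = 1 while A(c2→c1) can be small), so both
directions are always reported; when extraction failures shrink one
universe, missing reads simply contribute nothing to m (N stays |c1|), and
`restrict_shared=True` recomputes on the intersection instead.

Species-per-OTU counts distinct species binomials among each OTU's members
and averages over OTUs.

## Taxonomic resolution

Best-hit search is an exhaustive identity scan (no E-values, no heuristic
seeding — at package scale exactness is cheaper than approximation), ties
broken by longer reference then smallest accession, so database order never
matters. Self-return searches include the query's own record (that is what
makes the rate informative: identical regions across species steal hits via
the tie policy); `exclude_self=True` gives leave-one-out behaviour.
Species agreement can never be below self-return, since an identical
accession implies an identical binomial. Rank composition counts a query as
classified at a rank iff its best-hit lineage names that rank and the hit
identity clears a configurable floor (default 0, i.e. pure best-hit label
transfer).

Group tests: Fisher's exact (two-sided by summing tables no more probable
than observed) for rate differences; Mann–Whitney U for per-taxon abundance
differences, exact null at the study's group sizes (≤ 8 per group), normal
approximation above that or when ties make the exact null unavailable;
identical constant groups are pinned to p = 1. The pooled-variance
two-sample t (Welch behind a flag) covers length/GC comparisons, with fixed
conventions for degenerate variance.

## Pipeline scales and determinism

All randomness flows from a single integer seed, split per operation by
hashing stable operation tags, so every bundle re-runs byte-identically;
every stage writes its artifact (FASTA/FASTQ, TSV, newick, JSON manifest)
so later stages can be re-run from files. The packaged study sizes — the
default 50 species × 20 copies community for rate-contrast analyses, the
30 species × 6 copies sister-species community for threshold sweeps, and a
10-sample/3-group design of ~1,600 reads for the amplicon study — were
chosen so the qualitative contrasts of interest (OTU inflation by the
faster spacer, commonality ordering, marker-taxon detection) are stable
across seeds while a full analysis completes in minutes on one CPU.

## Known limitations

* Motif anchors fail on sequences whose 5.8S termini diverge beyond
  `max_mismatch`; ITSx-style profile HMMs are strictly more sensitive.
* The identity definition is one of several in use (tools differ in how
  they count terminal gaps and internal gap columns); absolute OTU counts
  are therefore comparable only within this package, though threshold
  *trends* are robust to the convention.
* Greedy clustering is order-sensitive by nature; the fixed ordering policy
  makes results reproducible, not order-free.
* Chao1 is reported without a variance estimate, and no rarefaction is
  performed; sample depths in the simulated designs are comparable by
  construction.
* Taxonomic "classification" is best-hit label transfer; no lowest common
  ancestor or naive-Bayes smoothing is attempted.
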