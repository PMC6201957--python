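"""Synthetic fungal ITS communities, amplicon reads and the read filter.

The generator emulates the statistical structure a marker-comparison
analysis needs from real data without shipping any: a hierarchical taxonomy
(phylum..species), per-region length and GC profiles (ITS1 ~177 bp, 5.8S
~158 bp, ITS2 ~182 bp, full ITS ~517 bp), a faster-evolving ITS1 than ITS2,
a conserved 5.8S that doubles as the extraction anchor, multi-sample
abundance profiles, and 454-style reads with quality scores and tag errors.

Evolution model
---------------
Each genus receives independently drawn ancestral spacers; species are the
genus ancestor with substitutions applied per region at
``interspecies_rate``; copies within a species add substitutions at
``intraspecies_rate``.  Substitutions hit uniformly chosen sites and change
the base to a uniformly chosen different base; indels occur only during
read simulation, so region boundaries of community sequences are known
exactly.

Real spacers evolve idiosyncratically: a pair of sister species can be
identical in ITS1 yet clearly distinct in ITS2, or vice versa, which is what
makes OTU partitions of the two spacers cross-cut rather than nest.  To
reproduce that, each (species, region) branch scales its substitution rate
by a random multiplier with mean 1 (Gamma with coefficient of variation
``rate_cv``, truncated at 3); independent multipliers per region decorrelate
the two spacers' divergences while preserving the configured mean rates.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .extract import AnchorSet
from .records import RANKS, SeqRecord, format_lineage, lineage_ranks

REGIONS = ("ITS1", "5.8S", "ITS2")

#: primers of the classic fungal ITS amplicon
PRIMER_ITS5 = "GGAAGTAAAAGTCGTAACAAGG"
PRIMER_ITS4 = "ATCCTCCGCTTATTGATATGC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_RATE_CAP = 0.5
_MULT_CAP = 3.0


@dataclass(frozen=True)
class RegionParams:
    """Length, composition and substitution-rate knobs for one region."""

    mean_length: int
    sd_length: float = 0.0
    gc_target: float = 0.5
    interspecies_rate: float = 0.0
    intraspecies_rate: float = 0.0
    #: coefficient of variation of the per-branch rate multiplier (0 = clock)
    rate_cv: float = 1.0

    def __post_init__(self) -> None:
        if self.mean_length < 10:
            raise ValueError("mean_length must be >= 10")
        if not (0.0 <= self.gc_target <= 1.0):
            raise ValueError("gc_target must be in [0, 1]")
        if self.sd_length < 0 or self.interspecies_rate < 0 \
                or self.intraspecies_rate < 0 or self.rate_cv < 0:
            raise ValueError("sd_length, rates and rate_cv must be >= 0")


#: default per-region parameters: mean lengths from the empirical averages
#: (ITS1 177 bp, ITS2 182 bp, total ITS ~517 bp), ITS1 twice as fast and
#: more length-variable than ITS2, ITS2 the more GC-rich spacer, 5.8S
#: conserved.
DEFAULT_REGION_PARAMS: dict[str, RegionParams] = {
    "ITS1": RegionParams(mean_length=177, sd_length=28, gc_target=0.50,
                         interspecies_rate=0.06, intraspecies_rate=0.02),
    "5.8S": RegionParams(mean_length=158, sd_length=2, gc_target=0.50,
                         interspecies_rate=0.0, intraspecies_rate=0.0),
    "ITS2": RegionParams(mean_length=182, sd_length=14, gc_target=0.55,
                         interspecies_rate=0.03, intraspecies_rate=0.01),
}


@dataclass
class CommunitySpec:
    """Everything needed to synthesise a community deterministically."""

    lineages: list[str]
    region_params: dict[str, RegionParams] = field(
        default_factory=lambda: dict(DEFAULT_REGION_PARAMS))
    anchors: AnchorSet = field(default_factory=AnchorSet)
    #: sample id -> {species binomial -> copy count}
    samples: dict[str, dict[str, int]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(set(self.lineages)) != len(self.lineages):
            raise ValueError("duplicate lineages")
        self._species = []
        for lin in self.lineages:
            self._species.append(lineage_ranks(lin)["species"])
        if len(set(self._species)) != len(self._species):
            raise ValueError("duplicate species binomials")
        missing = set(REGIONS) - set(self.region_params)
        if missing:
            raise ValueError(f"region_params missing {sorted(missing)}")
        sampled = {sp for prof in self.samples.values() for sp in prof}
        unknown = sampled - set(self._species)
        if unknown:
            raise ValueError(f"unknown species in samples: {sorted(unknown)}")

    @property
    def species(self) -> list[str]:
        return list(self._species)

    def lineage_of(self) -> dict[str, str]:
        return dict(zip(self._species, self.lineages))


def _rng(seed: int, tag: str) -> np.random.Generator:
    """A generator deterministically derived from the top-level seed."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF,
                                  zlib.crc32(tag.encode()) & 0x7FFFFFFF])


def _random_seq(rng: np.random.Generator, length: int, gc_target: float) -> str:
    """Random sequence whose GC count is fixed at round(length * gc_target)."""
    n_gc = int(round(length * gc_target))
    arr = np.empty(length, dtype=np.uint8)
    gc = rng.choice(np.frombuffer(b"GC", dtype=np.uint8), size=n_gc)
    at = rng.choice(np.frombuffer(b"AT", dtype=np.uint8), size=length - n_gc)
    pos = rng.permutation(length)
    arr[pos[:n_gc]] = gc
    arr[pos[n_gc:]] = at
    return arr.tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, sequence: str, rate: float) -> str:
    """Per-site substitutions at the given rate, to a different base."""
    if rate <= 0 or not sequence:
        return sequence
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8).copy()
    n_sub = rng.binomial(len(arr), min(rate, _RATE_CAP))
    if n_sub == 0:
        return sequence
    pos = rng.choice(len(arr), size=n_sub, replace=False)
    shift = rng.integers(1, 4, size=n_sub)
    idx = np.searchsorted(_BASES, arr[pos])
    arr[pos] = _BASES[(idx + shift) % 4]
    return arr.tobytes().decode("ascii")


def _branch_rate(rng: np.random.Generator, rate: float, cv: float) -> float:
    if rate <= 0:
        return 0.0
    if cv <= 0:
        return rate
    # gamma(shape, scale) with shape = 1/cv^2, scale = cv^2 has mean 1
    mult = min(rng.gamma(1.0 / cv**2, cv**2), _MULT_CAP)
    return rate * mult


def _draw_length(rng: np.random.Generator, params: RegionParams,
                 minimum: int) -> int:
    raw = rng.normal(params.mean_length, params.sd_length)
    return max(minimum, int(round(raw)))


def build_reference_taxa(spec: CommunitySpec, seed: int | None = None
                         ) -> dict[str, SeqRecord]:
    """One full-length reference per species, UNITE-database style.

    Each reference is flank5 + ITS1 + 5.8S + ITS2 + flank3; the flanks and
    the 5.8S termini carry the anchor motifs verbatim.  Species within a
    genus descend from a shared, independently drawn genus ancestor.
    """
    if seed is None:
        seed = spec.seed
    anchors = spec.anchors
    p58 = spec.region_params["5.8S"]
    core = len(anchors.r58s_head) + len(anchors.r58s_tail)
    if p58.mean_length < core:
        raise ValueError("5.8S mean_length too short to hold its anchors")

    root_rng = _rng(seed, "refs/root")
    flank5 = _random_seq(root_rng, 20, 0.5) + anchors.ssu_tail
    flank3 = anchors.lsu_head + _random_seq(root_rng, 20, 0.5)
    len58 = _draw_length(root_rng, p58, core)
    middle58 = _random_seq(root_rng, len58 - core, p58.gc_target)

    by_genus: dict[str, list[str]] = {}
    for lin in sorted(spec.lineages):
        by_genus.setdefault(lineage_ranks(lin)["genus"], []).append(lin)

    lineage_of = spec.lineage_of()
    refs: dict[str, SeqRecord] = {}
    acc_index = {sp: i for i, sp in enumerate(sorted(spec.species))}
    for genus in sorted(by_genus):
        grng = _rng(seed, f"refs/genus/{genus}")
        ancestor = {}
        for region in ("ITS1", "ITS2"):
            params = spec.region_params[region]
            length = _draw_length(grng, params, 10)
            ancestor[region] = _random_seq(grng, length, params.gc_target)
        ancestor["5.8S"] = middle58
        for lin in by_genus[genus]:
            species = lineage_ranks(lin)["species"]
            srng = _rng(seed, f"refs/species/{species}")
            segs = {}
            for region in ("ITS1", "ITS2"):
                params = spec.region_params[region]
                rate = _branch_rate(srng, params.interspecies_rate,
                                    params.rate_cv)
                segs[region] = _mutate(srng, ancestor[region], rate)
            mid = _mutate(srng, ancestor["5.8S"],
                          _branch_rate(srng, p58.interspecies_rate,
                                       p58.rate_cv))
            r58s = anchors.r58s_head + mid + anchors.r58s_tail
            seq = flank5 + segs["ITS1"] + r58s + segs["ITS2"] + flank3
            a = len(flank5)
            b = a + len(segs["ITS1"])
            c = b + len(r58s)
            d = c + len(segs["ITS2"])
            refs[species] = SeqRecord(
                id=f"REF{acc_index[species]:05d}", sequence=seq,
                lineage=lin,
                accession=f"REF{acc_index[species]:05d}",
                features={"ITS1": (a, b), "5.8S": (b, c), "ITS2": (c, d)})
    return refs


def simulate_community(refs: Mapping[str, SeqRecord], spec: CommunitySpec,
                       seed: int | None = None) -> list[SeqRecord]:
    """Draw the requested per-sample copies, mutating each copy per region.

    Ids follow ``sample.species.cNNN`` so the sample and species of origin
    are recoverable; region boundaries are inherited from the reference.
    """
    if seed is None:
        seed = spec.seed
    out: list[SeqRecord] = []
    for sample in sorted(spec.samples):
        profile = spec.samples[sample]
        for species in sorted(profile):
            if species not in refs:
                raise KeyError(f"species {species!r} not in references")
            ref = refs[species]
            count = int(profile[species])
            crng = _rng(seed, f"community/{sample}/{species}")
            f = ref.features
            for k in range(count):
                parts = [ref.sequence[:f["ITS1"][0]]]
                for region in REGIONS:
                    lo, hi = f[region]
                    seg = ref.sequence[lo:hi]
                    rate = spec.region_params[region].intraspecies_rate
                    if region == "5.8S":
                        # keep the anchor termini intact; mutate the interior
                        head = len(spec.anchors.r58s_head)
                        tail = len(spec.anchors.r58s_tail)
                        seg = seg[:head] + _mutate(crng, seg[head:len(seg) - tail],
                                                   rate) + seg[len(seg) - tail:]
                    else:
                        seg = _mutate(crng, seg, rate)
                    parts.append(seg)
                parts.append(ref.sequence[f["ITS2"][1]:])
                out.append(SeqRecord(
                    id=f"{sample}.{species}.c{k:04d}",
                    sequence="".join(parts), lineage=ref.lineage,
                    accession=ref.accession, features=dict(f)))
    return out


def sample_of_id(record_id: str) -> str:
    """Sample of origin for ids shaped ``sample.species.cNNN[/region]``."""
    return record_id.split(".", 1)[0]


def species_of_id(record_id: str) -> str:
    return record_id.split(".")[1]


def simulate_reads(records: Sequence[SeqRecord], *,
                   error_rate: float = 0.005,
                   indel_fraction: float = 0.001,
                   barcode: str | Mapping[str, str] = "ACGTAC",
                   primer: str = PRIMER_ITS5,
                   seed: int = 0,
                   read_length_mean: float | None = None,
                   read_length_sd: float = 80.0,
                   bad_read_fraction: float = 0.10,
                   ambiguous_fraction: float = 0.05,
                   tag_error_rate: float = 0.01) -> list[SeqRecord]:
    """454-style reads: barcode + primer + (possibly truncated) template.

    Substitutions and indels hit the template at the stated rates (a
    fraction of substitutions become N); per-base qualities come from a
    good/bad two-component mixture so that roughly ``bad_read_fraction`` of
    reads fall below a mean-quality-30 trim threshold; ``tag_error_rate`` of
    reads get a corrupted barcode/primer prefix.  One read per template.
    """
    if not records:
        raise ValueError("empty template list")
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must be in [0, 0.5)")

    reads = []
    for rec in records:
        rrng = _rng(seed, f"reads/{rec.id}")
        if isinstance(barcode, str):
            tag = barcode
        else:
            tag = barcode[sample_of_id(rec.id)]
        template = rec.sequence
        if read_length_mean is not None:
            tlen = int(round(rrng.normal(read_length_mean, read_length_sd)))
            template = template[:max(30, min(len(template), tlen))]
        chars = []
        for base in template:
            u = rrng.random()
            if u < indel_fraction / 2:
                continue  # deletion
            if u < indel_fraction:
                chars.append(chr(_BASES[rrng.integers(4)]))  # insertion
            if rrng.random() < error_rate:
                if rrng.random() < ambiguous_fraction:
                    chars.append("N")
                else:
                    old = base
                    new = old
                    while new == old:
                        new = chr(_BASES[rrng.integers(4)])
                    chars.append(new)
            else:
                chars.append(base)
        prefix = tag + primer
        if rrng.random() < tag_error_rate and prefix:
            pos = int(rrng.integers(len(prefix)))
            old = prefix[pos]
            new = old
            while new == old:
                new = chr(_BASES[rrng.integers(4)])
            prefix = prefix[:pos] + new + prefix[pos + 1:]
        seq = prefix + "".join(chars)
        good = rrng.random() >= bad_read_fraction
        mu, sd = (37.0, 2.0) if good else (22.0, 5.0)
        quals = np.clip(np.round(rrng.normal(mu, sd, size=len(seq))),
                        2, 40).astype(int).tolist()
        reads.append(SeqRecord(id=rec.id, sequence=seq, qualities=quals,
                               lineage=rec.lineage, accession=rec.accession))
    return reads


def read_filter(reads: Sequence[SeqRecord], *,
                min_length: int = 60, min_quality: float = 30.0,
                barcodes: Iterable[str], primer: str = PRIMER_ITS5,
                quality_mode: str = "mean", window: int = 25
                ) -> tuple[list[SeqRecord], list[tuple[SeqRecord, list[str]]]]:
    """The raw-read trim filter.

    A read is rejected iff it is shorter than ``min_length``, its quality
    score is <= ``min_quality``, it contains an ambiguous base, or its
    barcode+primer prefix is not an exact match.  ``quality_mode='mean'``
    (default) applies the threshold to the read-mean quality;
    ``'window'`` to the minimum sliding-window mean.  All applicable
    rejection reasons are reported per read.
    """
    barcode_set = set(barcodes)
    kept: list[SeqRecord] = []
    rejected: list[tuple[SeqRecord, list[str]]] = []
    for read in reads:
        if read.qualities is None:
            raise ValueError(f"read {read.id!r} has no qualities")
        reasons = []
        if len(read.sequence) < min_length:
            reasons.append("length")
        q = np.asarray(read.qualities, dtype=float)
        if quality_mode == "mean":
            score = q.mean()
        elif quality_mode == "window":
            if len(q) <= window:
                score = q.mean()
            else:
                csum = np.concatenate([[0.0], np.cumsum(q)])
                score = ((csum[window:] - csum[:-window]) / window).min()
        else:
            raise ValueError(f"unknown quality_mode {quality_mode!r}")
        if score <= min_quality:
            reasons.append("quality")
        if "N" in read.sequence:
            reasons.append("ambiguous")
        if not any(read.sequence.startswith(b + primer) for b in barcode_set):
            reasons.append("tag")
        if reasons:
            rejected.append((read, reasons))
        else:
            kept.append(read)
    return kept, rejected


def demultiplex(reads: Sequence[SeqRecord], barcode_of_sample: Mapping[str, str],
                primer: str = PRIMER_ITS5) -> dict[str, list[SeqRecord]]:
    """Assign filtered reads to samples by barcode and strip the prefix."""
    by_barcode = {v: k for k, v in barcode_of_sample.items()}
    out: dict[str, list[SeqRecord]] = {s: [] for s in barcode_of_sample}
    for read in reads:
        for bc, sample in by_barcode.items():
            prefix = bc + primer
            if read.sequence.startswith(prefix):
                out[sample].append(SeqRecord(
                    id=read.id, sequence=read.sequence[len(prefix):],
                    qualities=None if read.qualities is None
                    else read.qualities[len(prefix):],
                    lineage=read.lineage, accession=read.accession))
                break
    return out


def sister_species_params() -> dict[str, RegionParams]:
    """Region parameters for a database-style community of close relatives.

    Interspecies divergence sits near the clustering thresholds (congeners
    0-6% apart), so OTUs at 91-97% lump several species, as reference
    databases dense in sister species do; intraspecific variation is kept
    small.  The ITS1:ITS2 rate ratio stays at 2.
    """
    return {
        "ITS1": replace(DEFAULT_REGION_PARAMS["ITS1"],
                        interspecies_rate=0.02, intraspecies_rate=0.004),
        "5.8S": DEFAULT_REGION_PARAMS["5.8S"],
        "ITS2": replace(DEFAULT_REGION_PARAMS["ITS2"],
                        interspecies_rate=0.01, intraspecies_rate=0.002),
    }


# ---------------------------------------------------------------------------
# ready-made community specifications

_PHYLA = [("Ascomycota", "Sordariomycetes", "Hypocreales", "Nectriaceae"),
          ("Ascomycota", "Dothideomycetes", "Pleosporales", "Pleosporaceae"),
          ("Basidiomycota", "Agaricomycetes", "Agaricales", "Tricholomataceae"),
          ("Basidiomycota", "Tremellomycetes", "Tremellales", "Tremellaceae"),
          ("Mortierellomycota", "Mortierellomycetes", "Mortierellales",
           "Mortierellaceae")]


def default_lineages(n_species: int, n_genera: int) -> list[str]:
    """A balanced six-rank taxonomy over a handful of fungal clades."""
    if n_genera < 1 or n_species < n_genera:
        raise ValueError("need 1 <= n_genera <= n_species")
    lineages = []
    for i in range(n_species):
        g = i % n_genera
        phylum, cls, order, family = _PHYLA[g % len(_PHYLA)]
        genus = f"Gen{g + 1:02d}"
        species = f"{genus}_sp{i + 1:03d}"
        lineages.append(format_lineage({
            "phylum": phylum, "class": cls, "order": order,
            "family": family, "genus": genus, "species": species}))
    return lineages


def default_community_spec(n_species: int = 50, n_genera: int = 10,
                           copies_per_species: int = 20, seed: int = 0,
                           region_params: dict[str, RegionParams] | None = None
                           ) -> CommunitySpec:
    """The standard single-sample in-silico community (database emulation)."""
    lineages = default_lineages(n_species, n_genera)
    species = [lineage_ranks(l)["species"] for l in lineages]
    samples = {"S1": {sp: copies_per_species for sp in species}}
    return CommunitySpec(lineages=lineages,
                         region_params=region_params or dict(DEFAULT_REGION_PARAMS),
                         samples=samples, seed=seed)


def default_amplicon_spec(n_species: int = 30, n_genera: int = 6,
                          n_samples: int = 10, mean_copies: int = 12,
                          marker_species_boost: float = 20.0, seed: int = 0
                          ) -> tuple[CommunitySpec, dict[str, str], dict[str, str]]:
    """A ten-sample, three-group soil-style design.

    Returns (spec, sample -> group, sample -> barcode).  Group sizes follow
    the soil study's layout (two larger groups and one small one); the first
    species is spiked in the first group as a group-associated marker taxon.
    """
    lineages = default_lineages(n_species, n_genera)
    species = [lineage_ranks(l)["species"] for l in lineages]
    groups = (["Os"] * 4 + ["Nos"] * 4 + ["MP"] * 2)[:n_samples]
    rng = _rng(seed, "amplicon/design")
    base = mean_copies * np.exp(-0.08 * np.arange(n_species))
    samples: dict[str, dict[str, int]] = {}
    sample_group: dict[str, str] = {}
    barcode_of: dict[str, str] = {}
    used = set()
    for i, group in enumerate(groups):
        sample = f"{group}{i + 1}"
        noise = rng.lognormal(0.0, 0.4, size=n_species)
        expect = base * noise
        if group == "Os":
            expect[0] *= marker_species_boost
        counts = np.maximum(0, np.round(expect)).astype(int)
        counts[counts.argmax()] = max(counts.max(), 1)  # never an empty sample
        samples[sample] = {sp: int(c) for sp, c in zip(species, counts) if c > 0}
        sample_group[sample] = group
        while True:
            bc = "".join(chr(_BASES[j]) for j in rng.integers(0, 4, size=6))
            if bc not in used:
                used.add(bc)
                break
        barcode_of[sample] = bc
    spec = CommunitySpec(lineages=lineages, samples=samples, seed=seed)
    return spec, sample_group, barcode_of


# ---------------------------------------------------------------------------
# config file round-trip

def spec_to_yaml(spec: CommunitySpec, path) -> None:
    doc = {
        "seed": spec.seed,
        "lineages": spec.lineages,
        "regions": {r: {"mean_length": p.mean_length, "sd_length": p.sd_length,
                        "gc_target": p.gc_target,
                        "interspecies_rate": p.interspecies_rate,
                        "intraspecies_rate": p.intraspecies_rate,
                        "rate_cv": p.rate_cv}
                    for r, p in spec.region_params.items()},
        "anchors": {"ssu_tail": spec.anchors.ssu_tail,
                    "r58s_head": spec.anchors.r58s_head,
                    "r58s_tail": spec.anchors.r58s_tail,
                    "lsu_head": spec.anchors.lsu_head,
                    "max_mismatch": spec.anchors.max_mismatch},
        "samples": spec.samples,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def spec_from_yaml(path) -> CommunitySpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    region_params = {r: RegionParams(**p) for r, p in doc["regions"].items()}
    anchors = AnchorSet(**doc.get("anchors", {}))
    return CommunitySpec(lineages=list(doc["lineages"]),
                         region_params=region_params, anchors=anchors,
                         samples={s: dict(p) for s, p in doc["samples"].items()},
                         seed=int(doc.get("seed", 0)))
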