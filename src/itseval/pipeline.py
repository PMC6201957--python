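"""End-to-end orchestration of the two study designs.

``run_insilico_comparison`` emulates the database study: full-length
sequences (simulated or read from FASTA) are decomposed into ITS/ITS1/ITS2,
profiled, clustered across a threshold sweep, and compared via diversity,
commonality and taxonomic resolution.  ``run_amplicon_comparison`` emulates
the multi-sample amplicon study: reads are trimmed, demultiplexed and
extracted, then clustered per sample and pooled, with dendrograms and
group-differential taxa on top.

Every stage writes its artifact into the output directory (TSV, FASTA,
newick, JSON manifest), so any stage can be re-run from files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .cluster import Clustering, greedy_cluster, otu_table, write_otu_tsv
from .commonality import commonality_report, species_per_otu
from .diversity import diversity_result, sample_dendrogram
from .extract import AnchorSet, extract_all, write_extraction_table
from .metrics import gc_content, group_summary, two_sample_t
from .records import SeqRecord, read_fasta, shared_key, write_fasta, write_fastq
from .simulate import (CommunitySpec, build_reference_taxa, demultiplex,
                       read_filter, sample_of_id, simulate_community,
                       simulate_reads, PRIMER_ITS5)
from .taxonomy import (ReferenceDB, assign_all, rank_composition,
                       self_return_rate, species_agreement_rate,
                       differential_taxa)

log = logging.getLogger("itseval")

DEFAULT_THRESHOLDS = tuple(round(0.91 + 0.01 * i, 2) for i in range(9))
REGION_LABELS = ("ITS", "ITS1", "ITS2")


@dataclass
class RunConfig:
    mode: str  # insilico | amplicon
    outdir: Path
    spec: CommunitySpec | None = None
    input_fasta: Path | None = None
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    otu_threshold: float = 0.97
    regions: Sequence[str] = REGION_LABELS
    seed: int = 0
    sample_groups: Mapping[str, str] | None = None
    barcodes: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        ts = list(self.thresholds)
        if ts != sorted(ts) or len(set(ts)) != len(ts):
            raise ValueError("thresholds must be strictly increasing")
        if any(not (0 < t <= 1) for t in ts):
            raise ValueError("thresholds must lie in (0, 1]")
        if self.otu_threshold not in ts:
            raise ValueError("otu_threshold must be one of the thresholds")


def _manifest(config: RunConfig, extra: dict) -> dict:
    return {"itseval_version": __version__, "mode": config.mode,
            "seed": config.seed, "thresholds": list(config.thresholds),
            "otu_threshold": config.otu_threshold,
            "regions": list(config.regions), **extra}


def _write_tsv(rows: list[dict], path: Path) -> None:
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _cluster_sweep(region_records, config: RunConfig
                   ) -> dict[str, dict[float, Clustering]]:
    sweeps: dict[str, dict[float, Clustering]] = {}
    for label in config.regions:
        recs = region_records[label]
        if not recs:
            raise ValueError(f"no sequences survived extraction for {label}")
        sweeps[label] = {}
        for t in config.thresholds:
            c = greedy_cluster(recs, t, label)
            sweeps[label][t] = c
            write_otu_tsv(c, config.outdir / f"otus_{label}_{t:.2f}.tsv")
        log.info("%s: %d sequences, %d OTUs at %.2f", label, len(recs),
                 len(sweeps[label][config.otu_threshold].otus),
                 config.otu_threshold)
    return sweeps


def _metrics_tables(region_records, config: RunConfig) -> None:
    rows = []
    for label in config.regions:
        for rank in ("phylum", "class"):
            for s in group_summary(region_records[label], rank):
                rows.append({"region": label, "rank": rank, **s.__dict__})
    _write_tsv(rows, config.outdir / "group_summaries.tsv")
    # ITS1 vs ITS2 length and GC comparisons (pooled-variance t)
    comps = []
    if "ITS1" in config.regions and "ITS2" in config.regions:
        l1 = [float(len(r.sequence)) for r in region_records["ITS1"]]
        l2 = [float(len(r.sequence)) for r in region_records["ITS2"]]
        g1 = [gc_content(r.sequence) for r in region_records["ITS1"]]
        g2 = [gc_content(r.sequence) for r in region_records["ITS2"]]
        for name, x, y in (("length", l1, l2), ("gc", g1, g2)):
            t, p = two_sample_t(x, y)
            comps.append({"comparison": f"ITS1_vs_ITS2_{name}",
                          "t": t, "p": p,
                          "mean1": sum(x) / len(x), "mean2": sum(y) / len(y)})
    _write_tsv(comps, config.outdir / "two_sample_tests.tsv")


def _diversity_rows(sweeps, sample_of, config: RunConfig) -> list[dict]:
    rows = []
    for label in config.regions:
        clustering = sweeps[label][config.otu_threshold]
        table = otu_table(clustering, sample_of)
        for sample in table.columns:
            counts = table[sample][table[sample] > 0].tolist()
            if not counts:
                continue
            d = diversity_result(sample, counts)
            rows.append({"region": label, "threshold": config.otu_threshold,
                         **d.__dict__})
    return rows


def run_insilico_comparison(config: RunConfig) -> dict:
    """The database-style study on full-length sequences; returns a summary."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    if config.spec is not None:
        refs = build_reference_taxa(config.spec, config.seed)
        community = simulate_community(refs, config.spec, config.seed)
        write_fasta(refs.values(), config.outdir / "references.fasta")
        write_fasta(community, config.outdir / "community.fasta")
        anchors = config.spec.anchors
    elif config.input_fasta is not None:
        community = read_fasta(config.input_fasta)
        refs = None
        anchors = AnchorSet()
    else:
        raise ValueError("insilico mode needs a community spec or a FASTA")
    log.info("community: %d full-length sequences", len(community))

    region_records, table = extract_all(community, anchors)
    write_extraction_table(table, config.outdir / "extraction.tsv")
    n_full = sum(1 for row in table if row["status"] == "full")
    log.info("extraction: %d/%d full", n_full, len(table))

    _metrics_tables(region_records, config)
    sweeps = _cluster_sweep(region_records, config)

    otu_rows = [{"region": lab, "threshold": t, "otus": len(sweeps[lab][t].otus)}
                for lab in config.regions for t in config.thresholds]
    _write_tsv(otu_rows, config.outdir / "otu_counts.tsv")

    sample_of = {r.id: sample_of_id(shared_key(r.id))
                 for lab in config.regions for r in region_records[lab]}
    div_rows = _diversity_rows(sweeps, sample_of, config)
    _write_tsv(div_rows, config.outdir / "diversity.tsv")

    lineage_of = {r.id: r.lineage for lab in config.regions
                  for r in region_records[lab]}
    spo_rows = []
    for label in config.regions:
        for t in config.thresholds:
            mean, _ = species_per_otu(sweeps[label][t], lineage_of)
            spo_rows.append({"region": label, "threshold": t,
                             "mean_species_per_otu": mean})
    _write_tsv(spo_rows, config.outdir / "species_per_otu.tsv")

    comm_rows = commonality_report(sweeps, config.thresholds)
    _write_tsv(comm_rows, config.outdir / "commonality.tsv")

    tax_rows = []
    if refs is not None:
        ref_regions, _ = extract_all(refs.values(), anchors)
        for label in config.regions:
            db = ReferenceDB(ref_regions[label])
            queries = ref_regions[label]
            hits = assign_all(queries, db)
            tax_rows.append({
                "region": label,
                "self_return_rate": self_return_rate(queries, db, hits=hits),
                "species_agreement_rate":
                    species_agreement_rate(queries, db, hits=hits)})
        _write_tsv(tax_rows, config.outdir / "taxonomic_resolution.tsv")

    summary = {
        "n_sequences": len(community),
        "n_full_extraction": n_full,
        "otus": {lab: {f"{t:.2f}": len(sweeps[lab][t].otus)
                       for t in config.thresholds} for lab in config.regions},
        "species_per_otu": {f"{r['region']}@{r['threshold']:.2f}":
                            r["mean_species_per_otu"] for r in spo_rows},
        "commonality": {f"{r['db1']}->{r['db2']}@{r['t1']:.2f}/{r['t2']:.2f}":
                        r["A"] for r in comm_rows},
        "taxonomy": {r["region"]: {"self_return": r["self_return_rate"],
                                   "species_agreement":
                                       r["species_agreement_rate"]}
                     for r in tax_rows},
    }
    (config.outdir / "manifest.json").write_text(
        json.dumps(_manifest(config, {"summary": summary}), indent=2,
                   sort_keys=True) + "\n")
    return summary


def run_amplicon_comparison(config: RunConfig, *,
                            error_rate: float = 0.005,
                            read_length_mean: float | None = 520.0,
                            read_length_sd: float = 60.0) -> dict:
    """The multi-sample amplicon study on simulated 454-style reads."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    if config.spec is None or config.barcodes is None:
        raise ValueError("amplicon mode needs a community spec and barcodes")
    spec = config.spec
    refs = build_reference_taxa(spec, config.seed)
    community = simulate_community(refs, spec, config.seed)
    reads = simulate_reads(community, error_rate=error_rate,
                           barcode=config.barcodes, seed=config.seed,
                           read_length_mean=read_length_mean,
                           read_length_sd=read_length_sd)
    write_fastq(reads, config.outdir / "reads.fastq")
    log.info("reads: %d raw", len(reads))

    kept, rejected = read_filter(reads, barcodes=config.barcodes.values())
    reasons: dict[str, int] = {}
    for _, rs in rejected:
        for r in rs:
            reasons[r] = reasons.get(r, 0) + 1
    log.info("filter: %d kept, %d rejected %s", len(kept), len(rejected),
             reasons)
    _write_tsv([{"read": r.id, "reasons": ",".join(rs)} for r, rs in rejected],
               config.outdir / "rejected_reads.tsv")

    by_sample = demultiplex(kept, config.barcodes)
    dropped = [s for s, recs in by_sample.items() if not recs]
    for s in dropped:
        log.warning("sample %s has zero surviving reads; dropped", s)
    by_sample = {s: recs for s, recs in by_sample.items() if recs}

    pooled = [rec for s in sorted(by_sample) for rec in by_sample[s]]
    region_records, table = extract_all(pooled, spec.anchors)
    write_extraction_table(table, config.outdir / "extraction.tsv")

    sweeps = _cluster_sweep(region_records, config)
    sample_of = {r.id: sample_of_id(shared_key(r.id))
                 for lab in config.regions for r in region_records[lab]}

    div_rows = _diversity_rows(sweeps, sample_of, config)
    _write_tsv(div_rows, config.outdir / "diversity.tsv")

    comm_rows = commonality_report(sweeps, config.thresholds)
    _write_tsv(comm_rows, config.outdir / "commonality.tsv")

    newicks = {}
    for label in config.regions:
        tab = otu_table(sweeps[label][config.otu_threshold], sample_of)
        nwk = sample_dendrogram(tab)
        (config.outdir / f"dendrogram_{label}.nwk").write_text(nwk + "\n")
        newicks[label] = nwk

    # genus-level differential taxa between groups, via best-hit taxonomy
    diff_rows = []
    if config.sample_groups:
        ref_regions, _ = extract_all(refs.values(), spec.anchors)
        label = "ITS2" if "ITS2" in config.regions else config.regions[0]
        db = ReferenceDB(ref_regions[label])
        hits = assign_all(region_records[label], db)
        lineage_by_acc = {r.accession: r.lineage for r in refs.values()}
        counts: dict[tuple[str, str], int] = {}
        for rec, hit in zip(region_records[label], hits):
            from .records import lineage_ranks
            genus = lineage_ranks(lineage_by_acc[hit.hit_accession])["genus"]
            sample = sample_of[rec.id]
            counts[(genus, sample)] = counts.get((genus, sample), 0) + 1
        genera = sorted({g for g, _ in counts})
        samples = sorted(by_sample)
        abundance = pd.DataFrame(
            [[counts.get((g, s), 0) for s in samples] for g in genera],
            index=genera, columns=samples, dtype=float)
        abundance = abundance / abundance.sum(axis=0)
        groups = {s: g for s, g in config.sample_groups.items() if s in samples}
        diff_rows = differential_taxa(abundance, groups)
        _write_tsv(diff_rows, config.outdir / "differential_taxa.tsv")

    summary = {
        "n_reads": len(reads), "n_kept": len(kept),
        "rejection_reasons": reasons,
        "n_samples": len(by_sample),
        "otus": {lab: len(sweeps[lab][config.otu_threshold].otus)
                 for lab in config.regions},
        "commonality": {f"{r['db1']}->{r['db2']}@{r['t1']:.2f}/{r['t2']:.2f}":
                        r["A"] for r in comm_rows
                        if r["t1"] == r["t2"] == config.otu_threshold},
        "dendrograms": newicks,
        "differential_taxa_min_p": min((r["p"] for r in diff_rows),
                                       default=None),
    }
    (config.outdir / "manifest.json").write_text(
        json.dumps(_manifest(config, {"summary": summary}), indent=2,
                   sort_keys=True) + "\n")
    return summary
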