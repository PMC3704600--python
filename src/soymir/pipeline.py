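"""End-to-end orchestration of the analysis stages.

``run_all`` drives simulate -> process -> known -> novel -> de -> targets
with a single :class:`RunConfig`, writes every stage artifact as TSV/FASTA
under the output directory and records a manifest of parameters and row
counts.  Stages read their inputs from files, so deleting a downstream
output and rerunning reproduces it bit-for-bit from the intermediates.
"""

from __future__ import annotations

import json
import logging
import os

import pandas as pd

from soymir import de as de_mod
from soymir import novel as novel_mod
from soymir import reads as reads_mod
from soymir import targets as targets_mod
from soymir import variants as variants_mod
from soymir.config import RunConfig
from soymir.design import library_ids, make_design, stress_control_pairs
from soymir.io import read_bed, read_fasta, read_gff
from soymir.simulate import GeneModel, Simulator

log = logging.getLogger("soymir")


def simulate_stage(cfg: RunConfig) -> dict[str, str]:
    sim = Simulator(cfg.sim_config())
    sim.build_truth()
    refdir = os.path.join(cfg.outdir, "reference")
    libdir = os.path.join(cfg.outdir, "libraries")
    paths = sim.write_reference(refdir)
    fq = sim.simulate_libraries(libdir)
    log.info("simulate: %d libraries, %d planted precursors", len(fq), len(sim.truth.precursors))
    paths.update(fq)
    return paths


def _input_paths(cfg: RunConfig) -> dict[str, str]:
    ref = os.path.join(cfg.outdir, "reference")
    libdir = cfg.libraries_dir or os.path.join(cfg.outdir, "libraries")
    out = {
        "genome": cfg.genome or os.path.join(ref, "genome.fa"),
        "known_precursors": cfg.known_precursors or os.path.join(ref, "known_precursors.fa"),
        "known_precursor_gff": cfg.known_precursor_gff or os.path.join(ref, "known_precursors.gff3"),
        "annotated_matures": cfg.annotated_matures or os.path.join(ref, "annotated_matures.fa"),
        "ncrna_bed": cfg.ncrna_bed or os.path.join(ref, "ncrna.bed"),
        "genes_gff": cfg.genes_gff or os.path.join(ref, "genes.gff3"),
        "transcripts": cfg.transcripts or os.path.join(ref, "transcripts.fa"),
        "libraries_dir": libdir,
    }
    missing = [k for k, v in out.items() if not os.path.exists(v)]
    if missing:
        raise FileNotFoundError(f"missing inputs: {missing}")
    return out


def process_stage(cfg: RunConfig) -> tuple[pd.DataFrame, dict, pd.DataFrame]:
    paths = _input_paths(cfg)
    genome = read_fasta(paths["genome"])
    fq = {
        lib: os.path.join(paths["libraries_dir"], f"{lib}.fastq")
        for lib in library_ids()
        if os.path.exists(os.path.join(paths["libraries_dir"], f"{lib}.fastq"))
    }
    tags, hits, stats = reads_mod.process_libraries(
        fq, genome, cfg.adapter3, cfg.min_len, cfg.max_len, cfg.min_qual
    )
    procdir = os.path.join(cfg.outdir, "process")
    os.makedirs(procdir, exist_ok=True)
    stats.to_csv(os.path.join(procdir, "library_stats.tsv"), sep="\t")
    tags.to_csv(os.path.join(procdir, "tags.tsv"), sep="\t")
    reads_mod.write_tag_fasta(os.path.join(procdir, "tags.fa"), tags.head(100_000))
    for weighting in ("total", "unique"):
        reads_mod.length_distribution(tags, weighting).to_csv(
            os.path.join(procdir, f"length_distribution_{weighting}.tsv"), sep="\t"
        )
    log.info("process: %d unique tags across %d libraries", len(tags), len(fq))
    return tags, hits, stats


def known_stage(cfg: RunConfig, tags: pd.DataFrame) -> pd.DataFrame:
    paths = _input_paths(cfg)
    precursors = read_fasta(paths["known_precursors"])
    annotated = read_fasta(paths["annotated_matures"])
    libs = [l for l in library_ids() if l in tags.columns]
    genotype_of = {d.library_id: d.genotype for d in make_design()}
    variants = variants_mod.run_known_analysis(
        tags, precursors, libs, annotated, genotype_of,
        cfg.majority_frac, cfg.closeness_ratio, cfg.window, cfg.min_secondary,
    )
    table = variants_mod.variants_table(variants, libs)
    outdir = os.path.join(cfg.outdir, "known")
    os.makedirs(outdir, exist_ok=True)
    table.to_csv(os.path.join(outdir, "unified_variants.tsv"), sep="\t", index=False)
    log.info("known: %d variant rows over %d precursors", len(table), table["precursor_id"].nunique() if len(table) else 0)
    return table


def novel_stage(cfg: RunConfig, tags: pd.DataFrame, hits: dict) -> pd.DataFrame:
    paths = _input_paths(cfg)
    genome = read_fasta(paths["genome"])
    pre_gff = read_gff(paths["known_precursor_gff"])
    known_loci = [
        (r.seqid, int(r.start), int(r.end), r.strand) for r in pre_gff.itertuples()
    ]
    ncrna_df = read_bed(paths["ncrna_bed"])
    ncrna = [
        (r.chrom, int(r.start) + 1, int(r.end), r.strand) for r in ncrna_df.itertuples()
    ]
    genes_gff = read_gff(paths["genes_gff"])
    exons = [
        (r.seqid, int(r.start), int(r.end), r.strand)
        for r in genes_gff.itertuples()
        if r.type == "exon"
    ]
    genes = _gene_models(genes_gff)
    libs = [l for l in library_ids() if l in tags.columns]
    novel, candidates, hosts = novel_mod.run_novel_analysis(
        tags, hits, genome, known_loci, ncrna, exons, libs, genes,
        cfg.flank, cfg.merge_dist, cfg.mfe_cutoff, cfg.min_total,
        cfg.min_candidate_count,
    )
    table = novel_mod.novel_table(novel, libs)
    outdir = os.path.join(cfg.outdir, "novel")
    os.makedirs(outdir, exist_ok=True)
    table.to_csv(os.path.join(outdir, "novel_mirnas.tsv"), sep="\t", index=False)
    if len(hosts):
        hosts.to_csv(os.path.join(outdir, "host_genes.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "hairpins.fa"), "w") as fh:
        for m in novel:
            fh.write(f">{m.name}\n{m.candidate.sequence}\n{m.candidate.structure}\n")
    log.info("novel: %d called from %d candidates", len(novel), len(candidates))
    return table


def _gene_models(gff: pd.DataFrame) -> list[GeneModel]:
    genes = []
    for r in gff[gff["type"] == "gene"].itertuples():
        gid = str(r.attributes).split("ID=")[1].split(";")[0]
        exons = [
            (int(x.start), int(x.end))
            for x in gff[(gff["type"] == "exon")].itertuples()
            if f"Parent={gid}" in str(x.attributes)
        ]
        genes.append(GeneModel(gid, r.seqid, int(r.start), int(r.end), r.strand, sorted(exons)))
    return genes


def de_stage(
    cfg: RunConfig,
    known_table: pd.DataFrame,
    novel_table: pd.DataFrame,
    stats: pd.DataFrame,
) -> pd.DataFrame:
    libs = [l for l in library_ids() if l in stats.index]
    counts = _count_matrix(known_table, novel_table, libs)
    sizes = stats["mapped_reads"]
    de = de_mod.run_de(
        counts, sizes, stress_control_pairs(), cfg.alpha, cfg.lfc, cfg.min_reads, cfg.tail
    )
    outdir = os.path.join(cfg.outdir, "de")
    os.makedirs(outdir, exist_ok=True)
    de.to_csv(os.path.join(outdir, "differential_expression.tsv"), sep="\t", index=False)
    de_mod.de_summary(de).to_csv(os.path.join(outdir, "summary.tsv"), sep="\t")
    log.info("de: %d tests, %d significant", len(de), int(de["status"].isin(["up", "down"]).sum()))
    return de


def _count_matrix(known_table, novel_table, libs) -> pd.DataFrame:
    frames = []
    if len(known_table):
        sub = known_table[known_table["role"] == "miRNA"]
        frames.append(sub.set_index("name")[libs])
    if novel_table is not None and len(novel_table):
        frames.append(novel_table.set_index("name")[libs])
    if not frames:
        return pd.DataFrame(columns=libs)
    return pd.concat(frames)


def targets_stage(
    cfg: RunConfig, de: pd.DataFrame, known_table: pd.DataFrame, novel_table: pd.DataFrame
) -> pd.DataFrame:
    paths = _input_paths(cfg)
    transcripts = read_fasta(paths["transcripts"])
    seq_of = {}
    for tbl in (known_table, novel_table):
        if tbl is not None and len(tbl):
            for r in tbl.itertuples():
                if getattr(r, "sequence", None):
                    seq_of[r.name] = r.sequence
    de_ids = sorted(set(de.loc[de["status"].isin(["up", "down"]), "mirna_id"]))
    mirnas = {mid: seq_of[mid] for mid in de_ids if mid in seq_of}
    table = targets_mod.predict_all(mirnas, transcripts, cfg.max_score)
    outdir = os.path.join(cfg.outdir, "targets")
    os.makedirs(outdir, exist_ok=True)
    table.to_csv(os.path.join(outdir, "target_sites.tsv"), sep="\t", index=False)
    log.info("targets: %d sites for %d miRNAs", len(table), len(mirnas))
    return table


def run_all(cfg: RunConfig) -> dict:
    """Run every stage; returns a manifest of parameters and row counts."""
    os.makedirs(cfg.outdir, exist_ok=True)
    simulate_stage(cfg)
    tags, hits, stats = process_stage(cfg)
    known_table = known_stage(cfg, tags)
    nov_table = novel_stage(cfg, tags, hits)
    de = de_stage(cfg, known_table, nov_table, stats)
    targets = targets_stage(cfg, de, known_table, nov_table)
    manifest = {
        "seed": cfg.seed,
        "parameters": {
            k: getattr(cfg, k)
            for k in (
                "adapter3", "min_len", "max_len", "min_qual", "majority_frac",
                "closeness_ratio", "window", "mfe_cutoff", "min_total",
                "alpha", "lfc", "min_reads", "max_score",
            )
        },
        "rows": {
            "unique_tags": int(len(tags)),
            "known_variants": int(len(known_table)),
            "novel_mirnas": int(len(nov_table)),
            "de_tests": int(len(de)),
            "target_sites": int(len(targets)),
        },
    }
    with open(os.path.join(cfg.outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
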