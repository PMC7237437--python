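"""Stage orchestration: the candidate scan (map -> screen -> cluster -> size
filter -> sharpness -> target evaluation -> annotation -> outputs) and the
conservation analysis (windows -> labels -> Kruskal-Wallis -> Dunn), each
writing a manifest of configuration and per-stage counts."""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict

import pandas as pd

from . import __version__
from .annotate import assemble_candidates, write_outputs
from .config import PipelineConfig
from .diversity import (
    SequenceAlignment,
    assign_regions,
    dunn_test,
    kruskal_wallis,
    mann_whitney,
    sliding_window_diversity,
)
from .genome import CircularGenome, AnnotationSet, read_fasta_genome, read_gff3
from .pipeline import (
    SmallRead,
    cluster_reads,
    end_profile,
    map_reads_mito,
    read_fastq,
    sharpness_filter,
    size_filter,
    screen_nuclear,
    write_bedgraph,
    write_clusters_tsv,
)
from .targets import UTRRecord, evaluate_targets, read_utr_fasta, write_hits_tsv

log = logging.getLogger("smithrna")

__all__ = ["run_scan", "run_diversity", "run_assay_stats"]


def _manifest(prefix: str, stage_counts: dict, config: PipelineConfig) -> str:
    path = f"{prefix}.manifest.json"
    with open(path, "w") as fh:
        json.dump(
            {"version": __version__, "config": asdict(config),
             "stages": stage_counts},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    return path


def run_scan(
    config: PipelineConfig,
    genome: CircularGenome | None = None,
    annotation: AnnotationSet | None = None,
    reads: list[SmallRead] | None = None,
    utrome: list[UTRRecord] | None = None,
    nuclear: list[tuple[str, str]] | None = None,
    write: bool = True,
):
    """Full candidate scan; inputs may be passed in memory or read from the
    paths in ``config``.  Returns (candidates, stage_counts)."""
    if genome is None:
        if not config.genome_fasta:
            raise FileNotFoundError("no genome FASTA configured (genome_fasta)")
        genome = read_fasta_genome(config.genome_fasta)
    if annotation is None:
        if not config.annotation_gff3:
            raise FileNotFoundError("no annotation GFF3 configured (annotation_gff3)")
        annotation = read_gff3(config.annotation_gff3, genome.id)
    if not annotation.has_urs:
        from .genome import reannotate_urs

        annotation = reannotate_urs(annotation, genome)
    if reads is None:
        if not config.reads_fastq:
            raise FileNotFoundError("no reads FASTQ configured (reads_fastq)")
        reads = read_fastq(config.reads_fastq)
    if utrome is None:
        if not config.utr_fasta:
            raise FileNotFoundError("no UTR FASTA configured (utr_fasta)")
        utrome = read_utr_fasta(config.utr_fasta)
    if nuclear is None and config.nuclear_fasta:
        from Bio import SeqIO

        nuclear = [(r.id, str(r.seq)) for r in SeqIO.parse(config.nuclear_fasta, "fasta")]

    counts = {"reads": len(reads)}
    log.info("mapping %d reads (seed=%d)", len(reads), config.seed)
    alignments = map_reads_mito(reads, genome, config.max_mismatch)
    counts["mito_mapped_reads"] = len({a.read_id for a in alignments})

    if nuclear:
        retained = screen_nuclear(alignments, reads, nuclear, config.max_mismatch)
        alignments = [a for a in alignments if a.read_id in retained]
    counts["screened_reads"] = len({a.read_id for a in alignments})

    clusters = cluster_reads(alignments, reads, config.identity)
    counts["clusters"] = len(clusters)

    big = size_filter(clusters, config.min_cluster_size)
    counts["clusters_size_pass"] = len(big)

    survivors = []
    reports = []
    for cl in big:
        rep = sharpness_filter(cl, None, config.min_frac5, config.min_frac3)
        reports.append(rep)
        if rep.passed:
            survivors.append((cl, rep))
    counts["clusters_sharp_pass"] = len(survivors)

    thresholds = config.to_thresholds()
    hits_by_centroid = {}
    for cl, _rep in survivors:
        hits = evaluate_targets(cl.centroid, utrome, thresholds)
        if hits:
            hits_by_centroid[cl.centroid] = hits
    counts["centroids_with_targets"] = len(hits_by_centroid)

    candidates = assemble_candidates(
        survivors, hits_by_centroid, annotation, genome,
        config.species, config.sex, config.pre_length,
    )
    counts["candidates"] = len(candidates)

    if write:
        prefix = config.out_prefix
        profile = end_profile(alignments, genome)
        write_bedgraph(profile, genome.id, prefix)
        all_reports = [sharpness_filter(c, None, config.min_frac5, config.min_frac3)
                       for c in clusters]
        write_clusters_tsv(clusters, all_reports, f"{prefix}.clusters.tsv")
        write_hits_tsv(hits_by_centroid, f"{prefix}.hits.tsv")
        write_outputs(candidates, genome.id, prefix)
        _manifest(prefix, counts, config)
    return candidates, counts


def run_diversity(
    config: PipelineConfig,
    alignment: SequenceAlignment | None = None,
    regions: list[tuple[int, int, str]] | None = None,
    write: bool = True,
):
    """Windowed diversity + region labels + KW and Dunn tests.

    Returns (windows, kw_result, dunn_table).  Refuses to test when fewer
    than two region labels are present.
    """
    if alignment is None:
        if not config.alignment_fasta:
            raise FileNotFoundError("no alignment FASTA configured (alignment_fasta)")
        alignment = SequenceAlignment.from_fasta(config.alignment_fasta)
    if regions is None:
        if not config.regions_tsv:
            raise FileNotFoundError("no region table configured (regions_tsv)")
        tab = pd.read_csv(config.regions_tsv, sep="\t",
                          names=["start", "end", "region"], comment="#")
        regions = [(int(r.start), int(r.end), str(r.region)) for r in tab.itertuples()]

    windows = sliding_window_diversity(
        alignment, config.window_size, config.window_step, config.ordered_pairs
    )
    windows = assign_regions(windows, regions)
    labels = sorted({w.region for w in windows})
    if len(labels) < 2:
        raise ValueError(
            f"only one region label present ({labels}); need >= 2 groups for testing"
        )
    groups = [[w.pi_hat for w in windows if w.region == lab] for lab in labels]
    kw = kruskal_wallis(groups)
    dunn = dunn_test(groups, labels)

    if write:
        prefix = config.out_prefix
        pd.DataFrame(
            [{"start": w.start, "end": w.end, "pi_hat": w.pi_hat, "region": w.region}
             for w in windows]
        ).to_csv(f"{prefix}.windows.tsv", sep="\t", index=False)
        with open(f"{prefix}.tests.tsv", "w") as fh:
            fh.write("test\tstatistic\tdf\tp\n")
            fh.write(f"kruskal-wallis\t{kw.statistic:.4f}\t{kw.df}\t{kw.pvalue:.6g}\n")
        dunn.to_csv(f"{prefix}.dunn.tsv", sep="\t", index=False)
        _manifest(prefix, {"windows": len(windows), "groups": len(labels)}, config)
    return windows, kw, dunn


def run_assay_stats(
    config: PipelineConfig,
    table: pd.DataFrame | None = None,
    group_col: str = "group",
    value_col: str = "measurement",
    mw_pair: tuple[str, str] | None = None,
    alternative: str = "less",
    write: bool = True,
):
    """Nonparametric tests on an assay table: KW + Dunn across all groups and
    an optional one-tailed Mann-Whitney between two named groups."""
    if table is None:
        if not config.assay_tsv:
            raise FileNotFoundError("no assay table configured (assay_tsv)")
        table = pd.read_csv(config.assay_tsv, sep="\t")
    labels = sorted(table[group_col].unique())
    groups = [table.loc[table[group_col] == lab, value_col].to_numpy()
              for lab in labels]
    kw = kruskal_wallis(groups) if len(groups) >= 2 else None
    dunn = dunn_test(groups, labels) if len(groups) >= 2 else None
    mw = None
    if mw_pair:
        a, b = mw_pair
        mw = mann_whitney(
            table.loc[table[group_col] == a, value_col].to_numpy(),
            table.loc[table[group_col] == b, value_col].to_numpy(),
            alternative=alternative,
        )
    if write:
        prefix = config.out_prefix
        with open(f"{prefix}.assay_tests.tsv", "w") as fh:
            fh.write("test\tstatistic\tdf\tp\n")
            if kw:
                fh.write(f"kruskal-wallis\t{kw.statistic:.4f}\t{kw.df}\t{kw.pvalue:.6g}\n")
            if mw:
                fh.write(f"mann-whitney\t{mw.statistic:.1f}\t.\t{mw.pvalue:.6g}\n")
        if dunn is not None:
            dunn.to_csv(f"{prefix}.assay_dunn.tsv", sep="\t", index=False)
    return kw, dunn, mw
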