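"""End-to-end orchestration: simulate/load -> demux -> align -> exon
catalog -> architecture clustering -> quantification -> junctions ->
proteome, with stage outputs and a machine-readable summary."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .align import AlignParams, LocusIndex, ReadAlignment, Rejection, \
    align_read, refine_splice_boundaries
from .cluster import AnnotatedRead, AnnotationParams, annotate_exons, \
    cluster_and_name, qc_select_variants
from .exons import collect_boundaries, exon_sequences, validate_splice_sites
from .io import DemuxResult, GeneLocus, ReadRecord, SampleSheet, demultiplex, \
    write_counts_tsv, write_exons_bed, write_fasta, write_transcripts_bed12
from .junctions import build_junction_reference, count_short_read_support, \
    enumerate_junctions, junction_table, min_unique_overhangs
from .proteome import digest_and_map, drop_duplicates_and_ptc, filter_by_tis, \
    map_junction_spanning, molecular_weights, orfs_for_transcripts
from .quantify import build_matrix, exon_usage, major_isoforms


@dataclass
class PipelineResult:
    summary: dict
    demux: DemuxResult
    alignments: list[ReadAlignment]
    rejections: list[Rejection]
    catalog: object
    exclusion_log: pd.DataFrame
    annotated: list[AnnotatedRead]
    clusters: list
    cluster_log: pd.DataFrame
    matrix: object
    junctions: list
    junction_counts: dict | None
    isoforms: list
    peptide_table: pd.DataFrame | None


def run_pipeline(locus: GeneLocus, reads: list[ReadRecord],
                 sheet: SampleSheet,
                 mode: str = "pacbio",
                 short_reads: list[ReadRecord] | None = None,
                 validated_tis: set[int] | None = None,
                 align_params: AlignParams | None = None,
                 annot_params: AnnotationParams | None = None,
                 demux_max_mismatch: int = 2,
                 boundary_tol: int = 3,
                 exon_min_support: int = 2,
                 junction_overhangs: tuple[int, int] = (9, 6),
                 junction_min_overlap: int = 15,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage on in-memory inputs; optionally write stage outputs
    under ``out_dir`` (one subdirectory per stage plus summary.json)."""
    ap = align_params or AlignParams()
    an = annot_params or AnnotationParams()
    summary: dict = {"version": __version__, "mode": mode,
                     "reads_in": len(reads)}

    # demultiplex
    demux = demultiplex(reads, sheet, max_mismatch=demux_max_mismatch)
    summary["reads_assigned"] = len(demux.assigned)
    summary["reads_ambiguous"] = len(demux.ambiguous)
    summary["reads_unassigned"] = len(demux.unassigned)

    # spliced alignment
    index = LocusIndex(locus, ap.k)
    alignments: list[ReadAlignment] = []
    rejections: list[Rejection] = []
    for read in demux.assigned:
        res = align_read(read, index, ap)
        if isinstance(res, Rejection):
            rejections.append(res)
        else:
            alignments.append(refine_splice_boundaries(res, locus))
    summary["reads_aligned"] = len(alignments)
    summary["reads_rejected"] = len(rejections)

    # exon catalog
    candidates = collect_boundaries(alignments, tol=boundary_tol,
                                    min_support=exon_min_support)
    catalog, exclusion_log = validate_splice_sites(candidates, locus)
    summary["exon_candidates"] = len(candidates)
    summary["exons_retained"] = len(catalog)
    exon_seqs = exon_sequences(catalog, locus)

    # per-read annotation + QC
    sample_of = {r.read_id: r.sample_id for r in demux.assigned}
    aligned_seq = {a.read_id: a.sequence for a in alignments}
    annotated: list[AnnotatedRead] = []
    n_no_arch = n_non_colinear = n_qc_fail = 0
    for aln in alignments:
        seq = aligned_seq[aln.read_id]
        barcode, hits, reason = annotate_exons(seq, exon_seqs, catalog, an)
        if barcode is None:
            if reason == "no_architecture":
                n_no_arch += 1
            else:
                n_non_colinear += 1
            continue
        barcode, keep, ident = qc_select_variants(seq, barcode, catalog,
                                                  exon_seqs, an)
        if not keep:
            n_qc_fail += 1
            continue
        annotated.append(AnnotatedRead(aln.read_id, sample_of[aln.read_id],
                                       barcode, hits, ident, True))
    summary["reads_no_architecture"] = n_no_arch
    summary["reads_non_colinear"] = n_non_colinear
    summary["reads_qc_failed"] = n_qc_fail
    summary["reads_annotated"] = len(annotated)

    # clustering
    clusters, cluster_log = cluster_and_name(annotated, exon_seqs, catalog,
                                             an, mode=mode)
    summary["transcripts"] = len(clusters)
    summary["reads_excluded_at_clustering"] = len(cluster_log)

    # quantification
    matrix = build_matrix(clusters, sheet) if clusters else None
    if matrix is not None:
        summary["major_isoforms"] = major_isoforms(matrix)

    # junctions
    junctions = enumerate_junctions(clusters, catalog.genomic_order) \
        if clusters else []
    junction_counts = None
    if junctions:
        per_side, (ga, gb) = min_unique_overhangs(junctions, exon_seqs)
        o5 = max(junction_overhangs[0], ga)
        o3 = max(junction_overhangs[1], gb)
        records = build_junction_reference(junctions, exon_seqs, o5, o3)
        summary["junctions"] = len(junctions)
        summary["junction_overhangs_used"] = [o5, o3]
        if short_reads:
            junction_counts = count_short_read_support(
                short_reads, records, junction_point=o5,
                min_overlap=junction_min_overlap, per_side_min=per_side)
            for j in junctions:
                j.short_read_count = junction_counts[j.junction_id]

    # proteome
    isoforms = []
    peptide_table = None
    if clusters:
        orfs = orfs_for_transcripts(clusters, catalog)
        summary["orfs_found"] = len(orfs)
        summary["tis_observed"] = len({o.genomic_tis for o in orfs})
        if validated_tis is not None:
            orfs_kept, tis_report = filter_by_tis(orfs, validated_tis)
            summary["tis_validated"] = int(tis_report["validated"].sum())
            summary["orfs_tis_filtered"] = len(orfs_kept)
        else:
            orfs_kept = orfs
            summary["orfs_tis_filtered"] = len(orfs)
        isoforms, removal_log, n_dedup = drop_duplicates_and_ptc(orfs_kept,
                                                                 catalog)
        summary["orfs_deduplicated"] = n_dedup
        summary["protein_isoforms"] = len(isoforms)
        if isoforms:
            molecular_weights(isoforms)
            peptide_table = digest_and_map(isoforms)
            peptide_table = map_junction_spanning(peptide_table, isoforms,
                                                  clusters, catalog)
            summary["peptides"] = int(peptide_table["peptide"].nunique())
            summary["isoform_unique_peptides"] = int(
                peptide_table.loc[peptide_table["uniqueness"]
                                  == "isoform_unique", "peptide"].nunique())

    result = PipelineResult(summary, demux, alignments, rejections, catalog,
                            exclusion_log, annotated, clusters, cluster_log,
                            matrix, junctions, junction_counts, isoforms,
                            peptide_table)
    if out_dir is not None:
        _write_outputs(result, locus, exon_seqs, Path(out_dir))
    return result


def _write_outputs(res: PipelineResult, locus: GeneLocus,
                   exon_seqs: dict, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    (out / "demux").mkdir(exist_ok=True)
    res.demux.report.to_csv(out / "demux" / "report.tsv", sep="\t",
                            index=False)
    (out / "align").mkdir(exist_ok=True)
    pd.DataFrame([{"read_id": r.read_id, "reason": r.reason}
                  for r in res.rejections]).to_csv(
        out / "align" / "rejections.tsv", sep="\t", index=False)
    (out / "exons").mkdir(exist_ok=True)
    write_exons_bed(res.catalog, locus, out / "exons" / "exons.bed")
    res.exclusion_log.to_csv(out / "exons" / "excluded.tsv", sep="\t",
                             index=False)
    (out / "transcripts").mkdir(exist_ok=True)
    if res.clusters:
        write_transcripts_bed12(res.clusters, locus, res.catalog,
                                out / "transcripts" / "transcripts.bed12")
        pd.DataFrame([{"name": c.name,
                       "barcode": c.barcode.canonical_string,
                       "total": c.total_count, **c.per_sample_counts}
                      for c in res.clusters]).to_csv(
            out / "transcripts" / "clusters.tsv", sep="\t", index=False)
    (out / "quantify").mkdir(exist_ok=True)
    if res.matrix is not None:
        write_counts_tsv(res.matrix, out / "quantify" / "counts.tsv")
        res.matrix.percentages.to_csv(out / "quantify" / "percentages.tsv",
                                      sep="\t", index_label="transcript")
        usage = exon_usage(res.matrix, res.clusters, list(exon_seqs))
        usage.to_csv(out / "quantify" / "exon_usage.tsv", sep="\t",
                     index_label="exon")
    (out / "junctions").mkdir(exist_ok=True)
    if res.junctions:
        junction_table(res.junctions).to_csv(
            out / "junctions" / "junctions.tsv", sep="\t", index=False)
    (out / "proteome").mkdir(exist_ok=True)
    if res.isoforms:
        write_fasta([(i.isoform_id, i.protein) for i in res.isoforms],
                    out / "proteome" / "isoforms.faa")
        if res.peptide_table is not None:
            res.peptide_table.to_csv(out / "proteome" / "peptides.tsv",
                                     sep="\t", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(res.summary, fh, indent=1, sort_keys=True)
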