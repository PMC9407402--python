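"""End-to-end orchestration: from input files (or a simulated study) to
the final QTL-resident candidate gene report.

Stages: PAV matrix from coverage → SNP filtering and consequence
annotation → SNPs specific to the highly heat-tolerant accessions → DEG
consensus across datasets → intersection → QTL marker placement and gene
membership → final candidates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import deg as deg_mod
from . import group_snps as gs_mod
from . import io_formats as iof
from . import pav as pav_mod
from . import qtl as qtl_mod
from . import variants as var_mod


@dataclass
class PipelineResult:
    matrix: pav_mod.PresenceMatrix
    excluded_accessions: list[tuple[str, str]]
    core: set[str]
    variable: set[str]
    kept_variants: list
    removal_log: list
    records: list
    summary: dict
    group_result: gs_mod.GroupSnpResult
    consensus: deg_mod.ConsensusResult
    candidates: deg_mod.CandidateSets
    intervals: list
    qtl_membership: dict
    report: qtl_mod.CandidateReport


def run_pipeline(
    data_dir: str | Path,
    target_classes: set[str] = frozenset({"HT"}),
    scope: str = "genic_and_flank",
    pav_params: pav_mod.PavParams | None = None,
    filter_params: var_mod.FilterParams | None = None,
    annot_params: var_mod.AnnotParams | None = None,
    deg_params: deg_mod.DegParams | None = None,
    merge_qtls: bool = True,
) -> PipelineResult:
    """Run every stage on the files of a study directory.

    Expects the layout the synthetic generator writes: ``genome.fa``,
    ``genes.gff3``, ``variants.vcf``, ``metadata.tsv``, ``deg.tsv``,
    ``markers.tsv``, and ``coverage/<accession>.tsv``.
    """
    d = Path(data_dir)
    genome = iof.read_fasta(d / "genome.fa")
    models = iof.read_gff3(d / "genes.gff3")
    meta = iof.read_metadata(d / "metadata.tsv")
    variants, samples = iof.read_vcf(d / "variants.vcf")
    deg_table = iof.read_deg_table(d / "deg.tsv")
    marker_table = iof.read_marker_table(d / "markers.tsv")
    coverage = {
        m.accession: iof.read_coverage(d / "coverage" / f"{m.accession}.tsv")
        for m in meta
        if (d / "coverage" / f"{m.accession}.tsv").exists()
    }

    # 1. presence/absence
    matrix, excluded = pav_mod.build_matrix(models, coverage, meta, pav_params)
    core, variable, _private = pav_mod.classify_genes(matrix)

    # 2. SNP filtering and annotation
    kept, removal_log = var_mod.filter_variants(variants, filter_params)
    records, summary = var_mod.annotate(kept, models, genome, annot_params)

    # 3. SNPs specific to the target heat classes
    nonref_contigs = {c.name for c in genome if not c.is_reference}
    group_result = gs_mod.select_group_specific(
        kept,
        samples,
        meta,
        records,
        gs_mod.GroupSpec(set(target_classes), scope),
        nonref_contigs=nonref_contigs,
    )

    # 4. DEG consensus and intersection
    calls = deg_mod.call_degs(deg_table, deg_params)
    cons = deg_mod.consensus(calls)
    candidates = deg_mod.intersect_with_snp_genes(cons, group_result)

    # 5. QTL intervals and the final report
    markers = qtl_mod.markers_from_frame(marker_table)
    placed, log = qtl_mod.place_markers(markers, genome)
    if log.unplaced or log.ambiguous:
        warnings.warn(
            f"markers unplaced: {log.unplaced}; ambiguous: {log.ambiguous}"
        )
    intervals = qtl_mod.build_intervals(placed, merge=merge_qtls)
    _per_interval, per_gene = qtl_mod.genes_in_qtls(models, intervals)
    report = qtl_mod.final_candidates(candidates, per_gene)

    return PipelineResult(
        matrix=matrix,
        excluded_accessions=excluded,
        core=core,
        variable=variable,
        kept_variants=kept,
        removal_log=removal_log,
        records=records,
        summary=summary,
        group_result=group_result,
        consensus=cons,
        candidates=candidates,
        intervals=intervals,
        qtl_membership=per_gene,
        report=report,
    )
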