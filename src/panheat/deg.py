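"""Differential-expression thresholding and cross-dataset consensus.

Per comparison, a gene is up-regulated when padj <= 0.05 and log2FC >= 1,
down-regulated when padj <= 0.05 and log2FC <= -1 (both thresholds
inclusive; a missing padj is never significant).  The consensus across
comparisons keeps a gene as up (down) when it is up (down) in at least one
comparison and down (up) in none; genes called in both directions anywhere
are excluded as contradictory.  The consensus sets are then intersected
with the genes bearing group-specific SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .group_snps import GroupSnpResult


@dataclass
class DegParams:
    padj_max: float = 0.05
    lfc_min: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.padj_max <= 1):
            raise ValueError("padj_max must be in (0, 1]")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")


@dataclass
class ComparisonCalls:
    dataset: str
    comparison: str
    up: set[str]
    down: set[str]


@dataclass
class ConsensusResult:
    up_genes: set[str]
    down_genes: set[str]
    excluded_contradictory: set[str]
    membership: dict[tuple[str, str], dict[str, set[str]]] = field(
        default_factory=dict
    )  # (dataset, comparison) -> {"up": ..., "down": ...}


def call_degs(
    records: pd.DataFrame, params: DegParams | None = None
) -> list[ComparisonCalls]:
    """Threshold DEG records (dataset, comparison, gene, log2fc, padj)."""
    params = params or DegParams()
    dup = records.duplicated(subset=["dataset", "comparison", "gene"])
    if dup.any():
        bad = records.loc[dup, ["dataset", "comparison", "gene"]].iloc[0]
        raise ValueError(
            f"duplicate DEG row for gene {bad.gene} in "
            f"{bad.dataset}/{bad.comparison}"
        )
    calls = []
    for (ds, comp), sub in records.groupby(["dataset", "comparison"], sort=True):
        sig = sub["padj"].notna() & (sub["padj"] <= params.padj_max)
        up = set(sub.loc[sig & (sub["log2fc"] >= params.lfc_min), "gene"])
        down = set(sub.loc[sig & (sub["log2fc"] <= -params.lfc_min), "gene"])
        calls.append(ComparisonCalls(str(ds), str(comp), up, down))
    return calls


def consensus(calls: list[ComparisonCalls]) -> ConsensusResult:
    """Cross-comparison consensus excluding contradictory genes.

    A gene untested in a comparison is neutral there.  Contradiction is
    any up call against any down call, across or within datasets.
    """
    if not calls:
        raise ValueError("need >= 1 comparison")
    any_up = set().union(*(c.up for c in calls))
    any_down = set().union(*(c.down for c in calls))
    contradictory = any_up & any_down
    return ConsensusResult(
        up_genes=any_up - contradictory,
        down_genes=any_down - contradictory,
        excluded_contradictory=contradictory,
        membership={
            (c.dataset, c.comparison): {"up": set(c.up), "down": set(c.down)}
            for c in calls
        },
    )


@dataclass
class CandidateSets:
    up: set[str]
    down: set[str]
    up_nonref: set[str]
    down_nonref: set[str]
    evidence: pd.DataFrame


def intersect_with_snp_genes(
    cons: ConsensusResult,
    snps: GroupSnpResult,
    nonref_genes: set[str] | None = None,
) -> CandidateSets:
    """Restrict consensus DEGs to genes bearing group-specific SNPs.

    ``nonref_genes`` flags genes on non-reference contigs (defaults to the
    flag carried by the SNP result).  Raises when the two gene-id
    namespaces share nothing at all.
    """
    snp_genes = snps.gene_ids
    universe = cons.up_genes | cons.down_genes | cons.excluded_contradictory
    if universe and snp_genes and not (universe & snp_genes):
        raise ValueError(
            "no overlap between DEG and SNP gene ids: namespace mismatch?"
        )
    nonref = snps.nonref_genes if nonref_genes is None else nonref_genes
    up = cons.up_genes & snp_genes
    down = cons.down_genes & snp_genes
    rows = []
    for gene in sorted(up | down):
        datasets = sorted(
            {
                ds
                for (ds, _comp), m in cons.membership.items()
                if gene in m["up"] or gene in m["down"]
            }
        )
        cats = sorted({r.category for r in snps.genes.get(gene, [])})
        rows.append(
            {
                "gene": gene,
                "direction": "up" if gene in up else "down",
                "non_reference": gene in nonref,
                "snp_categories": ",".join(cats),
                "supporting_datasets": ",".join(datasets),
            }
        )
    evidence = pd.DataFrame(
        rows,
        columns=[
            "gene",
            "direction",
            "non_reference",
            "snp_categories",
            "supporting_datasets",
        ],
    )
    return CandidateSets(
        up=up,
        down=down,
        up_nonref=up & nonref,
        down_nonref=down & nonref,
        evidence=evidence,
    )


def venn_counts(cons: ConsensusResult, snp_genes: set[str]) -> pd.DataFrame:
    """Per-comparison overlap sizes with the SNP-bearing gene set."""
    rows = []
    for (ds, comp), m in sorted(cons.membership.items()):
        rows.append(
            {
                "dataset": ds,
                "comparison": comp,
                "n_up": len(m["up"]),
                "n_down": len(m["down"]),
                "n_up_with_snp": len(m["up"] & snp_genes),
                "n_down_with_snp": len(m["down"] & snp_genes),
            }
        )
    return pd.DataFrame(rows)
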