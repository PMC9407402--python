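"""Selection of SNPs whose alternate allele is specific to a phenotype group.

A SNP is *group-specific* (e.g. specific to the highly heat-tolerant
cultivars) when at least one accession of the target heat classes carries
the alternate allele while no accession outside the group with a called
genotype does.  Heterozygous carriage counts as presence; missing
genotypes outside the group do not block selection.  Selected SNPs must
additionally have at least one consequence record in scope — genic (any
category other than intergenic/upstream/downstream), the 2 kb flanks, or
high-impact, depending on the requested scope.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import AccessionMeta, VariantRecord
from .variants import ConsequenceRecord, severity_rank

FLANK_CATEGORIES = {"upstream", "downstream"}
HIGH_IMPACT = "HIGH"

SCOPES = ("genic_and_flank", "high_impact_only", "both_union")


@dataclass
class GroupSpec:
    """Which heat classes form the target group and which consequence scope
    a selected SNP must fall in."""

    target_classes: set[str]
    scope: str = "genic_and_flank"

    def __post_init__(self) -> None:
        if not self.target_classes:
            raise ValueError("target_classes must be non-empty")
        if self.scope not in SCOPES:
            raise ValueError(f"scope must be one of {SCOPES}")


@dataclass
class GroupSnpResult:
    selected: list[VariantRecord]
    records: list[ConsequenceRecord]  # in-scope records of selected variants
    category_tally: Counter = field(default_factory=Counter)
    genes: dict[str, list[ConsequenceRecord]] = field(default_factory=dict)
    nonref_genes: set[str] = field(default_factory=set)

    @property
    def selected_keys(self) -> set[tuple]:
        return {v.key for v in self.selected}

    @property
    def gene_ids(self) -> set[str]:
        return set(self.genes)


def _record_in_scope(rec: ConsequenceRecord, scope: str) -> bool:
    if rec.category == "intergenic":
        return False
    genic_or_flank = True  # any non-intergenic record: genic or within-flank
    if scope == "genic_and_flank":
        return genic_or_flank
    if scope == "high_impact_only":
        return rec.impact == HIGH_IMPACT
    return genic_or_flank or rec.impact == HIGH_IMPACT


def is_group_specific(
    variant: VariantRecord, in_group: list[bool]
) -> bool:
    """Alt allele carried by >=1 target accession and by no called
    non-target accession."""
    any_target = False
    for j, member in enumerate(in_group):
        d = variant.alt_dosage(j)
        if d is None or d == 0:
            continue
        if member:
            any_target = True
        else:
            return False
    return any_target


def select_group_specific(
    variants: list[VariantRecord],
    accessions: list[str],
    meta: list[AccessionMeta],
    records: list[ConsequenceRecord],
    spec: GroupSpec,
    nonref_contigs: set[str] | None = None,
) -> GroupSnpResult:
    """Select group-specific SNPs among filtered, annotated variants.

    ``records`` are the per-variant-gene consequence records from the
    annotator.  The tally counts variant-gene records (a SNP in two genes'
    flanks contributes twice); ``selected`` holds unique variants.
    """
    by_acc = {m.accession: m.heat_class for m in meta}
    missing = [a for a in accessions if a not in by_acc]
    if missing:
        raise KeyError(
            f"metadata missing for VCF samples: {missing} "
            "(silent exclusion would corrupt specificity)"
        )
    in_group = [by_acc[a] in spec.target_classes for a in accessions]
    if not any(in_group):
        raise ValueError(
            f"target classes {sorted(spec.target_classes)} select no accession"
        )
    recs_by_key: dict[tuple, list[ConsequenceRecord]] = defaultdict(list)
    for r in records:
        recs_by_key[r.variant_key].append(r)

    selected: list[VariantRecord] = []
    kept_records: list[ConsequenceRecord] = []
    tally: Counter = Counter()
    genes: dict[str, list[ConsequenceRecord]] = defaultdict(list)
    nonref_contigs = nonref_contigs or set()
    for v in variants:
        if not is_group_specific(v, in_group):
            continue
        in_scope = [
            r for r in recs_by_key.get(v.key, []) if _record_in_scope(r, spec.scope)
        ]
        if not in_scope:
            continue
        selected.append(v)
        for r in in_scope:
            kept_records.append(r)
            tally[r.category] += 1
            if r.gene_id is not None:
                genes[r.gene_id].append(r)
    nonref_genes = {
        g
        for g, rs in genes.items()
        if any(r.variant_key[0] in nonref_contigs for r in rs)
    }
    return GroupSnpResult(
        selected=selected,
        records=kept_records,
        category_tally=tally,
        genes=dict(genes),
        nonref_genes=nonref_genes,
    )


def tally_table(result: GroupSnpResult) -> pd.DataFrame:
    """Category-count table (variant-gene record unit) with a total row."""
    return tally_from_counts(dict(result.category_tally))


def tally_from_counts(counts: dict[str, int]) -> pd.DataFrame:
    """Build the category table from a category -> count mapping.

    The reporting code path shared by :func:`tally_table` and by callers
    tabulating externally obtained counts; the total is the sum of the
    categories.
    """
    cats = sorted(counts, key=severity_rank)
    rows = [{"category": c, "count": int(counts[c])} for c in cats]
    rows.append({"category": "total", "count": int(sum(counts.values()))})
    return pd.DataFrame(rows)


def impact_subtotals(
    counts: dict[str, int], impact_map: dict[str, str]
) -> dict[str, int]:
    """Sum category counts into impact classes via the impact map."""
    out: dict[str, int] = {"HIGH": 0, "MODERATE": 0, "LOW": 0, "MODIFIER": 0}
    for cat, n in counts.items():
        out[impact_map[cat]] += int(n)
    return out


def per_gene_table(
    result: GroupSnpResult, nonref_contigs: set[str] | None = None
) -> pd.DataFrame:
    nonref_contigs = nonref_contigs or set()
    rows = []
    for gene, recs in sorted(result.genes.items()):
        rows.append(
            {
                "gene": gene,
                "n_snps": len({r.variant_key for r in recs}),
                "categories": ",".join(
                    sorted({r.category for r in recs}, key=severity_rank)
                ),
                "non_reference": any(
                    r.variant_key[0] in nonref_contigs for r in recs
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "n_snps", "categories", "non_reference"]
    )
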