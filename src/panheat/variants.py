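"""SNP filtering, functional-consequence annotation, and SNP distances.

The annotator assigns each biallelic SNP, per overlapping or flanking gene,
exactly one category out of the taxonomy

    intergenic, upstream, downstream, utr5, utr3, exonic (non-coding gene
    exon), intronic, splice_acceptor, splice_donor, synonymous, missense,
    stop_gained, stop_lost, start_lost, start_gained

using positional precedence (splice sites beat intron, coding effects are
resolved by rebuilding the alternate CDS strand-aware and comparing
translations under the standard genetic code).  Impact classes group the
categories: HIGH = splice_acceptor/donor, start_lost, stop_gained;
MODERATE = missense; LOW = synonymous, start_gained, stop_lost; everything
else MODIFIER.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .io_formats import ContigSet, GeneModel, VariantRecord

CATEGORIES = (
    "intergenic",
    "upstream",
    "downstream",
    "utr5",
    "utr3",
    "exonic",
    "intronic",
    "splice_acceptor",
    "splice_donor",
    "synonymous",
    "missense",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "start_gained",
)

# most to least severe; drives the per-variant summary
SEVERITY_ORDER = (
    "splice_acceptor",
    "splice_donor",
    "start_lost",
    "stop_gained",
    "stop_lost",
    "missense",
    "synonymous",
    "start_gained",
    "utr5",
    "utr3",
    "exonic",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
)
_SEVERITY_RANK = {c: i for i, c in enumerate(SEVERITY_ORDER)}

DEFAULT_IMPACT_MAP: dict[str, str] = {
    "splice_acceptor": "HIGH",
    "splice_donor": "HIGH",
    "start_lost": "HIGH",
    "stop_gained": "HIGH",
    "missense": "MODERATE",
    "synonymous": "LOW",
    "start_gained": "LOW",
    "stop_lost": "LOW",
    "utr5": "MODIFIER",
    "utr3": "MODIFIER",
    "exonic": "MODIFIER",
    "intronic": "MODIFIER",
    "upstream": "MODIFIER",
    "downstream": "MODIFIER",
    "intergenic": "MODIFIER",
}

STOP_CODONS = {"TAA", "TAG", "TGA"}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class FilterParams:
    """Site-level filters: keep biallelic SNPs with MAF >= ``maf_min`` and
    missing-genotype fraction below ``max_missing_fraction``."""

    maf_min: float = 0.05
    max_missing_fraction: float = 0.8
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.maf_min <= 0.5):
            raise ValueError("maf_min must be in [0, 0.5]")
        if not (0 <= self.max_missing_fraction <= 1):
            raise ValueError("max_missing_fraction must be in [0, 1]")


@dataclass
class AnnotParams:
    flank_bp: int = 2000
    splice_window: int = 2
    impact_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_IMPACT_MAP)
    )

    def __post_init__(self) -> None:
        if self.flank_bp <= 0:
            raise ValueError("flank_bp must be > 0")
        if self.splice_window < 1:
            raise ValueError("splice_window must be >= 1")


@dataclass(frozen=True)
class ConsequenceRecord:
    """One variant-gene consequence (gene_id None for intergenic)."""

    variant_key: tuple[str, int, str, str]
    gene_id: str | None
    category: str
    impact: str
    aa_change: str | None = None
    distance: int = 0  # bp to the gene span (0 when inside)


def impact_of(category: str, impact_map: dict[str, str] | None = None) -> str:
    impact_map = impact_map or DEFAULT_IMPACT_MAP
    if category not in impact_map:
        raise KeyError(f"unknown category {category!r}")
    return impact_map[category]


def severity_rank(category: str) -> int:
    return _SEVERITY_RANK[category]


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_variants(
    variants: list[VariantRecord], params: FilterParams | None = None
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, str]]]:
    """Apply biallelic-SNP / missingness / MAF filters.

    A record is kept iff it is a biallelic single-base SNP, its fraction of
    missing genotypes is below ``max_missing_fraction``, and its minor
    allele frequency over called alleles is at least ``maf_min``.
    """
    params = params or FilterParams()
    kept: list[VariantRecord] = []
    removed: list[tuple[VariantRecord, str]] = []
    for v in variants:
        if params.biallelic_only and not v.is_biallelic_snp():
            removed.append((v, "not a biallelic SNP"))
            continue
        miss = v.missing_fraction()
        if miss >= params.max_missing_fraction:
            removed.append((v, f"missing fraction {miss:.2f}"))
            continue
        maf = v.maf()
        if maf < params.maf_min:
            removed.append((v, f"MAF {maf:.4f} < {params.maf_min}"))
            continue
        kept.append(v)
    return kept, removed


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

class GeneIndex:
    """Interval index of gene spans (padded by the flank) per contig."""

    def __init__(self, models: list[GeneModel], flank_bp: int):
        self.models = {m.gene_id: m for m in models}
        self.trees: dict[str, IntervalTree] = {}
        for m in models:
            tree = self.trees.setdefault(m.contig, IntervalTree())
            # intervaltree is half-open; +1 converts 1-based inclusive ends
            tree.addi(max(1, m.start - flank_bp), m.end + flank_bp + 1, m.gene_id)

    def query(self, contig: str, pos: int) -> list[GeneModel]:
        tree = self.trees.get(contig)
        if tree is None:
            return []
        return sorted(
            (self.models[iv.data] for iv in tree.at(pos)),
            key=lambda m: m.gene_id,
        )


def _cds_coding_positions(gene: GeneModel) -> list[int]:
    """Genomic positions of CDS bases in translation order."""
    pos = [p for s, e in gene.cds for p in range(s, e + 1)]
    return pos if gene.strand == "+" else pos[::-1]


def _spliced_positions(
    intervals: list[tuple[int, int]], strand: str
) -> list[int]:
    pos = [p for s, e in sorted(intervals) for p in range(s, e + 1)]
    return pos if strand == "+" else pos[::-1]


def _coding_base(base: str, strand: str) -> str:
    return base if strand == "+" else revcomp(base)


def _cds_sequence(gene: GeneModel, contig_seq: str) -> str:
    seq = "".join(contig_seq[s - 1 : e] for s, e in gene.cds)
    return seq if gene.strand == "+" else revcomp(seq)


def _classify_coding(
    gene: GeneModel, contig_seq: str, pos: int, alt: str
) -> tuple[str, str]:
    """Category and amino-acid change for a SNP inside the CDS."""
    order = _cds_coding_positions(gene)
    idx = order.index(pos)
    cds = _cds_sequence(gene, contig_seq)
    ci = idx // 3
    within = idx % 3
    ref_codon = cds[3 * ci : 3 * ci + 3]
    alt_base = _coding_base(alt, gene.strand)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = "*" if ref_codon in STOP_CODONS else str(Seq(ref_codon).translate())
    alt_aa = "*" if alt_codon in STOP_CODONS else str(Seq(alt_codon).translate())
    change = f"p.{ref_aa}{ci + 1}{alt_aa}"
    if ci == 0:
        if alt_codon != "ATG":
            return "start_lost", change
        return "synonymous", change
    if ref_codon in STOP_CODONS:
        if alt_codon in STOP_CODONS:
            return "synonymous", change
        return "stop_lost", change
    if alt_codon in STOP_CODONS:
        return "stop_gained", change
    if ref_aa == alt_aa:
        return "synonymous", change
    return "missense", change


def _creates_start(
    gene: GeneModel, contig_seq: str, pos: int, alt: str
) -> bool:
    """True when the alt allele creates an ATG overlapping ``pos`` within
    the spliced 5'UTR (the start_gained predicate)."""
    if not gene.utr5:
        return False
    utr_pos = _spliced_positions(gene.utr5, gene.strand)
    if pos not in utr_pos:
        return False
    k = utr_pos.index(pos)
    seq = list(
        _coding_base(contig_seq[p - 1], gene.strand) for p in utr_pos
    )
    ref_windows = {
        "".join(seq[i : i + 3]) for i in range(max(0, k - 2), k + 1)
        if i + 3 <= len(seq)
    }
    seq[k] = _coding_base(alt, gene.strand)
    alt_windows = {
        "".join(seq[i : i + 3]) for i in range(max(0, k - 2), k + 1)
        if i + 3 <= len(seq)
    }
    return "ATG" in alt_windows and "ATG" not in ref_windows


def _splice_category(
    gene: GeneModel, pos: int, window: int
) -> str | None:
    for intron_s, intron_e in gene.introns:
        if not (intron_s <= pos <= intron_e):
            continue
        if gene.strand == "+":
            donor = range(intron_s, min(intron_s + window, intron_e + 1))
            acceptor = range(max(intron_e - window + 1, intron_s), intron_e + 1)
        else:
            donor = range(max(intron_e - window + 1, intron_s), intron_e + 1)
            acceptor = range(intron_s, min(intron_s + window, intron_e + 1))
        if pos in donor:
            return "splice_donor"
        if pos in acceptor:
            return "splice_acceptor"
        return "intronic"
    return None


def classify_against_gene(
    gene: GeneModel,
    contig_seq: str,
    pos: int,
    alt: str,
    params: AnnotParams,
) -> tuple[str, str | None, int] | None:
    """Category, aa-change and distance of a SNP relative to one gene.

    Returns None when the SNP is outside the gene span and its flank.
    """
    if gene.start <= pos <= gene.end:
        in_exon = any(s <= pos <= e for s, e in gene.exons)
        if in_exon:
            if any(s <= pos <= e for s, e in gene.cds):
                cat, change = _classify_coding(gene, contig_seq, pos, alt)
                return cat, change, 0
            if any(s <= pos <= e for s, e in gene.utr5):
                if _creates_start(gene, contig_seq, pos, alt):
                    return "start_gained", None, 0
                return "utr5", None, 0
            if any(s <= pos <= e for s, e in gene.utr3):
                return "utr3", None, 0
            return "exonic", None, 0
        cat = _splice_category(gene, pos, params.splice_window)
        return (cat or "intronic"), None, 0
    if pos < gene.start:
        dist = gene.start - pos
        side = "upstream" if gene.strand == "+" else "downstream"
    else:
        dist = pos - gene.end
        side = "downstream" if gene.strand == "+" else "upstream"
    if dist <= params.flank_bp:
        return side, None, dist
    return None


def annotate(
    variants: list[VariantRecord],
    models: list[GeneModel],
    genome: ContigSet,
    params: AnnotParams | None = None,
) -> tuple[list[ConsequenceRecord], dict[tuple, ConsequenceRecord]]:
    """Annotate biallelic SNPs against gene models.

    Returns the full list of variant-gene consequence records plus a
    per-variant summary mapping each variant key to its most severe record
    (ties broken by distance to the gene, then by gene id; a variant with
    no gene within the flank is summarised as intergenic).
    """
    params = params or AnnotParams()
    index = GeneIndex(models, params.flank_bp)
    seqs = {c.name: c.sequence for c in genome}
    records: list[ConsequenceRecord] = []
    summary: dict[tuple, ConsequenceRecord] = {}
    for v in variants:
        if v.contig not in seqs:
            raise KeyError(f"variant contig {v.contig} absent from genome")
        if v.pos > len(seqs[v.contig]):
            raise ValueError(
                f"variant {v.contig}:{v.pos} beyond contig end"
            )
        per_gene: list[ConsequenceRecord] = []
        for gene in index.query(v.contig, v.pos):
            hit = classify_against_gene(
                gene, seqs[v.contig], v.pos, v.alt, params
            )
            if hit is None:
                continue
            cat, change, dist = hit
            per_gene.append(
                ConsequenceRecord(
                    variant_key=v.key,
                    gene_id=gene.gene_id,
                    category=cat,
                    impact=impact_of(cat, params.impact_map),
                    aa_change=change,
                    distance=dist,
                )
            )
        if not per_gene:
            rec = ConsequenceRecord(
                variant_key=v.key,
                gene_id=None,
                category="intergenic",
                impact=impact_of("intergenic", params.impact_map),
            )
            records.append(rec)
            summary[v.key] = rec
            continue
        records.extend(per_gene)
        summary[v.key] = min(
            per_gene,
            key=lambda r: (severity_rank(r.category), r.distance, r.gene_id),
        )
    return records, summary


def records_to_frame(records: list[ConsequenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": r.variant_key[0],
                "pos": r.variant_key[1],
                "ref": r.variant_key[2],
                "alt": r.variant_key[3],
                "gene": r.gene_id,
                "category": r.category,
                "impact": r.impact,
                "aa_change": r.aa_change,
            }
            for r in records
        ]
    )


def tally_by_category(
    records: list[ConsequenceRecord],
    genome: ContigSet | None = None,
) -> pd.DataFrame:
    """Count consequence records per category (variant-gene pair unit).

    With a genome, counts are additionally split into reference and
    non-reference contig classes.  A ``total`` row closes the table.
    """
    cats = sorted({r.category for r in records}, key=severity_rank)
    rows = []
    for cat in cats:
        sub = [r for r in records if r.category == cat]
        row = {"category": cat, "count": len(sub)}
        if genome is not None:
            n_ref = sum(1 for r in sub if genome.is_reference(r.variant_key[0]))
            row["reference"] = n_ref
            row["non_reference"] = len(sub) - n_ref
        rows.append(row)
    total = {"category": "total", "count": len(records)}
    if genome is not None:
        total["reference"] = sum(r["reference"] for r in rows)
        total["non_reference"] = sum(r["non_reference"] for r in rows)
    rows.append(total)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# SNP distances
# ---------------------------------------------------------------------------

def snp_distance_matrix(
    variants: list[VariantRecord], accessions: list[str]
) -> pd.DataFrame:
    """Allele-sharing distance: 1 - mean shared-allele proportion over
    sites where both genotypes are called.

    At one site a pair with alt dosages d1, d2 in {0,1,2} shares
    1 - |d1 - d2| / 2 of its alleles.  A pair with no co-called site gets
    the maximal distance 1 with a warning.
    """
    import warnings

    if len(accessions) < 2:
        raise ValueError("need >= 2 accessions")
    n = len(accessions)
    dosages = np.full((len(variants), n), -1, dtype=np.int8)
    for i, v in enumerate(variants):
        for j in range(n):
            d = v.alt_dosage(j)
            dosages[i, j] = -1 if d is None else d
    dist = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            called = (dosages[:, a] >= 0) & (dosages[:, b] >= 0)
            if not called.any():
                warnings.warn(
                    f"no co-called sites for {accessions[a]}/{accessions[b]}; "
                    "distance set to 1"
                )
                d = 1.0
            else:
                diff = np.abs(
                    dosages[called, a].astype(float) - dosages[called, b]
                )
                d = float(np.mean(diff / 2.0))
            dist[a, b] = dist[b, a] = d
    return pd.DataFrame(dist, index=accessions, columns=accessions)
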