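"""Readers/writers and shared coordinate conventions for the pipeline.

Every coordinate held in memory is 1-based and inclusive, matching the
native conventions of GFF3 and VCF.  The BEDGraph-like coverage dialect
consumed here is likewise declared 1-based inclusive so that no conversion
happens anywhere in the package.
"""

from __future__ import annotations

import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

VALID_BASES = set("ACGTN")

HEAT_CLASSES = ("HT", "T", "MT", "S", "HS")
SUBPOPULATIONS = ("Indica", "Japonica", "Aus", "Admix")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive interval on a named contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass
class Contig:
    name: str
    sequence: str
    is_reference: bool = True


@dataclass
class ContigSet:
    """Ordered collection of reference and non-reference contigs."""

    contigs: list[Contig] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for c in self.contigs:
            if c.name in seen:
                raise FormatError(f"duplicate contig name: {c.name}")
            seen.add(c.name)
            if not c.sequence:
                raise FormatError(f"empty sequence for contig {c.name}")
            bad = set(c.sequence) - VALID_BASES
            if bad:
                raise FormatError(
                    f"non-IUPAC characters {sorted(bad)} in contig {c.name}"
                )

    def __iter__(self):
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)

    def names(self) -> list[str]:
        return [c.name for c in self.contigs]

    def get(self, name: str) -> Contig:
        for c in self.contigs:
            if c.name == name:
                return c
        raise KeyError(name)

    def is_reference(self, name: str) -> bool:
        return self.get(name).is_reference


@dataclass
class GeneModel:
    """One gene's exon/CDS/UTR structure on a contig.

    ``exons`` and ``cds`` are sorted, disjoint lists of ``(start, end)``
    1-based inclusive pairs.  ``utr5``/``utr3`` are derived: exonic bases
    outside the CDS, assigned to the 5' or 3' side strand-aware.  A model
    with an empty ``cds`` is non-coding.
    """

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon outside gene span in {self.gene_id}")
        if self.cds and not (self.utr5 or self.utr3):
            self.utr5, self.utr3 = derive_utrs(self.exons, self.cds, self.strand)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.start, self.end)

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def exon_positions(self) -> list[int]:
        """All exonic genomic positions, ascending."""
        return [p for s, e in self.exons for p in range(s, e + 1)]


def derive_utrs(
    exons: Sequence[tuple[int, int]],
    cds: Sequence[tuple[int, int]],
    strand: str,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Split exonic non-CDS bases into 5' and 3' UTR interval lists."""
    cds_lo = min(s for s, _ in cds)
    cds_hi = max(e for _, e in cds)
    left: list[tuple[int, int]] = []
    right: list[tuple[int, int]] = []
    for s, e in exons:
        if e < cds_lo:
            left.append((s, e))
        elif s > cds_hi:
            right.append((s, e))
        else:
            if s < cds_lo:
                left.append((s, cds_lo - 1))
            if e > cds_hi:
                right.append((cds_hi + 1, e))
    if strand == "+":
        return left, right
    return right, left


@dataclass
class AccessionMeta:
    accession: str
    subpopulation: str
    heat_class: str
    spikelet_fertility: float | None = None
    depth: float | None = None

    def __post_init__(self) -> None:
        if self.subpopulation not in SUBPOPULATIONS:
            raise ValueError(f"unknown subpopulation {self.subpopulation!r}")
        if self.heat_class not in HEAT_CLASSES:
            raise ValueError(f"unknown heat class {self.heat_class!r}")
        if self.spikelet_fertility is not None:
            expected = classify_heat_response(self.spikelet_fertility)
            if expected != self.heat_class:
                raise ValueError(
                    f"{self.accession}: heat_class {self.heat_class} "
                    f"inconsistent with fertility {self.spikelet_fertility} "
                    f"(expected {expected})"
                )


def classify_heat_response(fertility: float) -> str:
    """Assign one of the five heat-response classes from spikelet fertility.

    Highly tolerant: fertility > 65; tolerant: 50 < f <= 65; moderately
    tolerant: 35 < f <= 50; susceptible: 15 < f <= 35; highly susceptible:
    f <= 15.  Boundaries are half-open upward so that the partition of
    [0, 100] is exhaustive and mutually exclusive.
    """
    if not (0 <= fertility <= 100):
        raise ValueError(f"fertility {fertility} outside [0, 100]")
    if fertility > 65:
        return "HT"
    if fertility > 50:
        return "T"
    if fertility > 35:
        return "MT"
    if fertility > 15:
        return "S"
    return "HS"


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, nonref_prefix: str = "contig") -> ContigSet:
    """Read a genome FASTA.

    Sequences are uppercased on read.  Contigs whose name starts with
    ``nonref_prefix`` are flagged non-reference (the convention used by
    the synthetic generator and by ``write_fasta``'s description field).
    """
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        is_ref = not rec.id.startswith(nonref_prefix)
        if "nonref" in rec.description.split():
            is_ref = False
        contigs.append(Contig(rec.id, seq, is_ref))
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return ContigSet(contigs)


def write_fasta(contig_set: ContigSet, path: str | Path, width: int = 80) -> None:
    records = []
    for c in contig_set:
        desc = "" if c.is_reference else "nonref"
        records.append(SeqRecord(Seq(c.sequence), id=c.name, description=desc))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse GFF3 gene/mRNA/exon/CDS features into :class:`GeneModel` s.

    One model per gene; if a gene carries several mRNAs the one with the
    longest CDS is kept (with a warning).  UTRs are derived from exon/CDS
    structure when not given.  A CDS whose length is not divisible by 3
    triggers a warning and the model is flagged non-coding.  An exon lying
    outside its gene span rejects the record.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            mrnas = [gene]
        if len(mrnas) > 1:
            mrnas.sort(
                key=lambda m: sum(
                    c.end - c.start + 1 for c in db.children(m, featuretype="CDS")
                ),
                reverse=True,
            )
            warnings.warn(
                f"gene {gene.id} has {len(mrnas)} mRNAs; keeping longest CDS"
            )
        mrna = mrnas[0]
        exons = [
            (f.start, f.end)
            for f in db.children(mrna, featuretype="exon", order_by="start")
        ]
        cds = [
            (f.start, f.end)
            for f in db.children(mrna, featuretype="CDS", order_by="start")
        ]
        if not exons:
            exons = [(gene.start, gene.end)]
        for s, e in exons:
            if s < gene.start or e > gene.end:
                raise FormatError(
                    f"exon {s}-{e} outside gene span in {gene.id}"
                )
        cds_len = sum(e - s + 1 for s, e in cds)
        if cds and cds_len % 3 != 0:
            warnings.warn(
                f"gene {gene.id}: CDS length {cds_len} not divisible by 3; "
                "flagging non-coding"
            )
            cds = []
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                start=gene.start,
                end=gene.end,
                exons=sorted(exons),
                cds=sorted(cds),
            )
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            base = f"{m.contig}\tpanheat\t"
            tail = f"\t.\t{m.strand}\t"
            fh.write(
                base + f"gene\t{m.start}\t{m.end}" + tail + f".\tID={m.gene_id}\n"
            )
            mrna_id = f"{m.gene_id}.t1"
            fh.write(
                base
                + f"mRNA\t{m.start}\t{m.end}"
                + tail
                + f".\tID={mrna_id};Parent={m.gene_id}\n"
            )
            for s, e in m.exons:
                fh.write(base + f"exon\t{s}\t{e}" + tail + f".\tParent={mrna_id}\n")
            phase = 0
            cds_blocks = m.cds if m.strand == "+" else list(reversed(m.cds))
            for s, e in cds_blocks:
                fh.write(
                    base + f"CDS\t{s}\t{e}" + tail + f"{phase}\tParent={mrna_id}\n"
                )
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass
class VariantRecord:
    """One variant with per-accession diploid genotypes.

    ``genotypes[i]`` is a pair of allele indices (0 = ref, 1.. = alt) or
    ``(None, None)`` for a missing call.  ``alts`` may hold several alleles
    straight off the parser; the filter stage removes multiallelics.
    """

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    genotypes: list[tuple[int | None, int | None]]
    vid: str = "."

    @property
    def alt(self) -> str:
        if len(self.alts) != 1:
            raise ValueError("variant is not biallelic")
        return self.alts[0]

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, ",".join(self.alts))

    def is_biallelic_snp(self) -> bool:
        return (
            len(self.alts) == 1
            and len(self.ref) == 1
            and len(self.alts[0]) == 1
            and self.ref != self.alts[0]
        )

    def missing_fraction(self) -> float:
        n_missing = sum(1 for a, b in self.genotypes if a is None and b is None)
        return n_missing / len(self.genotypes) if self.genotypes else 0.0

    def alt_dosage(self, i: int) -> int | None:
        """Count of alt alleles in sample ``i`` (biallelic); None if missing."""
        a, b = self.genotypes[i]
        if a is None and b is None:
            return None
        return int(a == 1) + int(b == 1)

    def maf(self) -> float:
        """Minor allele frequency over called alleles only (biallelic)."""
        alleles = [x for a, b in self.genotypes for x in (a, b) if x is not None]
        if not alleles:
            return 0.0
        p_alt = sum(1 for x in alleles if x == 1) / len(alleles)
        return min(p_alt, 1.0 - p_alt)


def read_vcf(path: str | Path) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF 4.x file; returns (records, sample names).

    Biallelic and multiallelic records are both parsed; missing genotypes
    come back as ``(None, None)``.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        gts: list[tuple[int | None, int | None]] = []
        for g in v.genotypes:
            a, b = g[0], g[1]
            gts.append(
                (a if a >= 0 else None, b if b >= 0 else None)
            )
        if len(gts) != len(samples):
            raise FormatError(
                f"sample count mismatch at {v.CHROM}:{v.POS}"
            )
        records.append(
            VariantRecord(
                contig=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                genotypes=gts,
                vid=v.ID or ".",
            )
        )
    vcf.close()
    return records, samples


def write_vcf(
    variants: Iterable[VariantRecord],
    accessions: Sequence[str],
    path: str | Path,
    contig_lengths: dict[str, int] | None = None,
    info: dict[tuple, str] | None = None,
) -> None:
    """Write variants as a minimal VCF 4.2 with GT (and optional ANN info)."""

    def fmt_gt(g: tuple[int | None, int | None]) -> str:
        a, b = g
        if a is None and b is None:
            return "./."
        return f"{a}/{b}"

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if info is not None:
            fh.write(
                '##INFO=<ID=ANN,Number=1,Type=String,'
                'Description="Consequence annotation: category|impact|gene">\n'
            )
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(accessions)
            + "\n"
        )
        for v in sorted(variants, key=lambda r: (r.contig, r.pos)):
            if len(v.genotypes) != len(accessions):
                raise FormatError(
                    f"variant {v.contig}:{v.pos} has {len(v.genotypes)} "
                    f"genotypes for {len(accessions)} accessions"
                )
            inf = info.get(v.key, ".") if info is not None else "."
            fh.write(
                f"{v.contig}\t{v.pos}\t{v.vid}\t{v.ref}\t{','.join(v.alts)}"
                f"\t.\tPASS\t{inf}\tGT\t"
                + "\t".join(fmt_gt(g) for g in v.genotypes)
                + "\n"
            )


# ---------------------------------------------------------------------------
# tabular formats
# ---------------------------------------------------------------------------

META_COLUMNS = ["accession", "subpopulation", "fertility", "heat_class", "depth"]


def read_metadata(path: str | Path) -> list[AccessionMeta]:
    df = pd.read_csv(path, sep="\t")
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"metadata missing columns: {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        fert = None if pd.isna(row.fertility) else float(row.fertility)
        depth = None if pd.isna(row.depth) else float(row.depth)
        out.append(
            AccessionMeta(
                accession=str(row.accession),
                subpopulation=str(row.subpopulation),
                heat_class=str(row.heat_class),
                spikelet_fertility=fert,
                depth=depth,
            )
        )
    return out


def write_metadata(meta: Iterable[AccessionMeta], path: str | Path) -> None:
    rows = [
        {
            "accession": m.accession,
            "subpopulation": m.subpopulation,
            "fertility": m.spikelet_fertility,
            "heat_class": m.heat_class,
            "depth": m.depth,
        }
        for m in meta
    ]
    pd.DataFrame(rows, columns=META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_coverage(path: str | Path) -> dict[str, list[tuple[int, int, int]]]:
    """Read a BEDGraph-like coverage TSV (contig, start, end, depth).

    Coordinates are 1-based inclusive in this dialect.  Positions absent
    from the file have depth 0.  Returns runs grouped by contig.
    """
    df = pd.read_csv(
        path, sep="\t", names=["contig", "start", "end", "depth"], comment="#"
    )
    out: dict[str, list[tuple[int, int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.contig), []).append(
            (int(row.start), int(row.end), int(row.depth))
        )
    return out


def write_coverage(
    runs: dict[str, list[tuple[int, int, int]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for contig in runs:
            for s, e, d in runs[contig]:
                fh.write(f"{contig}\t{s}\t{e}\t{d}\n")


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a DEG TSV with columns dataset, comparison, gene, log2fc, padj."""
    df = pd.read_csv(path, sep="\t")
    need = {"dataset", "comparison", "gene", "log2fc", "padj"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"DEG table missing columns: {sorted(missing)}")
    return df


def read_marker_table(path: str | Path) -> pd.DataFrame:
    """Read a QTL marker TSV (qtl_id, marker_id, sequence [, contig, pos])."""
    df = pd.read_csv(path, sep="\t")
    need = {"qtl_id", "marker_id"}
    missing = need - set(df.columns)
    if missing:
        raise FormatError(f"marker table missing columns: {sorted(missing)}")
    if "sequence" not in df.columns and not {"contig", "pos"} <= set(df.columns):
        raise FormatError("marker table needs 'sequence' or 'contig'+'pos'")
    return df
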