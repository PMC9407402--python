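"""Synthetic toy study generator with planted ground truth.

Emits a complete miniature input set — genome FASTA (reference plus
non-reference contigs), GFF3 gene models with 1-9 exons, per-accession
coverage tracks realizing a known presence/absence matrix, a VCF with
background SNPs plus group-specific SNPs planted per consequence category,
DEG tables with planted directions and deliberate contradictions, a QTL
marker table whose intervals contain known genes, and accession metadata —
together with a :class:`GroundTruth` object recording every planted signal
so each downstream stage can be verified exactly.

Generation is fully deterministic given the seed: a single root seed is
split into independent substreams (genome, presence, variants, expression,
QTLs, metadata) so that reconfiguring one stage does not perturb the
others.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from . import io_formats as iof
from .io_formats import AccessionMeta, Contig, ContigSet, GeneModel, VariantRecord
from .pav import PresenceMatrix
from .variants import STOP_CODONS, revcomp

BASES = np.array(list("ACGT"))
SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]

_FERTILITY_RANGES = {
    "HT": (66.0, 95.0),
    "T": (50.5, 65.0),
    "MT": (35.5, 50.0),
    "S": (15.5, 35.0),
    "HS": (1.0, 15.0),
}

DEFAULT_PLANTED_SNPS = {
    "missense": 3,
    "synonymous": 2,
    "stop_gained": 1,
    "start_lost": 1,
    "stop_lost": 1,
    "splice_donor": 1,
    "splice_acceptor": 1,
    "start_gained": 1,
    "utr5": 1,
    "utr3": 1,
    "exonic": 1,
    "intronic": 2,
    "upstream": 2,
    "downstream": 2,
}

DATASET_COMPARISONS = {
    "dsA": ["cmp1", "cmp2"],
    "dsB": ["cmp1", "cmp2"],
    "dsC": ["cmp1", "cmp2", "cmp3", "cmp4"],
    "dsD": ["cmp1", "cmp2", "cmp3", "cmp4"],
}


@dataclass
class SimConfig:
    """Study conditions of the toy cohort.

    The defaults mirror the real study's design at desk scale: the heat
    class composition (2 highly tolerant, 6 tolerant, 2 moderately
    tolerant, 3 susceptible, 2 highly susceptible accessions, one of which
    falls under the 10x depth cutoff), ~100 pan-genes of which a fifth are
    variable and ~12% sit on non-reference contigs, ~2000 background SNPs,
    four expression datasets with 2/2/4/4 comparisons, and six QTLs of
    which two overlap.
    """

    seed: int = 0
    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"HT": 2, "T": 6, "MT": 2, "S": 3, "HS": 2}
    )
    n_contigs_ref: int = 3
    n_contigs_nonref: int = 4
    contig_length: int = 260_000
    nonref_contig_length: int = 30_000
    n_core_genes: int = 80
    n_variable_genes: int = 20
    n_nonref_genes: int = 12
    n_noncoding_genes: int = 2
    variable_presence_prob: float = 0.7
    planted_group_snps: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_SNPS)
    )
    n_background_snps: int = 2000
    n_multiallelic: int = 20
    n_deg_up: int = 6
    n_deg_up_nonref: int = 2
    n_deg_down: int = 4
    n_deg_down_nonref: int = 1
    n_deg_contradictory: int = 2
    deg_background_per_comparison: int = 30
    n_qtl: int = 6
    qtl_span: int = 12_000
    flank_bp: int = 2000
    n_low_depth: int = 1

    def __post_init__(self) -> None:
        if self.group_sizes.get("HT", 0) < 2:
            raise ValueError("need >= 2 highly tolerant accessions")
        if any(v < 0 for v in self.group_sizes.values()):
            raise ValueError("group sizes must be >= 0")
        if not (0 <= self.variable_presence_prob <= 1):
            raise ValueError("variable_presence_prob must be in [0, 1]")
        if self.n_nonref_genes > self.n_genes:
            raise ValueError("more non-reference genes than genes")

    @property
    def n_accessions(self) -> int:
        return sum(self.group_sizes.values())

    @property
    def n_genes(self) -> int:
        return self.n_core_genes + self.n_variable_genes


@dataclass
class GroundTruth:
    """Everything planted, for exact downstream verification."""

    presence_truth: PresenceMatrix
    group_specific_snps: dict[tuple, tuple[str, str]]  # key -> (category, gene)
    deg_truth: dict[str, set[str]]  # up / down / contradictory gene sets
    qtl_member_genes: set[str]
    expected_candidates: dict[str, set[str]]  # up / down
    snp_genes: set[str]
    nonref_genes: set[str]
    excluded_accessions: set[str]

    def to_json(self) -> str:
        def enc(x):
            if isinstance(x, set):
                return sorted(x)
            return x

        payload = {
            "group_specific_snps": {
                f"{k[0]}:{k[1]}:{k[2]}:{k[3]}": list(v)
                for k, v in sorted(self.group_specific_snps.items())
            },
            "deg_truth": {k: sorted(v) for k, v in self.deg_truth.items()},
            "qtl_member_genes": sorted(self.qtl_member_genes),
            "expected_candidates": {
                k: sorted(v) for k, v in self.expected_candidates.items()
            },
            "snp_genes": sorted(self.snp_genes),
            "nonref_genes": sorted(self.nonref_genes),
            "excluded_accessions": sorted(self.excluded_accessions),
        }
        return json.dumps(payload, indent=1, sort_keys=True, default=enc)


@dataclass
class SimOutput:
    """In-memory handles to everything ``simulate`` wrote."""

    genome: ContigSet
    models: list[GeneModel]
    meta: list[AccessionMeta]
    variants: list[VariantRecord]
    accessions: list[str]
    coverage: dict[str, dict[str, list[tuple[int, int, int]]]]
    deg_table: pd.DataFrame
    marker_table: pd.DataFrame
    truth: GroundTruth
    paths: dict[str, Path]


# ---------------------------------------------------------------------------
# gene construction
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _partition(rng: np.random.Generator, total: int, parts: int, minimum: int) -> list[int]:
    """Split ``total`` into ``parts`` integers each >= minimum."""
    if parts == 1:
        return [total]
    slack = total - parts * minimum
    cuts = np.sort(rng.choice(slack + 1, size=parts - 1, replace=True))
    sizes = np.diff(np.concatenate([[0], cuts, [slack]]))
    return [int(minimum + s) for s in sizes]


def _build_gene(
    rng: np.random.Generator,
    gene_id: str,
    contig: str,
    offset: int,
    coding: bool,
) -> tuple[GeneModel, str]:
    """Construct one gene; returns the model (absolute, plus-strand
    coordinates) and its plus-strand genomic sequence."""
    strand = "+" if rng.random() < 0.5 else "-"
    n_exons = int(
        rng.choice(np.arange(1, 10), p=[0.3, 0.2, 0.15, 0.1, 0.08, 0.07, 0.05, 0.03, 0.02])
    )
    if coding:
        utr5_len = int(rng.integers(30, 120))
        utr3_len = int(rng.integers(30, 150))
        n_codons = int(rng.integers(50, 160))
        cds_codons = (
            ["ATG"]
            + [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons - 2)]
            + [("TAA", "TAG", "TGA")[rng.integers(0, 3)]]
        )
        transcript = _random_seq(rng, utr5_len) + "".join(cds_codons) + _random_seq(rng, utr3_len)
        cds_range = (utr5_len + 1, utr5_len + 3 * n_codons)  # transcript coords
    else:
        transcript = _random_seq(rng, int(rng.integers(300, 900)))
        cds_range = None
    tlen = len(transcript)
    if tlen < 40 * n_exons:
        n_exons = max(1, tlen // 60)
    exon_lens = _partition(rng, tlen, n_exons, 30)
    intron_lens = [int(rng.integers(80, 301)) for _ in range(n_exons - 1)]
    intron_seqs = ["GT" + _random_seq(rng, il - 4) + "AG" for il in intron_lens]

    # assemble in transcription orientation; local 1-based coordinates
    pieces: list[str] = []
    exons_local: list[tuple[int, int]] = []
    cds_local: list[tuple[int, int]] = []
    gpos = 0
    tpos = 0
    for i, elen in enumerate(exon_lens):
        pieces.append(transcript[tpos : tpos + elen])
        exons_local.append((gpos + 1, gpos + elen))
        if cds_range is not None:
            t_lo, t_hi = tpos + 1, tpos + elen
            lo = max(t_lo, cds_range[0])
            hi = min(t_hi, cds_range[1])
            if lo <= hi:
                cds_local.append((gpos + (lo - tpos), gpos + (hi - tpos)))
        gpos += elen
        tpos += elen
        if i < n_exons - 1:
            pieces.append(intron_seqs[i])
            gpos += intron_lens[i]
    gene_seq = "".join(pieces)
    glen = len(gene_seq)
    if strand == "-":
        gene_seq = revcomp(gene_seq)
        flip = lambda iv: (glen + 1 - iv[1], glen + 1 - iv[0])
        exons_local = sorted(flip(iv) for iv in exons_local)
        cds_local = sorted(flip(iv) for iv in cds_local)
    model = GeneModel(
        gene_id=gene_id,
        contig=contig,
        strand=strand,
        start=offset,
        end=offset + glen - 1,
        exons=[(offset + s - 1, offset + e - 1) for s, e in exons_local],
        cds=[(offset + s - 1, offset + e - 1) for s, e in cds_local],
    )
    return model, gene_seq


# ---------------------------------------------------------------------------
# planted SNP engineering
# ---------------------------------------------------------------------------

def _cds_order(gene: GeneModel) -> list[int]:
    pos = [p for s, e in gene.cds for p in range(s, e + 1)]
    return pos if gene.strand == "+" else pos[::-1]


def _aa(codon: str) -> str:
    return "*" if codon in STOP_CODONS else str(Seq(codon).translate())


def _plant_coding(
    rng: np.random.Generator, gene: GeneModel, seq: str, category: str
) -> tuple[int, str, str] | None:
    """Find (genomic pos, ref, alt) realizing a coding category in ``gene``."""
    order = _cds_order(gene)
    cds = "".join(seq[p - 1] for p in order)
    if gene.strand == "-":
        cds = "".join(revcomp(seq[p - 1]) for p in order)
    n = len(order) // 3
    if category == "start_lost":
        idxs = [0]
    elif category == "stop_lost":
        idxs = [n - 1]
    else:
        idxs = list(rng.permutation(np.arange(1, n - 1)))
    for ci in idxs:
        ref_codon = cds[3 * ci : 3 * ci + 3]
        for within in rng.permutation(3):
            for alt_base in rng.permutation(list("ACGT")):
                if alt_base == ref_codon[within]:
                    continue
                alt_codon = (
                    ref_codon[:within] + alt_base + ref_codon[within + 1 :]
                )
                ok = False
                if category == "start_lost":
                    ok = alt_codon != "ATG"
                elif category == "stop_lost":
                    ok = alt_codon not in STOP_CODONS
                elif category == "stop_gained":
                    ok = alt_codon in STOP_CODONS and ref_codon not in STOP_CODONS
                elif category == "missense":
                    ok = (
                        alt_codon not in STOP_CODONS
                        and ref_codon not in STOP_CODONS
                        and _aa(alt_codon) != _aa(ref_codon)
                    )
                elif category == "synonymous":
                    ok = (
                        alt_codon not in STOP_CODONS
                        and _aa(alt_codon) == _aa(ref_codon)
                    )
                if not ok:
                    continue
                pos = order[3 * ci + int(within)]
                genomic_alt = alt_base if gene.strand == "+" else revcomp(alt_base)
                return pos, seq[pos - 1], genomic_alt
    return None


def _utr5_spliced(gene: GeneModel) -> list[int]:
    pos = [p for s, e in sorted(gene.utr5) for p in range(s, e + 1)]
    return pos if gene.strand == "+" else pos[::-1]


def _atg_windows(seq: list[str], k: int) -> set[str]:
    return {
        "".join(seq[i : i + 3])
        for i in range(max(0, k - 2), k + 1)
        if i + 3 <= len(seq)
    }


def _plant_in_gene(
    rng: np.random.Generator,
    gene: GeneModel,
    contigs: dict[str, list[str]],
    category: str,
    flank_bp: int,
) -> tuple[int, str, str] | None:
    """(pos, ref, alt) realizing ``category`` against ``gene``; may edit the
    genome in place (start_gained context engineering)."""
    seq_list = contigs[gene.contig]
    seq = "".join(seq_list)
    if category in ("missense", "synonymous", "stop_gained", "start_lost", "stop_lost"):
        return _plant_coding(rng, gene, seq, category)
    if category in ("splice_donor", "splice_acceptor"):
        introns = gene.introns
        if not introns:
            return None
        s, e = introns[rng.integers(0, len(introns))]
        if gene.strand == "+":
            pos = s if category == "splice_donor" else e
        else:
            pos = e if category == "splice_donor" else s
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return pos, ref, alt
    if category == "intronic":
        introns = [iv for iv in gene.introns if iv[1] - iv[0] + 1 >= 9]
        if not introns:
            return None
        s, e = introns[rng.integers(0, len(introns))]
        pos = (s + e) // 2
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return pos, ref, alt
    if category == "start_gained":
        utr = _utr5_spliced(gene)
        if len(utr) < 7:
            return None
        k = len(utr) // 2
        coding = gene.strand == "+"
        # context A C G around k (coding orientation): alt C->T creates ATG
        for off, base in ((-2, "C"), (-1, "A"), (0, "C"), (1, "G"), (2, "C")):
            if 0 <= k + off < len(utr):
                p = utr[k + off]
                seq_list[p - 1] = base if coding else revcomp(base)
        pos = utr[k]
        ref = "C" if coding else "G"
        alt = "T" if coding else "A"
        return pos, ref, alt
    if category == "utr5":
        utr = _utr5_spliced(gene)
        if not utr:
            return None
        spliced = [
            seq[p - 1] if gene.strand == "+" else revcomp(seq[p - 1]) for p in utr
        ]
        for k in rng.permutation(len(utr)):
            k = int(k)
            for alt_c in rng.permutation(list("ACGT")):
                if alt_c == spliced[k]:
                    continue
                trial = list(spliced)
                trial[k] = alt_c
                if "ATG" in _atg_windows(trial, k) and "ATG" not in _atg_windows(
                    spliced, k
                ):
                    continue  # would be start_gained, not plain utr5
                pos = utr[k]
                alt = alt_c if gene.strand == "+" else revcomp(alt_c)
                return pos, seq[pos - 1], alt
        return None
    if category == "utr3":
        pos_list = [p for s, e in gene.utr3 for p in range(s, e + 1)]
        if not pos_list:
            return None
        pos = int(pos_list[rng.integers(0, len(pos_list))])
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return pos, ref, alt
    if category == "exonic":
        if gene.is_coding:
            return None
        pos_list = gene.exon_positions()
        pos = int(pos_list[rng.integers(0, len(pos_list))])
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return pos, ref, alt
    if category in ("upstream", "downstream"):
        d = int(rng.integers(200, flank_bp - 200))
        five_prime = (category == "upstream") == (gene.strand == "+")
        pos = gene.start - d if five_prime else gene.end + d
        if pos < 1 or pos > len(seq):
            return None
        ref = seq[pos - 1]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        return pos, ref, alt
    raise ValueError(f"cannot plant category {category!r}")


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def coverage_track(
    gene: GeneModel,
    target_fraction: float,
    depth: int,
    gene_body: str = "exons",
) -> list[tuple[int, int, int]]:
    """Coverage runs putting exactly ceil(fraction x body length) bases of
    the gene body at >= ``depth`` and the rest at 0 (omitted)."""
    if not (0 <= target_fraction <= 1):
        raise ValueError("target_fraction must be in [0, 1]")
    body = (
        gene.exon_positions()
        if gene_body == "exons" and gene.exons
        else list(range(gene.start, gene.end + 1))
    )
    k = math.ceil(target_fraction * len(body))
    covered = sorted(body[:k])
    runs: list[tuple[int, int, int]] = []
    for p in covered:
        if runs and p == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], p, depth)
        else:
            runs.append((p, p, depth))
    return runs


def _make_accessions(
    rng: np.random.Generator, config: SimConfig
) -> list[AccessionMeta]:
    metas: list[AccessionMeta] = []
    i = 0
    subpop_weights = {
        "HT": (["Indica", "Japonica", "Aus", "Admix"], [0.6, 0.2, 0.1, 0.1]),
        "T": (["Indica", "Japonica", "Aus", "Admix"], [0.6, 0.3, 0.05, 0.05]),
        "MT": (["Indica", "Japonica", "Aus", "Admix"], [0.5, 0.4, 0.05, 0.05]),
        "S": (["Indica", "Japonica", "Aus", "Admix"], [0.35, 0.5, 0.0, 0.15]),
        "HS": (["Indica", "Japonica", "Aus", "Admix"], [0.3, 0.55, 0.0, 0.15]),
    }
    low_depth_left = config.n_low_depth
    for cls in ("HT", "T", "MT", "S", "HS"):
        for _ in range(config.group_sizes.get(cls, 0)):
            i += 1
            lo, hi = _FERTILITY_RANGES[cls]
            fert = round(float(rng.uniform(lo, hi)), 1)
            pops, w = subpop_weights[cls]
            pop = str(rng.choice(pops, p=np.array(w) / sum(w)))
            if cls not in ("HT",) and low_depth_left > 0 and cls == "S":
                depth = round(float(rng.uniform(5, 9)), 1)
                low_depth_left -= 1
            else:
                depth = round(float(rng.uniform(12, 30)), 1)
            metas.append(
                AccessionMeta(
                    accession=f"acc{i:02d}",
                    subpopulation=pop,
                    heat_class=cls,
                    spikelet_fertility=fert,
                    depth=depth,
                )
            )
    return metas


def simulate(config: SimConfig, out_dir: str | Path) -> SimOutput:
    """Generate the full toy study under ``out_dir``; deterministic by seed."""
    out = Path(out_dir)
    (out / "coverage").mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    (
        rng_genome,
        rng_presence,
        rng_var,
        rng_deg,
        rng_qtl,
        rng_meta,
    ) = (np.random.default_rng(s) for s in root.spawn(6))

    meta = _make_accessions(rng_meta, config)
    accessions = [m.accession for m in meta]
    ht_idx = [i for i, m in enumerate(meta) if m.heat_class == "HT"]
    excluded = {
        m.accession
        for m in meta
        if m.depth is not None and m.depth <= 10.0
    }

    # --- genome and gene models -------------------------------------------
    n_ref_genes = config.n_genes - config.n_nonref_genes
    contig_specs: list[tuple[str, bool, int]] = []
    for i in range(config.n_contigs_ref):
        n = n_ref_genes // config.n_contigs_ref + (
            1 if i < n_ref_genes % config.n_contigs_ref else 0
        )
        contig_specs.append((f"chr{i + 1}", True, n))
    for i in range(config.n_contigs_nonref):
        n = config.n_nonref_genes // config.n_contigs_nonref + (
            1 if i < config.n_nonref_genes % config.n_contigs_nonref else 0
        )
        contig_specs.append((f"contig{i + 1:03d}", False, n))

    noncoding_left = config.n_noncoding_genes
    models: list[GeneModel] = []
    gene_seqs: dict[str, str] = {}
    contig_arrays: dict[str, list[str]] = {}
    contig_is_ref: dict[str, bool] = {}
    gid = 0
    for name, is_ref, n_genes_here in contig_specs:
        contig_is_ref[name] = is_ref
        placed: list[tuple[GeneModel, str]] = []
        offset = config.flank_bp + 1000
        for _ in range(n_genes_here):
            gid += 1
            coding = True
            if noncoding_left > 0 and is_ref and gid % 37 == 1 and gid > 1:
                coding = False
                noncoding_left -= 1
            model, gseq = _build_gene(rng_genome, f"gene{gid:04d}", name, offset, coding)
            placed.append((model, gseq))
            offset = model.end + 2 * config.flank_bp + 300 + int(rng_genome.integers(0, 500))
        needed = offset + config.flank_bp + 1000
        target = config.contig_length if is_ref else config.nonref_contig_length
        length = max(needed, target)
        arr = list(_random_seq(rng_genome, length))
        for model, gseq in placed:
            arr[model.start - 1 : model.end] = list(gseq)
            models.append(model)
            gene_seqs[model.gene_id] = gseq
        contig_arrays[name] = arr
    # a couple of leftover non-coding genes if chr layout skipped them
    nonref_gene_ids = {m.gene_id for m in models if not contig_is_ref[m.contig]}

    # --- presence truth ----------------------------------------------------
    gene_ids = [m.gene_id for m in models]
    ref_gene_ids = [g for g in gene_ids if g not in nonref_gene_ids]
    variable_pool = [g for g in gene_ids if g in nonref_gene_ids][
        : config.n_variable_genes // 2
    ]
    remaining = config.n_variable_genes - len(variable_pool)
    candidates_for_variable = [
        g for g in ref_gene_ids if g not in variable_pool
    ]
    pick = rng_presence.choice(
        len(candidates_for_variable), size=remaining, replace=False
    )
    variable_genes = set(variable_pool) | {
        str(candidates_for_variable[int(i)]) for i in pick
    }
    presence = np.ones((len(gene_ids), len(accessions)), dtype=bool)
    for i, g in enumerate(gene_ids):
        if g not in variable_genes:
            continue
        row = rng_presence.random(len(accessions)) < config.variable_presence_prob
        for j in ht_idx:
            row[j] = True  # planted-SNP hosts and resistant-unique genes stay callable
        if row.all():
            non_ht = [j for j in range(len(accessions)) if j not in ht_idx]
            row[int(rng_presence.choice(non_ht))] = False
        if not row.any():
            row[int(rng_presence.choice(len(accessions)))] = True
        presence[i] = row
    presence_truth = PresenceMatrix(gene_ids, list(accessions), presence)

    # --- planted group-specific SNPs --------------------------------------
    model_by_id = {m.gene_id: m for m in models}
    coding_multi_exon = [
        m.gene_id for m in models if m.is_coding and len(m.exons) >= 2
    ]
    coding_genes = [m.gene_id for m in models if m.is_coding]
    noncoding_genes = [m.gene_id for m in models if not m.is_coding]
    nonref_coding = [g for g in coding_genes if g in nonref_gene_ids]
    if len(nonref_coding) < 3:
        raise ValueError("infeasible config: need >= 3 coding non-reference genes")
    nonref_cand = nonref_coding[:3]

    planted: dict[tuple, tuple[str, str]] = {}
    planted_rows: list[tuple[int, str, str, str, str]] = []  # pos info
    used_hosts: set[str] = set()

    def pick_host(category: str, forced: str | None) -> str:
        if forced is not None:
            return forced
        if category in ("splice_donor", "splice_acceptor", "intronic"):
            pool = coding_multi_exon
        elif category == "exonic":
            pool = noncoding_genes
        elif category in ("upstream", "downstream"):
            pool = coding_genes
        else:
            pool = coding_genes
        fresh = [g for g in pool if g not in used_hosts and g not in nonref_cand]
        if not fresh:
            fresh = [g for g in pool if g not in nonref_cand] or pool
        if not fresh:
            raise ValueError(f"infeasible config: no host gene for {category}")
        return str(fresh[int(rng_var.integers(0, len(fresh)))])

    forced_hosts: dict[tuple[str, int], str] = {
        ("missense", 0): nonref_cand[0],
        ("missense", 1): nonref_cand[1],
        ("upstream", 0): nonref_cand[2],
    }
    for category in sorted(config.planted_group_snps):
        for k in range(config.planted_group_snps[category]):
            host = pick_host(category, forced_hosts.get((category, k)))
            attempts = 0
            hit = None
            while hit is None and attempts < 20:
                hit = _plant_in_gene(
                    rng_var, model_by_id[host], contig_arrays, category, config.flank_bp
                )
                if hit is None:
                    host = pick_host(category, None)
                attempts += 1
            if hit is None:
                raise ValueError(
                    f"infeasible config: cannot plant a {category} SNP"
                )
            pos, _ref, alt = hit
            contig = model_by_id[host].contig
            ref = contig_arrays[contig][pos - 1]
            key = (contig, pos, ref, alt)
            if key[:2] in {p[:2] for p in planted}:
                continue  # same position twice: skip the duplicate plant
            planted[key] = (category, host)
            used_hosts.add(host)

    genome = ContigSet(
        [
            Contig(name, "".join(arr), contig_is_ref[name])
            for name, arr in contig_arrays.items()
        ]
    )
    seqs = {c.name: c.sequence for c in genome}

    # --- VCF records -------------------------------------------------------
    variants: list[VariantRecord] = []
    taken = {(k[0], k[1]) for k in planted}
    host_presence = {g: presence_truth.values[gene_ids.index(g)] for g in gene_ids}
    for key, (category, host) in sorted(planted.items()):
        contig, pos, ref, alt = key
        gts: list[tuple[int | None, int | None]] = []
        present_row = host_presence[host]
        for j in range(len(accessions)):
            if j in ht_idx:
                gts.append((1, 1))
            elif not present_row[j]:
                gts.append((None, None))
            else:
                gts.append((0, 0))
        variants.append(VariantRecord(contig, pos, ref, (alt,), gts))

    contig_names = genome.names()
    lengths = np.array([len(seqs[n]) for n in contig_names], dtype=float)
    contig_p = lengths / lengths.sum()
    n_bg = config.n_background_snps
    attempts = 0
    while n_bg > 0 and attempts < 20 * config.n_background_snps:
        attempts += 1
        cname = str(rng_var.choice(contig_names, p=contig_p))
        pos = int(rng_var.integers(1, len(seqs[cname]) + 1))
        if (cname, pos) in taken:
            continue
        taken.add((cname, pos))
        ref = seqs[cname][pos - 1]
        alt = str(rng_var.choice([b for b in "ACGT" if b != ref]))
        u = rng_var.random()
        p_alt = (
            float(rng_var.uniform(0.005, 0.04))
            if u < 0.1
            else float(rng_var.uniform(0.05, 0.5))
        )
        miss = float(rng_var.uniform(0.85, 0.95)) if rng_var.random() < 0.05 else float(
            rng_var.uniform(0.0, 0.2)
        )
        gts = []
        for j in range(len(accessions)):
            if rng_var.random() < miss:
                gts.append((None, None))
            else:
                a = int(rng_var.random() < p_alt)
                b = int(rng_var.random() < p_alt)
                gts.append((min(a, b), max(a, b)))
        v = VariantRecord(cname, pos, ref, (alt,), gts)
        # background must never satisfy the group-specificity predicate
        carriers = [j for j in range(len(accessions)) if (v.alt_dosage(j) or 0) > 0]
        if carriers and all(j in ht_idx for j in carriers):
            non_ht = [j for j in range(len(accessions)) if j not in ht_idx]
            j = int(rng_var.choice(non_ht))
            gts[j] = (0, 1)
            v = VariantRecord(cname, pos, ref, (alt,), gts)
        variants.append(v)
        n_bg -= 1
    for _ in range(config.n_multiallelic):
        cname = str(rng_var.choice(contig_names, p=contig_p))
        pos = int(rng_var.integers(1, len(seqs[cname]) + 1))
        if (cname, pos) in taken:
            continue
        taken.add((cname, pos))
        ref = seqs[cname][pos - 1]
        alts = tuple(b for b in "ACGT" if b != ref)[:2]
        gts = []
        for j in range(len(accessions)):
            a = int(rng_var.integers(0, 3))
            b = int(rng_var.integers(0, 3))
            gts.append((min(a, b), max(a, b)))
        variants.append(VariantRecord(cname, pos, ref, alts, gts))
    variants.sort(key=lambda v: (v.contig, v.pos))

    # --- coverage tracks ---------------------------------------------------
    coverage: dict[str, dict[str, list[tuple[int, int, int]]]] = {}
    for j, m in enumerate(meta):
        depth = max(6, int(round(m.depth or 15)))
        runs_by_contig: dict[str, list[tuple[int, int, int]]] = {}
        for i, gene in enumerate(models):
            if presence[i, j]:
                frac = float(rng_presence.uniform(0.86, 1.0))
            else:
                frac = float(rng_presence.uniform(0.25, 0.65))
            for run in coverage_track(gene, frac, depth):
                runs_by_contig.setdefault(gene.contig, []).append(run)
        for cname in runs_by_contig:
            runs_by_contig[cname].sort()
        coverage[m.accession] = runs_by_contig

    # --- DEG tables --------------------------------------------------------
    snp_genes = sorted({host for _, host in planted.values()})
    ref_snp_genes = [g for g in snp_genes if g not in nonref_gene_ids]
    up_genes = set(nonref_cand[: config.n_deg_up_nonref])
    down_genes = {nonref_cand[2]} if config.n_deg_down_nonref > 0 else set()
    pool = [g for g in ref_snp_genes]
    need_up = config.n_deg_up - len(up_genes)
    need_down = config.n_deg_down - len(down_genes)
    need_contra = config.n_deg_contradictory
    if need_up + need_down + need_contra > len(pool):
        raise ValueError("infeasible config: not enough SNP-bearing genes for DEG plan")
    order = [str(g) for g in rng_deg.permutation(pool)]
    up_genes |= set(order[:need_up])
    down_genes |= set(order[need_up : need_up + need_down])
    contra_genes = set(order[need_up + need_down : need_up + need_down + need_contra])

    comparisons = [
        (ds, cmp) for ds in sorted(DATASET_COMPARISONS) for cmp in DATASET_COMPARISONS[ds]
    ]
    rows: list[dict] = []

    def sig_row(ds, cmp, gene, direction):
        lfc = float(rng_deg.uniform(1.5, 4.0)) * (1 if direction == "up" else -1)
        padj = float(10 ** -rng_deg.uniform(2, 6))
        rows.append(
            {"dataset": ds, "comparison": cmp, "gene": gene, "log2fc": round(lfc, 3), "padj": padj}
        )

    def null_row(ds, cmp, gene):
        rows.append(
            {
                "dataset": ds,
                "comparison": cmp,
                "gene": gene,
                "log2fc": round(float(rng_deg.normal(0, 0.3)), 3),
                "padj": float(rng_deg.uniform(0.1, 0.95)),
            }
        )

    for gene in sorted(up_genes | down_genes):
        direction = "up" if gene in up_genes else "down"
        n_support = int(rng_deg.integers(1, 4))
        chosen = [comparisons[int(i)] for i in rng_deg.choice(len(comparisons), n_support, replace=False)]
        for ds, cmp in chosen:
            sig_row(ds, cmp, gene, direction)
        others = [c for c in comparisons if c not in chosen]
        for ds, cmp in [others[int(i)] for i in rng_deg.choice(len(others), 2, replace=False)]:
            null_row(ds, cmp, gene)
    for gene in sorted(contra_genes):
        picks = [comparisons[int(i)] for i in rng_deg.choice(len(comparisons), 2, replace=False)]
        sig_row(*picks[0], gene, "up")
        sig_row(*picks[1], gene, "down")
    neutral_snp_genes = [
        g for g in snp_genes if g not in up_genes | down_genes | contra_genes
    ]
    for gene in neutral_snp_genes:
        for ds, cmp in [comparisons[int(i)] for i in rng_deg.choice(len(comparisons), 2, replace=False)]:
            null_row(ds, cmp, gene)
    non_snp_genes = [g for g in gene_ids if g not in set(snp_genes)]
    for ds, cmp in comparisons:
        picks = rng_deg.choice(
            len(non_snp_genes),
            min(config.deg_background_per_comparison, len(non_snp_genes)),
            replace=False,
        )
        for i in picks:
            gene = non_snp_genes[int(i)]
            if rng_deg.random() < 0.3:
                sig_row(ds, cmp, gene, "up" if rng_deg.random() < 0.5 else "down")
            else:
                null_row(ds, cmp, gene)
    # a sprinkle of NA padj rows (never significant)
    for ds, cmp in comparisons[:2]:
        gene = non_snp_genes[int(rng_deg.integers(0, len(non_snp_genes)))]
        rows.append(
            {"dataset": ds, "comparison": cmp, "gene": gene + "_na", "log2fc": 3.0, "padj": np.nan}
        )
    deg_table = pd.DataFrame(rows).drop_duplicates(
        subset=["dataset", "comparison", "gene"], keep="first"
    )

    # --- QTL markers -------------------------------------------------------
    sorted_up = sorted(up_genes)
    sorted_down = sorted(down_genes)
    ref_up = [g for g in sorted_up if g not in nonref_gene_ids]
    anchors: list[str] = []
    anchors.extend(ref_up[:1])
    anchors.extend(ref_up[:1])  # second QTL overlapping the first
    anchors.extend(g for g in sorted_up if g in nonref_gene_ids)
    anchors.extend(sorted_down[:1])
    anchors.extend(ref_up[1:2])
    anchors.extend(neutral_snp_genes[:1])
    anchors = anchors[: config.n_qtl]
    if not anchors:
        raise ValueError("infeasible config: no QTL anchors")

    def unique_kmer(cname: str, start: int, k: int = 20) -> str:
        s = seqs[cname]
        for klen in (k, 30, 40):
            sub = s[start - 1 : start - 1 + klen]
            if len(sub) < klen:
                continue
            n_hits = sum(seq_.count(sub) + seq_.count(revcomp(sub)) for seq_ in seqs.values())
            if n_hits == 1:
                return sub
        raise ValueError("could not find a unique marker k-mer")

    marker_rows = []
    raw_intervals: list[tuple[str, int, int]] = []
    for qi, gene in enumerate(anchors, start=1):
        m = model_by_id[gene]
        clen = len(seqs[m.contig])
        if qi == 2:  # overlap partner of QTL 1
            start = max(1, m.start + config.qtl_span // 2)
            end = min(clen, start + config.qtl_span)
        else:
            start = max(1, m.start - 1000)
            end = min(clen, start + config.qtl_span)
        left = unique_kmer(m.contig, start)
        right_start = end - 20 + 1
        right = unique_kmer(m.contig, right_start)
        end = right_start + len(right) - 1
        marker_rows.append(
            {"qtl_id": f"qtl{qi:02d}", "marker_id": f"qtl{qi:02d}_L", "sequence": left}
        )
        marker_rows.append(
            {"qtl_id": f"qtl{qi:02d}", "marker_id": f"qtl{qi:02d}_R", "sequence": right}
        )
        raw_intervals.append((m.contig, start, end))
    # one marker that will not place and one decoy QTL far from genes
    marker_rows.append(
        {"qtl_id": "qtl_unplaced", "marker_id": "qtl_unplaced_M", "sequence": "ACGT" * 6}
    )
    marker_table = pd.DataFrame(marker_rows)

    qtl_member_genes = {
        m.gene_id
        for m in models
        for (cname, s, e) in raw_intervals
        if m.contig == cname and m.start <= e and s <= m.end
    }

    expected = {
        "up": up_genes & qtl_member_genes,
        "down": down_genes & qtl_member_genes,
    }

    truth = GroundTruth(
        presence_truth=presence_truth,
        group_specific_snps=planted,
        deg_truth={"up": up_genes, "down": down_genes, "contradictory": contra_genes},
        qtl_member_genes=qtl_member_genes,
        expected_candidates=expected,
        snp_genes=set(snp_genes),
        nonref_genes=nonref_gene_ids,
        excluded_accessions=excluded,
    )

    # --- write files -------------------------------------------------------
    paths = {
        "genome": out / "genome.fa",
        "gff3": out / "genes.gff3",
        "vcf": out / "variants.vcf",
        "meta": out / "metadata.tsv",
        "deg": out / "deg.tsv",
        "markers": out / "markers.tsv",
        "truth": out / "ground_truth.json",
        "presence": out / "presence_truth.tsv",
        "coverage_dir": out / "coverage",
    }
    iof.write_fasta(genome, paths["genome"])
    iof.write_gff3(models, paths["gff3"])
    iof.write_vcf(
        variants,
        accessions,
        paths["vcf"],
        contig_lengths={c.name: len(c.sequence) for c in genome},
    )
    iof.write_metadata(meta, paths["meta"])
    deg_table.to_csv(paths["deg"], sep="\t", index=False, na_rep="NA")
    marker_table.to_csv(paths["markers"], sep="\t", index=False)
    presence_truth.to_frame().to_csv(paths["presence"], sep="\t")
    paths["truth"].write_text(truth.to_json())
    for acc in accessions:
        iof.write_coverage(coverage[acc], paths["coverage_dir"] / f"{acc}.tsv")

    return SimOutput(
        genome=genome,
        models=models,
        meta=meta,
        variants=variants,
        accessions=accessions,
        coverage=coverage,
        deg_table=deg_table,
        marker_table=marker_table,
        truth=truth,
        paths=paths,
    )
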