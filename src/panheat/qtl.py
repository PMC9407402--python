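"""QTL marker placement, interval construction/merging, and candidate
gene reporting.

Markers are located by exact substring search on both strands of the toy
genome; each QTL's interval spans its outermost placed markers; overlapping
intervals on a contig are merged (their QTL ids concatenated).  Candidate
genes from the DEG/SNP integration are finally restricted to genes whose
span overlaps a QTL interval by at least one base.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from intervaltree import IntervalTree

from .deg import CandidateSets
from .io_formats import ContigSet, GeneModel, GenomicInterval
from .variants import revcomp


@dataclass
class Marker:
    marker_id: str
    qtl_id: str
    sequence: str | None = None
    contig: str | None = None
    pos: int | None = None  # 1-based start of the placement
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is None and (self.contig is None or self.pos is None):
            raise ValueError(
                f"marker {self.marker_id}: need a sequence or a placement"
            )

    @property
    def placed(self) -> bool:
        return self.contig is not None and self.pos is not None


@dataclass
class QtlInterval:
    qtl_ids: tuple[str, ...]
    interval: GenomicInterval


@dataclass
class PlacementLog:
    placed: list[Marker] = field(default_factory=list)
    unplaced: list[str] = field(default_factory=list)
    ambiguous: list[str] = field(default_factory=list)


def markers_from_frame(df: pd.DataFrame) -> list[Marker]:
    out = []
    for row in df.itertuples(index=False):
        seq = getattr(row, "sequence", None)
        seq = None if seq is None or pd.isna(seq) else str(seq).upper()
        contig = getattr(row, "contig", None)
        contig = None if contig is None or pd.isna(contig) else str(contig)
        pos = getattr(row, "pos", None)
        pos = None if pos is None or pd.isna(pos) else int(pos)
        end = pos + len(seq) - 1 if (pos is not None and seq) else pos
        out.append(
            Marker(
                marker_id=str(row.marker_id),
                qtl_id=str(row.qtl_id),
                sequence=seq,
                contig=contig,
                pos=pos,
                end=end,
            )
        )
    return out


def place_markers(
    markers: list[Marker],
    genome: ContigSet,
    keep_ambiguous: bool = False,
    min_len: int = 15,
) -> tuple[list[Marker], PlacementLog]:
    """Place sequence markers by exact match on forward and reverse strands.

    A unique hit yields forward-strand coordinates; zero hits leaves the
    marker unplaced; several hits mark it ambiguous (excluded unless
    ``keep_ambiguous`` keeps the first by contig order then position).
    Markers that already carry coordinates pass through untouched.
    """
    log = PlacementLog()
    order = {c.name: i for i, c in enumerate(genome)}
    for m in markers:
        if m.placed:
            log.placed.append(m)
            continue
        assert m.sequence is not None
        if len(m.sequence) < min_len:
            raise ValueError(
                f"marker {m.marker_id}: sequence shorter than {min_len} bp"
            )
        hits: list[tuple[str, int, str]] = []
        rc = revcomp(m.sequence)
        for contig in genome:
            for query, strand in ((m.sequence, "+"), (rc, "-")):
                start = contig.sequence.find(query)
                while start != -1:
                    hits.append((contig.name, start + 1, strand))
                    start = contig.sequence.find(query, start + 1)
        hits.sort(key=lambda h: (order[h[0]], h[1]))
        if not hits:
            log.unplaced.append(m.marker_id)
            continue
        if len(hits) > 1:
            log.ambiguous.append(m.marker_id)
            if not keep_ambiguous:
                continue
        name, start, strand = hits[0]
        m.contig, m.pos, m.strand = name, start, strand
        m.end = start + len(m.sequence) - 1
        log.placed.append(m)
    return log.placed, log


def build_intervals(
    placed: list[Marker],
    merge: bool = True,
    expected_qtls: set[str] | None = None,
) -> list[QtlInterval]:
    """One interval per QTL spanning its outermost markers; optionally merge
    overlapping intervals on a contig (union, ids concatenated).

    When ``expected_qtls`` is given, a QTL from that set with no placed
    marker raises.
    """
    by_qtl: dict[str, list[Marker]] = {}
    for m in placed:
        by_qtl.setdefault(m.qtl_id, []).append(m)
    if expected_qtls is not None:
        lost = expected_qtls - set(by_qtl)
        if lost:
            raise ValueError(f"QTL(s) with all markers unplaced: {sorted(lost)}")
    raw: list[QtlInterval] = []
    for qtl_id, ms in sorted(by_qtl.items()):
        contigs = {m.contig for m in ms}
        if len(contigs) > 1:
            raise ValueError(
                f"QTL {qtl_id}: markers on several contigs {sorted(contigs)}"
            )
        start = min(m.pos for m in ms)
        end = max(m.end or m.pos for m in ms)
        raw.append(
            QtlInterval((qtl_id,), GenomicInterval(next(iter(contigs)), start, end))
        )
    if not merge:
        return sorted(raw, key=lambda q: (q.interval.contig, q.interval.start))
    merged: list[QtlInterval] = []
    by_contig: dict[str, list[QtlInterval]] = {}
    for q in raw:
        by_contig.setdefault(q.interval.contig, []).append(q)
    for contig in sorted(by_contig):
        items = sorted(by_contig[contig], key=lambda q: q.interval.start)
        cur_ids = list(items[0].qtl_ids)
        cur_s, cur_e = items[0].interval.start, items[0].interval.end
        for q in items[1:]:
            if q.interval.start <= cur_e:  # 1-based inclusive overlap
                cur_e = max(cur_e, q.interval.end)
                cur_ids.extend(q.qtl_ids)
            else:
                merged.append(
                    QtlInterval(tuple(cur_ids), GenomicInterval(contig, cur_s, cur_e))
                )
                cur_ids = list(q.qtl_ids)
                cur_s, cur_e = q.interval.start, q.interval.end
        merged.append(
            QtlInterval(tuple(cur_ids), GenomicInterval(contig, cur_s, cur_e))
        )
    return merged


def genes_in_qtls(
    models: list[GeneModel], intervals: list[QtlInterval]
) -> tuple[dict[tuple[str, ...], list[str]], dict[str, list[tuple[str, ...]]]]:
    """Overlap gene spans with QTL intervals (>= 1 bp of the span).

    Returns per-interval gene lists and per-gene interval lists, both keyed
    deterministically.
    """
    trees: dict[str, IntervalTree] = {}
    for q in intervals:
        trees.setdefault(q.interval.contig, IntervalTree()).addi(
            q.interval.start, q.interval.end + 1, q.qtl_ids
        )
    per_interval: dict[tuple[str, ...], list[str]] = {
        q.qtl_ids: [] for q in intervals
    }
    per_gene: dict[str, list[tuple[str, ...]]] = {}
    for gene in models:
        tree = trees.get(gene.contig)
        if tree is None:
            continue
        for iv in sorted(tree.overlap(gene.start, gene.end + 1)):
            per_interval[iv.data].append(gene.gene_id)
            per_gene.setdefault(gene.gene_id, []).append(iv.data)
    for ids in per_interval:
        per_interval[ids].sort()
    return per_interval, per_gene


@dataclass
class CandidateReport:
    up: set[str]
    down: set[str]
    up_nonref: set[str]
    down_nonref: set[str]

    @property
    def total(self) -> int:
        return len(self.up) + len(self.down)

    @property
    def total_nonref(self) -> int:
        return len(self.up_nonref) + len(self.down_nonref)

    def counts(self) -> dict[str, int]:
        return {
            "up": len(self.up),
            "down": len(self.down),
            "total": self.total,
            "up_nonref": len(self.up_nonref),
            "down_nonref": len(self.down_nonref),
            "total_nonref": self.total_nonref,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"gene": g, "direction": "up", "non_reference": g in self.up_nonref}
            for g in sorted(self.up)
        ] + [
            {"gene": g, "direction": "down", "non_reference": g in self.down_nonref}
            for g in sorted(self.down)
        ]
        return pd.DataFrame(rows, columns=["gene", "direction", "non_reference"])


def final_candidates(
    candidates: CandidateSets,
    per_gene: dict[str, list[tuple[str, ...]]],
) -> CandidateReport:
    """Restrict DEG/SNP candidates to QTL residents."""
    resident = set(per_gene)
    up = candidates.up & resident
    down = candidates.down & resident
    return CandidateReport(
        up=up,
        down=down,
        up_nonref=up & candidates.up_nonref,
        down_nonref=down & candidates.down_nonref,
    )


def candidate_counts(up: set[str] | int, down: set[str] | int) -> dict[str, int]:
    """Up/down/total summation used by candidate reporting.

    Accepts sets or plain counts so externally tabulated figures go through
    the same arithmetic.
    """
    n_up = up if isinstance(up, int) else len(up)
    n_down = down if isinstance(down, int) else len(down)
    return {"up": n_up, "down": n_down, "total": n_up + n_down}
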