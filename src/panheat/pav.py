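"""Gene presence/absence variation (PAV) analysis.

A gene is called *present* in an accession when more than 80% of its gene
body is covered by at least ``min_cov`` reads (defaults ``min_cov=5``,
``lost_cutoff=0.2``), the SGSgeneloss criterion.  On top of the resulting
genes x accessions boolean matrix this module classifies core vs variable
genes, finds group-unique genes, models pan/core growth curves over
accession subsets, and clusters accessions by Jaccard similarity with a
neighbor-joining tree.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io_formats import AccessionMeta, GeneModel


@dataclass
class PavParams:
    """Thresholds for presence calling.

    min_cov: minimum per-base read depth for a base to count as covered.
    lost_cutoff: a gene is absent when the uncovered fraction of its body
        is at least this value (present iff covered fraction > 1 - cutoff).
    min_depth_accession: accessions at or below this sequencing depth are
        excluded from the matrix.
    gene_body: "exons" restricts the body to exonic bases (SGSgeneloss
        semantics); "span" uses the full genomic span.
    """

    min_cov: int = 5
    lost_cutoff: float = 0.2
    min_depth_accession: float = 10.0
    gene_body: str = "exons"

    def __post_init__(self) -> None:
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if not (0 < self.lost_cutoff < 1):
            raise ValueError("lost_cutoff must be in (0, 1)")
        if self.gene_body not in ("exons", "span"):
            raise ValueError("gene_body must be 'exons' or 'span'")


@dataclass
class PresenceMatrix:
    """Boolean genes x accessions PAV table."""

    genes: list[str]
    accessions: list[str]
    values: np.ndarray  # bool, shape (n_genes, n_accessions)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accession ids")
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != (len(self.genes), len(self.accessions)):
            raise ValueError("matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.astype(int), index=self.genes, columns=self.accessions
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PresenceMatrix":
        return cls(
            genes=[str(g) for g in df.index],
            accessions=[str(a) for a in df.columns],
            values=df.to_numpy(dtype=bool),
        )

    def subset_accessions(self, names: list[str]) -> "PresenceMatrix":
        idx = [self.accessions.index(n) for n in names]
        return PresenceMatrix(self.genes, list(names), self.values[:, idx])


def gene_body_positions(gene: GeneModel, params: PavParams) -> list[int]:
    if params.gene_body == "exons" and gene.exons:
        return gene.exon_positions()
    return list(range(gene.start, gene.end + 1))


def call_presence(
    gene: GeneModel,
    coverage: dict[str, list[tuple[int, int, int]]],
    params: PavParams | None = None,
) -> bool:
    """Present iff > (1 - lost_cutoff) of the gene body has depth >= min_cov.

    ``coverage`` maps contig -> (start, end, depth) runs, 1-based inclusive;
    positions absent from the runs have depth 0.
    """
    params = params or PavParams()
    body = gene_body_positions(gene, params)
    if not body:
        raise ValueError(f"empty gene body for {gene.gene_id}")
    runs = coverage.get(gene.contig, [])
    covered = 0
    body_set = sorted(body)
    lo, hi = body_set[0], body_set[-1]
    depth = np.zeros(hi - lo + 1, dtype=np.int32)
    for s, e, d in runs:
        if e < lo or s > hi:
            continue
        depth[max(s, lo) - lo : min(e, hi) - lo + 1] = np.maximum(
            depth[max(s, lo) - lo : min(e, hi) - lo + 1], d
        )
    covered = int(sum(depth[p - lo] >= params.min_cov for p in body_set))
    return covered / len(body_set) > 1.0 - params.lost_cutoff


def build_matrix(
    models: list[GeneModel],
    coverage_by_accession: dict[str, dict[str, list[tuple[int, int, int]]]],
    meta: list[AccessionMeta],
    params: PavParams | None = None,
) -> tuple[PresenceMatrix, list[tuple[str, str]]]:
    """Call presence for every gene in every sufficiently deep accession.

    Returns the matrix over retained accessions plus an exclusion list of
    ``(accession, reason)`` pairs for those dropped by the depth filter.
    """
    params = params or PavParams()
    excluded: list[tuple[str, str]] = []
    retained: list[str] = []
    for m in meta:
        if m.accession not in coverage_by_accession:
            excluded.append((m.accession, "no coverage track"))
        elif m.depth is not None and m.depth <= params.min_depth_accession:
            excluded.append(
                (m.accession, f"depth {m.depth}x <= {params.min_depth_accession}x")
            )
        else:
            retained.append(m.accession)
    if not retained:
        raise ValueError("no accession passes the depth filter")
    values = np.zeros((len(models), len(retained)), dtype=bool)
    for j, acc in enumerate(retained):
        cov = coverage_by_accession[acc]
        for i, gene in enumerate(models):
            values[i, j] = call_presence(gene, cov, params)
    matrix = PresenceMatrix([m.gene_id for m in models], retained, values)
    return matrix, excluded


def classify_genes(
    matrix: PresenceMatrix,
) -> tuple[set[str], set[str], dict[str, str]]:
    """Partition genes into core (present everywhere) and variable.

    Also returns the *private* map: variable genes present in exactly one
    accession, mapped to that accession.
    """
    if not matrix.genes:
        raise ValueError("empty matrix")
    counts = matrix.values.sum(axis=1)
    n = len(matrix.accessions)
    core = {g for g, c in zip(matrix.genes, counts) if c == n}
    variable = {g for g, c in zip(matrix.genes, counts) if c < n}
    private = {
        matrix.genes[i]: matrix.accessions[int(np.flatnonzero(matrix.values[i])[0])]
        for i in range(len(matrix.genes))
        if counts[i] == 1
    }
    return core, variable, private


def classification_summary(n_core: int, n_variable: int) -> dict[str, float]:
    """Pan-genome composition summary: totals and percentages.

    The percentage code path used for reporting core/variable fractions of
    the pan-gene set (values rounded to 2 decimals, as percentages).
    """
    total = n_core + n_variable
    if total == 0:
        raise ValueError("empty pan-genome")
    return {
        "pan_total": float(total),
        "core_pct": round(100.0 * n_core / total, 2),
        "variable_pct": round(100.0 * n_variable / total, 2),
    }


def group_unique_genes(
    matrix: PresenceMatrix,
    meta: list[AccessionMeta],
    group: set[str],
) -> set[str]:
    """Genes present in >=1 accession of ``group`` (a set of heat classes)
    and in no accession outside it."""
    if not group:
        raise ValueError("empty group")
    by_acc = {m.accession: m.heat_class for m in meta}
    in_group = np.array(
        [by_acc.get(a) in group for a in matrix.accessions], dtype=bool
    )
    if not in_group.any():
        raise ValueError(f"group {sorted(group)} selects no accessions")
    vals = matrix.values
    hit = vals[:, in_group].any(axis=1) & ~vals[:, ~in_group].any(axis=1)
    return {g for g, h in zip(matrix.genes, hit) if h}


# ---------------------------------------------------------------------------
# pan/core growth curves
# ---------------------------------------------------------------------------

@dataclass
class GrowthCurve:
    sample_sizes: list[int]
    pan_mean: list[float]
    core_mean: list[float]
    n_samples: list[int]
    fit_pan: tuple[float, float, float] | None = None
    fit_core: tuple[float, float, float] | None = None
    fit_ok: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n": self.sample_sizes,
                "pan_mean": self.pan_mean,
                "core_mean": self.core_mean,
                "n_samples": self.n_samples,
            }
        )


def _pan_model(n, a, b, c):
    return a * np.power(n, b) + c


def _core_model(n, a, b, c):
    return a * np.exp(b * n) + c


def growth_curve(
    matrix: PresenceMatrix,
    n_samples_per_size: int = 500,
    seed: int = 0,
    fit: bool = True,
) -> GrowthCurve:
    """Mean pan (union) and core (intersection) gene counts per sample size.

    For each subset size k of the N accessions all C(N, k) combinations are
    evaluated when their number does not exceed ``n_samples_per_size``;
    otherwise that many distinct combinations are drawn uniformly without
    replacement (seeded).  Pan growth is fitted as A*n^B + C (power law) and
    core decay as A*exp(B*n) + C, the standard pan-genome model forms.
    """
    if n_samples_per_size < 1:
        raise ValueError("n_samples_per_size must be >= 1")
    rng = np.random.default_rng(seed)
    vals = matrix.values
    n_acc = len(matrix.accessions)
    sizes, pan_mean, core_mean, n_used = [], [], [], []
    for k in range(1, n_acc + 1):
        n_comb = math.comb(n_acc, k)
        if n_comb <= n_samples_per_size:
            combos = list(itertools.combinations(range(n_acc), k))
        else:
            seen: set[tuple[int, ...]] = set()
            while len(seen) < n_samples_per_size:
                seen.add(tuple(sorted(rng.choice(n_acc, size=k, replace=False))))
            combos = sorted(seen)
        pans, cores = [], []
        for combo in combos:
            sub = vals[:, list(combo)]
            pans.append(int(sub.any(axis=1).sum()))
            cores.append(int(sub.all(axis=1).sum()))
        sizes.append(k)
        pan_mean.append(float(np.mean(pans)))
        core_mean.append(float(np.mean(cores)))
        n_used.append(len(combos))
    curve = GrowthCurve(sizes, pan_mean, core_mean, n_used)
    if fit and n_acc >= 3:
        g = float(vals.any(axis=1).sum())
        try:
            p_pan, _ = curve_fit(
                _pan_model, sizes, pan_mean, p0=(g, 0.5, 0.0), maxfev=20000
            )
            p_core, _ = curve_fit(
                _core_model, sizes, core_mean, p0=(g, -0.5, 0.0), maxfev=20000
            )
            curve.fit_pan = tuple(float(x) for x in p_pan)
            curve.fit_core = tuple(float(x) for x in p_core)
        except (RuntimeError, ValueError):
            curve.fit_ok = False
    return curve


def plot_growth(curve: GrowthCurve, path: str) -> None:
    """Plot mean pan/core gene counts against sample size."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(curve.sample_sizes, curve.pan_mean, "o-", label="pan-genome")
    ax.plot(curve.sample_sizes, curve.core_mean, "s-", label="core genome")
    ax.set_xlabel("number of accessions")
    ax.set_ylabel("mean gene count")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Jaccard similarity and neighbor-joining tree
# ---------------------------------------------------------------------------

def jaccard_matrix(matrix: PresenceMatrix) -> pd.DataFrame:
    """Pairwise Jaccard similarity of accessions' present-gene sets.

    J(a, b) = |both| / |either|; an all-absent accession has J = 0 against
    any non-empty one and J = 1 against itself.
    """
    if len(matrix.accessions) < 2:
        raise ValueError("need >= 2 accessions")
    v = matrix.values.astype(np.int64)
    inter = v.T @ v
    sizes = v.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(jac, 1.0)
    return pd.DataFrame(jac, index=matrix.accessions, columns=matrix.accessions)


def nj_tree(distances: pd.DataFrame, labels: list[str] | None = None) -> str:
    """Neighbor-joining (Saitou-Nei) tree from a distance matrix, as Newick.

    Negative branch lengths are clamped to zero.  Requires >= 3 taxa.
    """
    from skbio import DistanceMatrix
    from skbio.tree import nj

    labels = labels or [str(c) for c in distances.columns]
    if len(labels) < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    dm = DistanceMatrix(np.asarray(distances, dtype=float), ids=labels)
    tree = nj(dm)
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            node.length = 0.0
    return str(tree).strip()
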