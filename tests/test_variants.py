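"""Annotator and filter tests against hand-computed and naive oracles."""

import numpy as np
import pytest
from Bio.Seq import Seq

from panheat.io_formats import VariantRecord
from panheat.variants import (
    AnnotParams,
    DEFAULT_IMPACT_MAP,
    FilterParams,
    annotate,
    filter_variants,
    impact_of,
    severity_rank,
    snp_distance_matrix,
    tally_by_category,
)

from conftest import TOY_EXPECTATIONS, make_toy, mirror_variant


def _variant(pos, ref, alt, genotypes=None, contig="toy1"):
    return VariantRecord(contig, pos, ref, (alt,), genotypes or [(0, 1)])


def _toy_variants(genome, positions):
    seq = genome.get("toy1").sequence
    return [_variant(pos, seq[pos - 1], alt) for pos, alt in positions]


class TestAnnotator:
    @pytest.mark.parametrize("pos,alt", sorted(TOY_EXPECTATIONS))
    def test_plus_strand_categories(self, pos, alt):
        genome, model = make_toy("+")
        (v,) = _toy_variants(genome, [(pos, alt)])
        _, summary = annotate([v], [model], genome)
        assert summary[v.key].category == TOY_EXPECTATIONS[(pos, alt)]

    @pytest.mark.parametrize("pos,alt", sorted(TOY_EXPECTATIONS))
    def test_strand_symmetry(self, pos, alt):
        """Reverse-complementing gene, genome and variant together leaves
        the category unchanged."""
        genome_m, model_m = make_toy("-")
        mpos, malt = mirror_variant(pos, alt)
        seq = genome_m.get("toy1").sequence
        v = _variant(mpos, seq[mpos - 1], malt)
        _, summary = annotate([v], [model_m], genome_m)
        assert summary[v.key].category == TOY_EXPECTATIONS[(pos, alt)]

    def test_aa_change_reported(self):
        genome, model = make_toy("+")
        (v,) = _toy_variants(genome, [(16, "C")])  # AAA -> ACA, K2T
        records, _ = annotate([v], [model], genome)
        (rec,) = [r for r in records if r.gene_id == "toy"]
        assert rec.aa_change == "p.K2T"

    def test_intergenic_beyond_flank(self):
        genome, model = make_toy("+")
        (v,) = _toy_variants(genome, [(60, "A")])
        _, summary = annotate([v], [model], genome, AnnotParams(flank_bp=10))
        assert summary[v.key].category == "intergenic"
        assert summary[v.key].gene_id is None

    def test_variant_beyond_contig_end_raises(self):
        genome, model = make_toy("+")
        v = _variant(999, "A", "G")
        with pytest.raises(ValueError, match="beyond contig end"):
            annotate([v], [model], genome)

    def test_summary_is_max_severity_across_genes(self):
        """Brute-force check: the per-variant summary always equals the
        min-rank record over all its per-gene records."""
        genome, model = make_toy("+")
        variants = _toy_variants(genome, sorted(TOY_EXPECTATIONS))
        records, summary = annotate(variants, [model], genome)
        by_key = {}
        for r in records:
            by_key.setdefault(r.variant_key, []).append(r)
        for key, recs in by_key.items():
            best = min(severity_rank(r.category) for r in recs)
            assert severity_rank(summary[key].category) == best

    def test_noncoding_model_exonic_category(self):
        genome, model = make_toy("+")
        model.cds, model.utr5, model.utr3 = [], [], []
        (v,) = _toy_variants(genome, [(16, "C")])
        _, summary = annotate([v], [model], genome)
        assert summary[v.key].category == "exonic"


class TestCodingOracle:
    """Coding calls must agree with a naive whole-CDS rebuild-and-translate
    oracle on every planted coding SNP of the simulated study, both strands."""

    @staticmethod
    def _oracle(gene, seq, pos, alt):
        order = [p for s, e in gene.cds for p in range(s, e + 1)]
        if gene.strand == "-":
            order = order[::-1]
        idx = order.index(pos)
        alt_seq = seq[: pos - 1] + alt + seq[pos:]
        ref_cds = "".join(seq[p - 1] for p in order)
        alt_cds = "".join(alt_seq[p - 1] for p in order)
        if gene.strand == "-":
            # positions are already in coding order; complement each base
            comp = str.maketrans("ACGT", "TGCA")
            ref_cds = ref_cds.translate(comp)
            alt_cds = alt_cds.translate(comp)
        ref_p = str(Seq(ref_cds).translate())
        alt_p = str(Seq(alt_cds).translate())
        if idx < 3:
            return "start_lost" if alt_cds[:3] != "ATG" else "synonymous"
        ref_stop = ref_p.find("*")
        alt_stop = alt_p.find("*")
        if ref_stop != -1 and alt_stop == -1:
            return "stop_lost"
        if alt_stop != -1 and (ref_stop == -1 or alt_stop < ref_stop):
            return "stop_gained"
        if ref_p == alt_p:
            return "synonymous"
        return "missense"

    CODING = {"missense", "synonymous", "stop_gained", "stop_lost", "start_lost"}

    def test_planted_coding_snps_agree(self, sim_study, sim_result):
        seqs = {c.name: c.sequence for c in sim_study.genome}
        models = {m.gene_id: m for m in sim_study.models}
        checked = {"+": 0, "-": 0}
        for key, (category, gene_id) in sim_study.truth.group_specific_snps.items():
            if category not in self.CODING:
                continue
            contig, pos, _ref, alt = key
            gene = models[gene_id]
            expected = self._oracle(gene, seqs[contig], pos, alt)
            assert sim_result.summary[key].category == expected == category
            checked[gene.strand] += 1
        assert checked["+"] > 0 and checked["-"] > 0


class TestFilter:
    def _het_one(self, n=10):
        gts = [(0, 1)] + [(0, 0)] * (n - 1)
        return VariantRecord("c1", 1, "A", ("G",), gts)

    def test_maf_boundary_kept(self):
        # 1 het in 10 diploids: MAF exactly 0.05 -> kept ("less than" removed)
        kept, _ = filter_variants([self._het_one()])
        assert len(kept) == 1

    def test_missingness_removed(self):
        gts = [(None, None)] * 8 + [(0, 1), (1, 1)]
        v = VariantRecord("c1", 1, "A", ("G",), gts)
        kept, removed = filter_variants([v])
        assert not kept and "missing" in removed[0][1]

    def test_multiallelic_removed(self):
        v = VariantRecord("c1", 1, "A", ("G", "T"), [(1, 2)] * 5)
        kept, removed = filter_variants([v])
        assert not kept and "biallelic" in removed[0][1]

    def test_agrees_with_exhaustive_predicate(self, sim_study):
        """Per-record brute-force predicate equals the implementation."""
        params = FilterParams()
        kept, _ = filter_variants(sim_study.variants, params)
        kept_keys = {v.key for v in kept}
        for v in sim_study.variants:
            gts = v.genotypes
            biallelic = (
                len(v.alts) == 1 and len(v.ref) == 1 and len(v.alts[0]) == 1
            )
            n_miss = sum(1 for a, b in gts if a is None and b is None)
            alleles = [x for a, b in gts for x in (a, b) if x is not None]
            p = sum(1 for x in alleles if x == 1) / len(alleles) if alleles else 0
            expect = (
                biallelic
                and n_miss / len(gts) < params.max_missing_fraction
                and min(p, 1 - p) >= params.maf_min
            )
            assert (v.key in kept_keys) == expect


class TestImpact:
    @pytest.mark.parametrize(
        "category,impact",
        [
            ("splice_acceptor", "HIGH"), ("splice_donor", "HIGH"),
            ("start_lost", "HIGH"), ("stop_gained", "HIGH"),
            ("missense", "MODERATE"), ("synonymous", "LOW"),
            ("stop_lost", "LOW"), ("start_gained", "LOW"),
            ("upstream", "MODIFIER"), ("intergenic", "MODIFIER"),
        ],
    )
    def test_default_map(self, category, impact):
        assert impact_of(category) == impact

    def test_unknown_category(self):
        with pytest.raises(KeyError):
            impact_of("frameshift")

    def test_map_is_total_over_taxonomy(self):
        from panheat.variants import CATEGORIES

        assert set(DEFAULT_IMPACT_MAP) == set(CATEGORIES)


class TestSnpDistance:
    def test_examples(self):
        v1 = VariantRecord("c", 1, "A", ("G",), [(0, 0), (0, 0), (1, 1)])
        v2 = VariantRecord("c", 2, "A", ("G",), [(0, 1), (1, 1), (0, 0)])
        d = snp_distance_matrix([v1, v2], ["a", "b", "c"])
        assert d.loc["a", "a"] == 0
        assert d.loc["a", "b"] == pytest.approx(0.25)  # sites: 0 and 0.5
        assert d.loc["a", "c"] == pytest.approx(0.75)  # 1.0 and 0.5

    def test_opposite_homozygotes(self):
        vs = [
            VariantRecord("c", i, "A", ("G",), [(0, 0), (1, 1)]) for i in range(3)
        ]
        d = snp_distance_matrix(vs, ["a", "b"])
        assert d.loc["a", "b"] == 1.0

    def test_no_cocalled_sites_maximal_with_warning(self):
        v = VariantRecord("c", 1, "A", ("G",), [(0, 0), (None, None)])
        with pytest.warns(UserWarning, match="no co-called"):
            d = snp_distance_matrix([v], ["a", "b"])
        assert d.loc["a", "b"] == 1.0


def test_tally_counts_and_total():
    genome, model = make_toy("+")
    variants = _toy_variants(genome, [(16, "C"), (3, "C"), (45, "C"), (37, "A")])
    records, _ = annotate(variants, [model], genome)
    table = tally_by_category(records, genome)
    by_cat = dict(zip(table.category, table["count"]))
    assert by_cat["missense"] == 1 and by_cat["upstream"] == 1
    assert by_cat["total"] == len(records)
    assert (table["reference"] + table["non_reference"] == table["count"]).all()
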