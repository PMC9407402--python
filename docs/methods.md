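# Methods

## Scope and model

`panheat` re-implements, at desk scale, an evidence-integration pipeline
for heat-tolerance candidate genes in rice built on a pan-genome (single
reference genome plus non-reference contigs assembled from unmapped
reads). The pipeline does not perform read alignment, assembly, variant
calling or expression quantification — it consumes their standard outputs
(coverage tracks, VCF, DEG tables) and implements everything downstream:
PAV calling, pan-genome modelling, SNP filtering and consequence
annotation, group-specific allele selection, cross-dataset DEG consensus,
and QTL interval mapping.

## Coordinate conventions

All in-memory coordinates are 1-based inclusive (GFF3/VCF native). The
BEDGraph-like coverage dialect read and written here is *declared* 1-based
inclusive, so no conversion exists anywhere in the package; this removes
the classic off-by-one class of bugs at the cost of a one-line departure
from UCSC BEDGraph (documented in the reader's docstring).

## Heat-response classes

Spikelet fertility f (%) after heat exposure maps to five classes:
HT (f > 65), T (50 < f ≤ 65), MT (35 < f ≤ 50), S (15 < f ≤ 35),
HS (f ≤ 15). The published class ranges touch at 50/35/15; the half-open
upward convention was chosen so the partition of [0, 100] is exhaustive
and mutually exclusive, and metadata with both fertility and class is
validated against it.

## PAV calling

A gene is present in an accession iff
`#(body bases with depth ≥ min_cov) / body length > 1 − lost_cutoff`
with `min_cov = 5`, `lost_cutoff = 0.2` (the SGSgeneloss criterion; the
inequality is strict, so exactly 80% covered is absent). The gene body
defaults to exonic bases — the semantics of coverage-based gene-loss
callers — and can be switched to the full genomic span
(`PavParams.gene_body`). Accessions with sequencing depth ≤ 10× are
excluded from the matrix with a logged reason.

Core genes are rows that are all-present; variable genes are the
complement; private genes are present in exactly one accession. Pan/core
growth curves evaluate, for each subset size k, either *all* C(N, k)
accession combinations (when that count is at most the sampling cap,
default 500 — exhaustive and exact at toy scale) or that many distinct
combinations drawn uniformly without replacement from a seeded generator.
Pan growth is fitted by nonlinear least squares to the power law
`A·n^B + C` and core decay to `A·e^{B·n} + C` (the standard pan-genome
model family), initialised at `A = G, B = ±0.5, C = 0`; a non-converging
fit is flagged rather than raised.

Accession clustering uses the Jaccard similarity of present-gene sets
(an accession with no present genes has similarity 0 to any non-empty
set) and neighbor joining (Saitou–Nei, via scikit-bio) on `1 − J`;
negative NJ branch lengths are clamped to zero. The same NJ routine
serves the SNP tree, fed by an allele-sharing distance: at each co-called
site a pair with alt dosages d₁, d₂ shares `1 − |d₁ − d₂|/2` of its
alleles, and the distance is one minus the mean over co-called sites
(pairs with no co-called site get the maximal distance 1 with a warning).

## SNP filtering and consequence annotation

A record is kept iff it is a biallelic single-base SNP, its fraction of
missing genotypes is < 0.8, and its minor allele frequency over *called*
alleles only (vcftools semantics) is ≥ 0.05 — both thresholds sit exactly
on the published filter wording ("missing in at least 80%", "MAF of less
than 0.05"), so MAF = 0.05 survives and 80% missing does not.

The annotator assigns one category per variant–gene pair by position:

- inside the CDS: the alternate codon is rebuilt strand-aware (reverse
  complement on minus-strand genes) and both codons translated under the
  standard genetic code — `start_lost` (first codon no longer ATG),
  `stop_gained` (non-stop codon becomes stop), `stop_lost` (terminal stop
  becomes sense), otherwise `synonymous`/`missense`;
- in the spliced 5′UTR: `start_gained` when the alternate allele creates
  an ATG on the coding strand in a window overlapping the variant,
  otherwise `utr5`; `utr3` symmetric; `exonic` for exons of non-coding
  models (CDS-less models can only receive non-coding categories);
- in an intron: `splice_donor`/`splice_acceptor` within 2 intronic bases
  of the transcription-direction exon boundaries (the GT/AG dinucleotides;
  no broader "splice region" category), else `intronic`;
- within 2 kb of the gene span: `upstream` on the 5′ side, `downstream`
  on the 3′ side, strand-aware and measured from the span ends;
- otherwise `intergenic`.

A variant in reach of several genes yields one record per gene; the
per-variant summary is the most severe record under the fixed severity
order, ties broken by distance to the gene and then gene id. Impact
classes follow the published accounting: HIGH = {splice acceptor, splice
donor, start lost, stop gained} (which reproduces the 16+19+11+116 = 162
arithmetic), MODERATE = missense, LOW = {synonymous, start gained, stop
lost}, MODIFIER = everything else. Note this HIGH set excludes stop_lost,
unlike common annotator defaults; placing stop_lost in LOW keeps the
four-class partition total, and the map is user-configurable
(`AnnotParams.impact_map`). The `exonic` category (non-coding-gene exon)
extends the taxonomy so that the 14-row category table is complete.

Tallies are counted in variant–gene record units (a SNP in two genes'
flanks counts twice), mirroring the additive structure of the published
tables; per-variant unique counts are available from the summary map.

## Group-specific SNP selection

A filtered, annotated SNP is specific to a target group of heat classes
(default {HT}) iff (a) at least one target accession carries the
alternate allele (heterozygous carriage counts), (b) *no* non-target
accession with a called genotype carries it — missing genotypes outside
the group do not block, since requiring calls everywhere would make
specificity depend on call rate — and (c) it has at least one consequence
record in scope. Scope `genic_and_flank` (default) is any non-intergenic
record; `high_impact_only` restricts to HIGH-impact records. Specificity
is exclusivity, not fixation: the allele need not be present in *all*
target accessions. Metadata missing for a VCF sample is a hard error,
because silently dropping a sample could fabricate specificity.

## DEG consensus and intersection

Per comparison, up = (padj ≤ 0.05 and log2FC ≥ 1), down symmetric; both
thresholds inclusive, missing padj never significant. (The source
methods state padj < 0.05 in one place and ≤ 0.05 in the screening step;
the inclusive screening definition is implemented.) Across comparisons a
gene is up (down) when called up (down) at least once and never the
opposite direction; any up-vs-down conflict — across or within datasets —
excludes the gene as contradictory. Genes untested in a comparison are
neutral. The consensus sets are intersected with the group-SNP-bearing
genes, and each candidate carries its evidence row (SNP categories,
supporting datasets, non-reference flag).

## QTL mapping

Markers with sequences (≥ 15 bp) are placed by exact substring search on
both strands; unique hits get forward-strand coordinates, ambiguous
markers are excluded (optionally kept, first hit by contig order then
position), unplaced markers are logged. Each QTL's interval spans its
outermost placed markers; a QTL whose markers land on several contigs is
an error. Overlapping intervals on a contig are *merged* (union, QTL ids
concatenated) — of the plausible readings of "filtering the overlapping
QTL regions" (merge, drop duplicates, keep largest), merging is the only
information-preserving one, and the pre-merge interval count is still
reported. A gene belongs to a QTL when its span overlaps the interval by
≥ 1 bp (configurable in principle to full containment; 1 bp is the
simplest defensible rule). Final candidates are the DEG/SNP candidates
restricted to QTL residents, reported as up/down/total with the
non-reference subset.

## Synthetic study design

The generator's defaults are the study conditions, scaled to desk size:

- **Cohort**: 15 accessions in classes 2 HT / 6 T / 2 MT / 3 S / 2 HS
  (the real cohort's 3/36/6/10/5 composition scaled to ~15), fertility
  drawn inside each class interval, depths 12–30× except one susceptible
  accession at 5–9× so the PAV depth filter has work to do.
- **Genome**: 3 reference chromosomes and 4 non-reference contigs; 100
  genes (80 core / 20 variable, ~12% on non-reference contigs, 2
  non-coding models), 1–9 exons per gene (decreasing frequency, echoing
  the observed exon-count range), canonical ATG…stop CDS with GT/AG
  introns. Genes are spaced > 2 × flank (+300 bp) apart so every planted
  SNP maps to exactly one gene.
- **Presence**: core genes present everywhere; variable genes present per
  accession with probability 0.7, forced absent somewhere, and kept
  present in all HT accessions so planted SNP hosts stay callable.
  Coverage tracks realize the matrix exactly: present genes get 86–100%
  of exon bases at accession depth, absent genes 25–65%.
- **Variants**: ~2,000 background SNPs with per-site allele frequencies
  and missingness drawn so that some sites fail each filter, ~20
  multiallelic records to exercise the biallelic filter, and 20
  group-specific SNPs planted across all 14 categories (engineered
  codon/splice/UTR contexts, including a constructed upstream-ATG site
  for `start_gained`). Background genotypes are checked by brute force at
  generation time and repaired (one non-target carrier added) if they
  ever satisfy the specificity predicate. HT accessions are homozygous
  alt at planted SNPs; accessions lacking the host gene are missing.
- **Expression**: four datasets with 2/2/4/4 comparisons; 6 up and 4 down
  genes planted among the SNP hosts (including the non-reference
  candidates), 2 contradictory up-vs-down pairs, null rows for the other
  hosts, and per-comparison background genes (some significant) that lack
  group SNPs. Background genotype/expression streams never touch planted
  hosts, so expected candidates are determined purely by construction.
- **QTLs**: six QTLs anchored on planted genes (two overlapping, to
  exercise merging; two on non-reference contigs, yielding the
  two-non-reference-upregulated-candidates configuration of the original
  analysis), each delimited by two unique 20-mers extracted from the
  genome, plus one deliberately unplaceable marker. Ground-truth QTL
  membership is computed by brute-force span overlap against the
  constructed intervals, and `expected_candidates` is the three-way
  intersection of the planted DE, SNP-host and QTL-member sets.

A single root seed is split into independent substreams (metadata,
genome, presence, variants, expression, QTLs), so the generator is
byte-identical per seed and reconfiguring one stage does not perturb the
others.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level noise and mapping bias (coverage is
written directly from the presence truth), linkage disequilibrium and
population structure among background SNPs, indels and multi-transcript
genes, expression count noise (DEG tables carry final log2FC/padj values),
and genotype–coverage consistency for background SNPs (only planted SNPs
respect gene absence). Recovery results on this fixture demonstrate the
correctness of the decision logic, not robustness to upstream noise.

## Numerical and degenerate-input choices

- Strict `>` in the presence criterion; inclusive thresholds in the MAF
  (≥) and DEG (≤, ≥) filters — each matching the quoted operational
  wording.
- Jaccard of two empty presence sets is defined as 0 off-diagonal, 1 on
  the diagonal.
- NJ requires ≥ 3 taxa; branch lengths are clamped at 0.
- Growth fits that fail to converge flag `fit_ok = False` and keep the
  raw curve.
- Multi-mRNA genes keep the longest-CDS transcript with a warning; a CDS
  length not divisible by 3 demotes the model to non-coding with a
  warning; an exon outside its gene span rejects the record.
- Problem sizes in the test and acceptance runs (15 accessions, ~100
  genes, ~2,000 SNPs, 3–5 seeds, exhaustive growth curves at N ≤ 8) were
  chosen as the smallest sizes at which every stage — including both
  reference and non-reference candidate paths and every consequence
  category — is exercised.

## Known limitations

- SNP-only: indel and MNV consequences are out of scope.
- One transcript per gene; no isoform-aware annotation.
- Marker placement is exact-match only (no mismatches/BLAST), appropriate
  for the toy genomes it targets.
- The published impact accounting cannot be fully reverse-engineered
  (its low-impact and modifier totals are internally inconsistent by a
  few counts); the implemented map reproduces the HIGH/MODERATE
  arithmetic exactly and makes the LOW assignment explicit and
  configurable.
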