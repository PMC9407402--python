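"""Shared fixtures: a hand-built two-exon toy gene with fully known
consequence positions, and a session-scoped simulated study."""

import warnings

import pytest

from panheat import SimConfig, simulate
from panheat.io_formats import Contig, ContigSet, GeneModel
from panheat.pipeline import run_pipeline
from panheat.variants import revcomp

# --- hand-built toy gene ---------------------------------------------------
#
# plus-strand layout on a 60 bp contig (1-based):
#   1-5    TTTTT        padding (upstream flank)
#   6-11   CACGCC       5'UTR (exon 1)
#   12-20  ATGAAATGG    CDS part 1: ATG AAA TGG
#   21-28  GTCCCCAG     intron (GT...AG)
#   29-34  CCCTAA       CDS part 2: CCC TAA
#   35-40  CCCCCC       3'UTR (exon 2)
#   41-60  padding (downstream flank)
#
# protein: M K W P *
TOY_SEQ = "TTTTT" + "CACGCC" + "ATGAAATGG" + "GTCCCCAG" + "CCCTAA" + "CCCCCC" + "G" * 20
assert len(TOY_SEQ) == 60

# (pos, alt) -> expected category on the plus strand (flank 2000)
TOY_EXPECTATIONS = {
    (17, "G"): "synonymous",      # AAA -> AAG (Lys)
    (20, "A"): "stop_gained",     # TGG -> TGA
    (21, "A"): "splice_donor",    # first intron base
    (28, "C"): "splice_acceptor", # last intron base
    (12, "G"): "start_lost",      # ATG -> GTG
    (34, "C"): "stop_lost",       # TAA -> TAC
    (16, "C"): "missense",        # AAA -> ACA (Lys -> Thr)
    (8, "T"): "start_gained",     # CACGCC -> CATGCC creates ATG
    (6, "G"): "utr5",
    (37, "A"): "utr3",
    (24, "T"): "intronic",
    (3, "C"): "upstream",
    (45, "C"): "downstream",
}


def make_toy(strand: str = "+"):
    """The toy gene as (genome, model); the minus version is the exact
    reverse complement with mirrored coordinates."""
    if strand == "+":
        seq = TOY_SEQ
        model = GeneModel(
            gene_id="toy", contig="toy1", strand="+", start=6, end=40,
            exons=[(6, 20), (29, 40)], cds=[(12, 20), (29, 34)],
        )
    else:
        L = len(TOY_SEQ)
        seq = revcomp(TOY_SEQ)
        flip = lambda iv: (L + 1 - iv[1], L + 1 - iv[0])
        model = GeneModel(
            gene_id="toy", contig="toy1", strand="-",
            start=L + 1 - 40, end=L + 1 - 6,
            exons=sorted(flip(iv) for iv in [(6, 20), (29, 40)]),
            cds=sorted(flip(iv) for iv in [(12, 20), (29, 34)]),
        )
    return ContigSet([Contig("toy1", seq)]), model


def mirror_variant(pos: int, alt: str, length: int = 60) -> tuple[int, str]:
    return length + 1 - pos, revcomp(alt)


# --- simulated study -------------------------------------------------------

@pytest.fixture(scope="session")
def sim_study(tmp_path_factory):
    d = tmp_path_factory.mktemp("sim")
    return simulate(SimConfig(seed=1), d)


@pytest.fixture(scope="session")
def sim_result(sim_study):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(sim_study.paths["genome"].parent)
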