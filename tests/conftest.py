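import numpy as np
import pytest

from fgfrscreen.annotate import TranscriptModel
from fgfrscreen.pipeline import run_study_scenario

SCENARIO_SEED = 17


@pytest.fixture(scope="session")
def scenario17():
    """The packaged worked-example scenario, run end to end once per session."""
    return run_study_scenario(SCENARIO_SEED)


@pytest.fixture()
def toy_model():
    """Three-codon plus-strand gene: CDS ATG GAC AAA (M, D, K) at 101-109."""
    return TranscriptModel("TOY", "1", "+", [(101, 109)], "ATGGACAAA")


@pytest.fixture()
def toy_model_minus():
    """The same coding sequence on the minus strand.

    Genomic sequence at 101-109 is the reverse complement of the CDS, so the
    transcript reads ATGGACAAA again."""
    return TranscriptModel("TOY", "1", "-", [(101, 109)], "ATGGACAAA")


def random_multiexon_model(rng: np.random.Generator, n_codons: int = 200, strand: str = "+"):
    """Random stop-free multi-exon transcript for oracle comparisons."""
    sense = [
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
        if a + b + c not in ("TAA", "TAG", "TGA")
    ]
    cds = "ATG" + "".join(sense[i] for i in rng.integers(0, len(sense), n_codons - 1))
    cuts = sorted(rng.choice(np.arange(1, len(cds)), size=3, replace=False))
    bounds = [0, *cuts, len(cds)]
    chunks = [cds[a:b] for a, b in zip(bounds[:-1], bounds[1:])]
    genomic_chunks = (
        chunks
        if strand == "+"
        else [c.translate(str.maketrans("ACGT", "TGCA"))[::-1] for c in chunks[::-1]]
    )
    segments = []
    cursor = 1000
    for chunk in genomic_chunks:
        segments.append((cursor, cursor + len(chunk) - 1))
        cursor += len(chunk) + 50  # 50 bp introns
    return TranscriptModel("RAND", "7", strand, segments, cds)
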