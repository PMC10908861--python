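import warnings

import numpy as np
import pytest

from periscore import pipeline, synthetic
from periscore.annotation_io import GenomeSequence, Transcript

warnings.filterwarnings("ignore", category=FutureWarning, module="sklearn")
warnings.filterwarnings(
    "ignore", message=".*lbfgs failed to converge.*"
)


@pytest.fixture
def toy_plus() -> tuple[Transcript, GenomeSequence]:
    """Single-exon plus-strand gene: exon chr1:[100,200), CDS at tx [10,40)."""
    seq = ["A"] * 300
    body = "ATGAAACCCGGGTTTAAACCCGGGTTTTAG"  # 30 nt CDS incl. stop
    seq[110:140] = body
    genome = GenomeSequence({"chr1": "".join(seq)})
    tx = Transcript("txp", "gp", "protein_coding", "chr1", "+", [(100, 200)], cds=(10, 40))
    return tx, genome


@pytest.fixture
def toy_minus() -> tuple[Transcript, GenomeSequence]:
    """Two-exon minus-strand gene on a 120-nt chromosome."""
    chrom = "".join(
        np.random.default_rng(3).choice(list("ACGT"), size=120)
    )
    genome = GenomeSequence({"chr2": chrom})
    tx = Transcript("txm", "gm", "protein_coding", "chr2", "-", [(20, 50), (70, 100)])
    return tx, genome


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark: two read samples over one transcriptome,
    run through the full calling pipeline (per-sample + merged models)."""
    spec = synthetic.SimulationSpec(n_transcripts=200)
    rng = np.random.default_rng(11)
    transcripts, genome, truth = synthetic.simulate_transcriptome(spec, rng)
    samples = {
        "s1": synthetic.simulate_ribo_reads(transcripts, truth, spec.reads, rng),
        "s2": synthetic.simulate_ribo_reads(transcripts, truth, spec.reads, rng),
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = pipeline.call_orfs(
            transcripts, samples, n_pos=80, n_neg=240, rng_seed=5
        )
    return {
        "spec": spec,
        "transcripts": transcripts,
        "genome": genome,
        "truth": truth,
        "samples": samples,
        "result": result,
    }
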