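import numpy as np
import pytest

from cysloop import (MotifPlan, TranscriptomeSpec, groom_reads,
                     make_synthetic_transcriptome, tile_reads)


@pytest.fixture
def rng():
    return np.random.default_rng(20150914)


def random_dna(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture
def small_truth():
    """One anion-type gene, one cation-type gene, one generic gene, actin."""
    plans = {
        "g00": MotifPlan(),
        "g01": MotifPlan(vicinal_cc=True,
                         tm2_prime_residues={-2: "S", -1: "E", 0: "Q",
                                             13: "V", 20: "E"}),
    }
    spec = TranscriptomeSpec(n_genes=3, motif_plan=plans, rng_seed=42,
                             error_rate=0.0)
    return make_synthetic_transcriptome(spec)


@pytest.fixture
def tiled_db(small_truth):
    """Error-free stride-3 tiling (~33x) of every truth transcript."""
    reads = []
    for t in small_truth.transcripts:
        reads.extend(tile_reads(t.seq, read_length=100, stride=3,
                                id_prefix=t.id))
    return groom_reads(reads)
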