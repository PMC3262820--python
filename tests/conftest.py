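import numpy as np
import pytest

from hollowmeth import (
    AlignParams,
    ReferenceSet,
    SimConfig,
    build_converted_references,
    simulate_bisulfite_reads,
    simulate_genome,
    simulate_methylome,
)
from hollowmeth.bsalign import align_pairs
from hollowmeth import dna


def make_perfect_pair(seq: str, start: int, flen: int, strand: str = "W",
                      read_len: int = 49, methylated: bool = False):
    """Error-free bisulfite read pair from a fragment of `seq`.

    With methylated=False every cytosine on the originating strand converts
    (reads as T); with methylated=True none do.
    """
    frag = seq[start : start + flen].upper()
    if strand == "C":
        frag = str.translate(frag, str.maketrans("ACGT", "TGCA"))[::-1]
    conv = frag if methylated else frag.replace("C", "T")
    r1 = conv[:read_len]
    r2 = str.translate(conv[-read_len:], str.maketrans("ACGT", "TGCA"))[::-1]
    q = np.full(read_len, 40, dtype=np.uint8)
    return r1, q.copy(), r2, q.copy()


def align_batch(reads, ref, sim_cfg, engine="seed"):
    conv = build_converted_references(ref)
    params = AlignParams.from_fragment_model(sim_cfg.fragment_mean, sim_cfg.fragment_sd, sim_cfg.read_length)
    return align_pairs(reads.r1, reads.q1, reads.r2, reads.q2, conv, params,
                       pair_ids=reads.ids, engine=engine)


@pytest.fixture(scope="session")
def small_sim():
    """A 50 kb simulated experiment shared by several test modules."""
    cfg = SimConfig(seed=11, genome_length=50_000, control_length=5_000)
    ref, repeats = simulate_genome(cfg)
    meth = simulate_methylome(ref, cfg)
    reads, truth = simulate_bisulfite_reads(ref, meth, cfg)
    return cfg, ref, repeats, meth, reads, truth


@pytest.fixture(scope="session")
def small_alignment(small_sim):
    cfg, ref, _, _, reads, truth = small_sim
    return align_batch(reads, ref, cfg)


@pytest.fixture()
def random_ref():
    """A 5 kb single-contig reference with a flagged control contig."""
    rng = np.random.default_rng(42)
    contig = dna.codes_to_seq(rng.integers(0, 4, 5000).astype(np.uint8))
    control = dna.codes_to_seq(rng.integers(0, 4, 1000).astype(np.uint8))
    return ReferenceSet({"chr1": contig, "lambda_control": control}, {"lambda_control"})
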