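"""Generator behavior: determinism, composition, conversion statistics."""

import io

import numpy as np
import pytest

from hollowmeth import (
    SimConfig,
    simulate_bisulfite_reads,
    simulate_genome,
    simulate_methylome,
)
from hollowmeth import dna
from hollowmeth.simdata import CONTROL_NAME, _rip_mutate


def _fasta_bytes(ref):
    buf = io.StringIO()
    for name, seq in ref.contigs.items():
        buf.write(f">{name}\n{seq}\n")
    return buf.getvalue().encode()


def test_same_seed_reproduces_identical_outputs():
    cfg = SimConfig(seed=7, genome_length=20_000, control_length=2_000)
    runs = []
    for _ in range(2):
        ref, repeats = simulate_genome(cfg)
        meth = simulate_methylome(ref, cfg)
        reads, truth = simulate_bisulfite_reads(ref, meth, cfg)
        runs.append((_fasta_bytes(ref), meth.entries, reads, truth))
    assert runs[0][0] == runs[1][0]
    assert runs[0][1] == runs[1][1]
    a, b = runs[0][2], runs[1][2]
    assert a.ids == b.ids
    assert np.array_equal(a.r1, b.r1) and np.array_equal(a.q2, b.q2)
    assert runs[0][3].equals(runs[1][3])


def test_genome_matches_requested_gc_fraction():
    cfg = SimConfig(seed=1, gc_fraction=0.5, genome_length=100_000)
    ref, _ = simulate_genome(cfg)
    codes = np.concatenate([ref.codes(n) for n in ref.genomic_names])
    assert 0.48 <= dna.gc_fraction(codes) <= 0.52


def test_genome_rejects_oversized_repeat_request():
    cfg = SimConfig(seed=1, genome_length=10_000, n_repeat_families=4,
                    repeat_length=800, repeat_copies=4)
    with pytest.raises(ValueError, match="repeats"):
        simulate_genome(cfg)


def test_rip_mutation_raises_tpa_apt_ratio():
    rng = np.random.default_rng(0)
    for _ in range(20):
        src = rng.integers(0, 4, 500).astype(np.uint8)
        mut = _rip_mutate(src, rng, 0.3)
        s, m = dna.codes_to_seq(src), dna.codes_to_seq(mut)
        if s.count("AT") == 0:
            continue
        assert m.count("TA") / m.count("AT") > s.count("TA") / s.count("AT")


def test_methylome_counts_and_control_exclusion():
    cfg = SimConfig(seed=3, genome_length=20_000, control_length=2_000,
                    n_methylated_sites=1000, methylation_level=0.8)
    ref, _ = simulate_genome(cfg)
    meth = simulate_methylome(ref, cfg)
    assert len(meth) == 1000
    assert all(lv == 0.8 for lv in meth.entries.values())
    assert all(c != CONTROL_NAME for c, _, _ in meth.entries)
    for (c, p, s) in meth.entries:
        base = ref.contigs[c][p]
        assert base == ("C" if s == "+" else "G")
    # zero-site case: everything unmethylated
    meth0 = simulate_methylome(ref, SimConfig(seed=3, genome_length=20_000, n_methylated_sites=0))
    assert len(meth0) == 0


def test_methylome_rejects_more_sites_than_cytosines():
    cfg = SimConfig(seed=3, genome_length=1_000, n_repeat_families=0, n_methylated_sites=10**6)
    ref, _ = simulate_genome(cfg)
    with pytest.raises(ValueError, match="cytosines"):
        simulate_methylome(ref, cfg)


def _observed_cytosine_reads(ref, reads, truth):
    """(unconverted, total) cytosine observations per contig group, from truth."""
    out = {}
    L = reads.r1.shape[1]
    for i in range(len(reads)):
        t = truth.iloc[i]
        g = ref.codes(t.contig)
        if t.strand == "W":
            windows = ((reads.r1[i], np.arange(t.start, t.start + L)),
                       (dna.revcomp_codes(reads.r2[i]), np.arange(t.end - L, t.end)))
            refbase, ub, cb = dna.C, dna.C, dna.T
        else:
            windows = ((dna.revcomp_codes(reads.r1[i]), np.arange(t.end - L, t.end)),
                       (reads.r2[i], np.arange(t.start, t.start + L)))
            refbase, ub, cb = dna.G, dna.G, dna.A
        k = n = 0
        for obs, pos in windows:
            sel = g[pos] == refbase
            k += int(((obs == ub) & sel).sum())
            n += int((((obs == ub) | (obs == cb)) & sel).sum())
        key = t.contig
        kk, nn = out.get(key, (0, 0))
        out[key] = (kk + k, nn + n)
    return out


def test_perfect_conversion_shows_no_unconverted_cytosines():
    cfg = SimConfig(seed=5, genome_length=5_000, control_length=500, n_repeat_families=0,
                    non_conversion_rate=0.0, seq_error_rate=0.0, coverage_target=4.0)
    ref, _ = simulate_genome(cfg)
    meth = simulate_methylome(ref, cfg)
    reads, truth = simulate_bisulfite_reads(ref, meth, cfg)
    obs = _observed_cytosine_reads(ref, reads, truth)
    assert sum(k for k, _ in obs.values()) == 0
    assert sum(n for _, n in obs.values()) > 1000


def test_fully_methylated_site_always_reads_cytosine():
    cfg = SimConfig(seed=6, genome_length=5_000, control_length=500, n_repeat_families=0,
                    non_conversion_rate=0.0, seq_error_rate=0.0,
                    n_methylated_sites=50, methylation_level=1.0, coverage_target=8.0)
    ref, _ = simulate_genome(cfg)
    meth = simulate_methylome(ref, cfg)
    reads, truth = simulate_bisulfite_reads(ref, meth, cfg)
    L = reads.r1.shape[1]
    checked = 0
    for i in range(len(reads)):
        t = truth.iloc[i]
        if t.strand != "W":
            continue
        obs = reads.r1[i]
        for j, p in enumerate(range(t.start, t.start + L)):
            if meth.level_at(t.contig, p, "+") == 1.0:
                assert obs[j] == dna.C
                checked += 1
    assert checked > 10


def test_lambda_non_conversion_matches_binomial_expectation():
    """Unconverted fraction on the control within 3 SE of the configured rate."""
    cfg = SimConfig(seed=8, genome_length=20_000, control_length=20_000,
                    lambda_mass_fraction=0.5, non_conversion_rate=0.005,
                    seq_error_rate=0.0, coverage_target=14.0)
    ref, _ = simulate_genome(cfg)
    meth = simulate_methylome(ref, cfg)
    reads, truth = simulate_bisulfite_reads(ref, meth, cfg)
    k, n = _observed_cytosine_reads(ref, reads, truth)[CONTROL_NAME]
    assert n >= 100_000
    se = np.sqrt(0.005 * 0.995 / n)
    assert abs(k / n - 0.005) < 3 * se


def test_emission_accounting_and_strand_symmetry():
    cfg = SimConfig(seed=9, genome_length=300_000)
    ref, _ = simulate_genome(cfg)
    meth = simulate_methylome(ref, cfg)
    reads, truth = simulate_bisulfite_reads(ref, meth, cfg)
    # conservation: emitted count implied by coverage target and spike-in share
    n_genomic = round(cfg.coverage_target * 300_000 / cfg.read_length)
    assert len(reads) == round(n_genomic / (1 - cfg.lambda_mass_fraction))
    # duplicates marked and byte-identical to their source
    dups = truth[truth.duplicate_of != ""]
    assert len(dups) == round(cfg.pcr_duplicate_rate * len(reads))
    src = truth.set_index("pair_id")
    row = dups.iloc[0]
    i = truth.index[truth.pair_id == row.pair_id][0]
    j = truth.index[truth.pair_id == row.duplicate_of][0]
    assert np.array_equal(reads.r1[i], reads.r1[j]) and np.array_equal(reads.q2[i], reads.q2[j])
    # strand symmetry at high coverage
    w = int((truth.strand == "W").sum())
    c = int((truth.strand == "C").sum())
    assert abs(w - c) / ((w + c) / 2) < 0.01


def test_read_count_ceiling_enforced():
    cfg = SimConfig(seed=1, genome_length=50_000, max_read_pairs=100)
    ref, _ = simulate_genome(cfg)
    meth = simulate_methylome(ref, cfg)
    with pytest.raises(ValueError, match="ceiling"):
        simulate_bisulfite_reads(ref, meth, cfg)


def test_config_validation_rejects_bad_proportions():
    with pytest.raises(ValueError):
        SimConfig(non_conversion_rate=1.5)
    with pytest.raises(ValueError):
        SimConfig(read_length=300, fragment_mean=200)
    with pytest.raises(ValueError):
        SimConfig(genome_length=100)


def test_fastq_round_trip(tmp_path, small_sim):
    _, _, _, _, reads, _ = small_sim
    from hollowmeth.simdata import ReadPairBatch

    p1, p2 = tmp_path / "r1.fastq.gz", tmp_path / "r2.fastq.gz"
    reads.to_fastq(p1, p2)
    back = ReadPairBatch.from_fastq(p1, p2)
    assert back.ids == reads.ids
    assert np.array_equal(back.r1, reads.r1)
    assert np.array_equal(back.q1, reads.q1)
    assert np.array_equal(back.r2, reads.r2)
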