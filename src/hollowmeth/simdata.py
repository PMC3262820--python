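"""Seeded synthetic data for the bisulfite pipeline.

Generates a small multi-contig genome with repeat families (optionally
carrying RIP-style C->T hypermutation), an unmethylated control contig
playing the lambda spike-in role, a per-cytosine truth methylome, and
paired-end bisulfite reads with sonication-style fragment lengths,
non-conversion noise, Phred-consistent base-call errors and PCR clonal
duplicates. Every output is a deterministic function of the config seed.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import dna
from .bsalign import ReferenceSet
from .dna import A, C, G, T

CONTROL_NAME = "lambda_control"


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic experiment.

    Defaults emulate the real library design: 49 bp paired-end reads from
    ~200 bp sonication fragments, 14x per-strand coverage, a 0.5% spike-in
    mass fraction (25 ng control DNA per 5 ug genomic), and near-complete
    bisulfite conversion.
    """

    seed: int = 0
    genome_length: int = 300_000
    n_contigs: int = 3
    gc_fraction: float = 0.48
    read_length: int = 49
    fragment_mean: float = 200.0
    fragment_sd: float = 50.0
    non_conversion_rate: float = 0.002
    seq_error_rate: float = 0.001
    lambda_mass_fraction: float = 0.005
    pcr_duplicate_rate: float = 0.02
    coverage_target: float = 14.0  # read-base coverage per strand
    n_methylated_sites: int = 0
    methylation_level: float = 0.8
    control_length: int = 10_000
    n_repeat_families: int = 2
    repeat_length: int = 600
    repeat_copies: int = 3
    repeat_divergence: float = 0.01
    rip_mutation_rate: float = 0.3
    max_read_pairs: int = 5_000_000

    def __post_init__(self) -> None:
        props = {
            "gc_fraction": self.gc_fraction,
            "non_conversion_rate": self.non_conversion_rate,
            "seq_error_rate": self.seq_error_rate,
            "lambda_mass_fraction": self.lambda_mass_fraction,
            "pcr_duplicate_rate": self.pcr_duplicate_rate,
            "methylation_level": self.methylation_level,
            "repeat_divergence": self.repeat_divergence,
            "rip_mutation_rate": self.rip_mutation_rate,
        }
        for name, v in props.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed fragment_mean")
        if self.genome_length < 10 * self.read_length:
            raise ValueError("genome_length must be at least 10 read lengths")
        if self.n_contigs < 1 or self.read_length < 1:
            raise ValueError("n_contigs and read_length must be positive")


@dataclass
class MethylomeTruth:
    """Ground-truth methylation probability per cytosine.

    Only non-zero sites are stored; every unkeyed reference cytosine is
    implicitly unmethylated. The control contig never carries entries.
    """

    entries: dict[tuple[str, int, str], float] = field(default_factory=dict)

    def level_at(self, contig: str, pos: int, strand: str) -> float:
        return self.entries.get((contig, pos, strand), 0.0)

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path) -> None:
        rows = [
            {"contig": c, "position": p + 1, "strand": s, "level": lv}
            for (c, p, s), lv in sorted(self.entries.items())
        ]
        pd.DataFrame(rows, columns=["contig", "position", "strand", "level"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "MethylomeTruth":
        df = pd.read_csv(path, sep="\t")
        return cls({(r.contig, int(r.position) - 1, r.strand): float(r.level) for r in df.itertuples()})


@dataclass
class RepeatCopy:
    contig: str
    start: int
    end: int
    family_id: str
    rip_mutated: bool


@dataclass
class RepeatTruthSet:
    """Inserted repeat copies, 0-based half-open, with their RIP status."""

    intervals: list[RepeatCopy] = field(default_factory=list)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.family_id}\t{int(iv.rip_mutated)}\n")

    @classmethod
    def from_bed(cls, path) -> "RepeatTruthSet":
        out = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                f = line.rstrip("\n").split("\t")
                out.append(RepeatCopy(f[0], int(f[1]), int(f[2]), f[3], bool(int(f[4]))))
        return cls(out)


class ReadPairBatch:
    """In-memory paired reads: ids plus (n, read_length) code/quality arrays."""

    def __init__(self, ids, r1, q1, r2, q2):
        self.ids = list(ids)
        self.r1, self.q1, self.r2, self.q2 = r1, q1, r2, q2

    def __len__(self) -> int:
        return len(self.ids)

    def to_fastq(self, path_r1, path_r2) -> None:
        for path, reads, quals, mate in ((path_r1, self.r1, self.q1, 1), (path_r2, self.r2, self.q2, 2)):
            opener = gzip.open if str(path).endswith(".gz") else open
            with opener(path, "wt") as fh:
                for i, name in enumerate(self.ids):
                    fh.write(f"@{name}/{mate}\n{dna.codes_to_seq(reads[i])}\n+\n{dna.quals_to_ascii(quals[i])}\n")

    @classmethod
    def from_fastq(cls, path_r1, path_r2) -> "ReadPairBatch":
        def read_one(path):
            names, seqs, quals = [], [], []
            opener = gzip.open if str(path).endswith(".gz") else open
            with opener(path, "rt") as fh:
                while True:
                    header = fh.readline()
                    if not header:
                        break
                    seq = fh.readline().strip()
                    fh.readline()
                    qual = fh.readline().strip()
                    names.append(header[1:].strip().split("/")[0].split()[0])
                    seqs.append(dna.seq_to_codes(seq))
                    quals.append(dna.ascii_to_quals(qual))
            return names, np.stack(seqs) if seqs else np.zeros((0, 0), np.uint8), \
                np.stack(quals) if quals else np.zeros((0, 0), np.uint8)

        n1, r1, q1 = read_one(path_r1)
        n2, r2, q2 = read_one(path_r2)
        if n1 != n2:
            raise ValueError("R1/R2 read names do not pair up")
        return cls(n1, r1, q1, r2, q2)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(4, size=length, p=p).astype(np.uint8)


def _rip_mutate(copy: np.ndarray, rng: np.random.Generator, rate: float) -> np.ndarray:
    """C->T at CpA sites (G->A at TpG, the reverse-strand equivalent).

    Sites whose 5' (for CpA) or 3' (for TpG) flank would turn an existing
    dinucleotide into ApT are skipped, so every mutation adds exactly one
    TpA and no ApT; at least one candidate is always mutated when any exist,
    making the TpA/ApT index strictly increase.
    """
    out = copy.copy()
    prev = np.concatenate(([np.uint8(dna.N)], copy[:-1]))
    nxt = np.concatenate((copy[1:], [np.uint8(dna.N)]))
    nxt2 = np.concatenate((copy[2:], [np.uint8(dna.N)] * 2))
    ca = (copy == C) & (nxt == A) & (prev != A)  # X C A, X != A
    tg = (copy == T) & (nxt == G) & (nxt2 != T)  # T G X, X != T  (mutate the G)
    ca_idx = np.flatnonzero(ca)
    tg_idx = np.flatnonzero(tg)
    hit_any = False
    for idx, base in ((ca_idx, T), (tg_idx, A)):
        if len(idx) == 0:
            continue
        hit = rng.random(len(idx)) < rate
        pos = idx + (1 if base == A else 0)  # for TpG the mutated base is the G
        out[pos[hit]] = base
        hit_any = hit_any or bool(hit.any())
    if not hit_any and len(ca_idx):
        out[ca_idx[0]] = T
    return out


def simulate_genome(config: SimConfig, control_gc: float = 0.5) -> tuple[ReferenceSet, RepeatTruthSet]:
    """Random multi-contig genome with inserted repeat families plus control.

    Repeat families are near-identical copies of a random consensus; families
    with odd index carry RIP-style hypermutation. The control contig (the
    spike-in role) is appended on top of ``genome_length``.
    """
    rng = np.random.default_rng([config.seed, 101])
    total_repeat = config.n_repeat_families * config.repeat_copies * config.repeat_length
    if total_repeat > 0.5 * config.genome_length:
        raise ValueError(
            f"genome_length {config.genome_length} too small for "
            f"{total_repeat} bp of requested repeats"
        )

    base_len = config.genome_length // config.n_contigs
    lengths = [base_len] * config.n_contigs
    lengths[0] += config.genome_length - base_len * config.n_contigs
    names = [f"contig_{i + 1}" for i in range(config.n_contigs)]
    contigs = {nm: _random_seq(rng, ln, config.gc_fraction) for nm, ln in zip(names, lengths)}

    occupied: dict[str, list[tuple[int, int]]] = {nm: [] for nm in names}
    truth: list[RepeatCopy] = []
    rlen = config.repeat_length
    for fam in range(config.n_repeat_families):
        consensus = _random_seq(rng, rlen, config.gc_fraction)
        rip = fam % 2 == 1
        for _copy in range(config.repeat_copies):
            placed = False
            for _try in range(1000):
                nm = names[int(rng.integers(config.n_contigs))]
                if lengths[names.index(nm)] < rlen:
                    continue
                start = int(rng.integers(0, len(contigs[nm]) - rlen + 1))
                if any(start < e and start + rlen > s for s, e in occupied[nm]):
                    continue
                seq = consensus.copy()
                div = rng.random(rlen) < config.repeat_divergence
                seq[div] = (seq[div] + rng.integers(1, 4, int(div.sum())).astype(np.uint8)) % 4
                if rip:
                    seq = _rip_mutate(seq, rng, config.rip_mutation_rate)
                contigs[nm][start : start + rlen] = seq
                occupied[nm].append((start, start + rlen))
                truth.append(RepeatCopy(nm, start, start + rlen, f"fam{fam}", rip))
                placed = True
                break
            if not placed:
                raise ValueError("could not place repeats; genome_length too small")

    seqs = {nm: dna.codes_to_seq(arr) for nm, arr in contigs.items()}
    seqs[CONTROL_NAME] = dna.codes_to_seq(_random_seq(rng, config.control_length, control_gc))
    ref = ReferenceSet(seqs, {CONTROL_NAME})
    truth.sort(key=lambda iv: (iv.contig, iv.start))
    return ref, RepeatTruthSet(truth)


def simulate_methylome(ref: ReferenceSet, config: SimConfig) -> MethylomeTruth:
    """Place ``n_methylated_sites`` cytosines at ``methylation_level``.

    Sites are drawn without replacement from all genomic cytosines on both
    strands; control contigs are excluded so the spike-in premise holds.
    """
    rng = np.random.default_rng([config.seed, 202])
    sites: list[tuple[str, int, str]] = []
    for name in ref.genomic_names:
        codes = ref.codes(name)
        for pos in np.flatnonzero(codes == C):
            sites.append((name, int(pos), "+"))
        for pos in np.flatnonzero(codes == G):
            sites.append((name, int(pos), "-"))
    if config.n_methylated_sites > len(sites):
        raise ValueError(
            f"requested {config.n_methylated_sites} methylated sites but the "
            f"genome has only {len(sites)} cytosines"
        )
    chosen = rng.choice(len(sites), size=config.n_methylated_sites, replace=False)
    return MethylomeTruth({sites[i]: config.methylation_level for i in chosen})


def _quality_model(error_rate: float, rng: np.random.Generator, shape) -> np.ndarray:
    """Phred scores whose implied error probability matches the target rate.

    A two-component mixture of Q40 and Q6 bases is weighted so the expected
    per-base error equals ``error_rate``; the Q6 component is what the
    downstream Q<20 mask removes. Base-call errors are then drawn per base
    at 10^(-Q/10), so quality and error are consistent by construction.
    """
    if error_rate <= 0:
        return np.full(shape, 40, dtype=np.uint8)
    e_hi, e_lo = 1e-4, 10 ** (-0.6)
    if error_rate <= e_hi:
        q = int(np.clip(round(-10 * math.log10(error_rate)), 2, 40))
        return np.full(shape, q, dtype=np.uint8)
    w = min(1.0, (error_rate - e_hi) / (e_lo - e_hi))
    low = rng.random(shape) < w
    quals = np.full(shape, 40, dtype=np.uint8)
    quals[low] = 6
    return quals


def simulate_bisulfite_reads(
    ref: ReferenceSet, meth: MethylomeTruth, config: SimConfig
) -> tuple[ReadPairBatch, pd.DataFrame]:
    """Draw sonication fragments and emit converted paired-end reads.

    Fragment counts follow ``coverage_target`` (per-strand read-base
    coverage of the genomic contigs); a ``lambda_mass_fraction`` share of
    fragments originates from the control contigs (mass is proportional to
    fragment count at an identical length law). A ``pcr_duplicate_rate``
    share of emitted pairs are byte-identical re-emissions of earlier pairs.

    Returns the reads plus a truth table (pair_id, contig, start, end,
    strand, duplicate_of).
    """
    rng = np.random.default_rng([config.seed, 303])
    L = config.read_length

    names = ref.names
    codes = np.concatenate([ref.codes(nm) for nm in names])
    clens = np.array([ref.length(nm) for nm in names], dtype=np.int64)
    offsets = np.concatenate(([0], np.cumsum(clens)))[:-1]
    is_control = np.array([nm in ref.control_names for nm in names])

    # truth methylation levels in concatenated coordinates
    plus_lv = np.zeros(len(codes), dtype=np.float32)
    minus_lv = np.zeros(len(codes), dtype=np.float32)
    name_to_idx = {nm: i for i, nm in enumerate(names)}
    for (cname, pos, strand), lv in meth.entries.items():
        gpos = offsets[name_to_idx[cname]] + pos
        (plus_lv if strand == "+" else minus_lv)[gpos] = lv

    genomic_bp = int(clens[~is_control].sum())
    n_genomic = int(round(config.coverage_target * genomic_bp / (2 * L) * 2))
    lam = config.lambda_mass_fraction
    n_total = int(round(n_genomic / (1 - lam))) if lam < 1 else n_genomic
    if n_total > config.max_read_pairs:
        raise ValueError(
            f"coverage_target implies {n_total} read pairs, above the "
            f"ceiling of {config.max_read_pairs}"
        )
    n_dup = int(round(config.pcr_duplicate_rate * n_total))
    n_unique = n_total - n_dup

    # contig choice: control share = lambda fraction, genomic share by length
    probs = np.where(is_control, 0.0, clens / max(genomic_bp, 1) * (1 - lam))
    ctrl_bp = int(clens[is_control].sum())
    if ctrl_bp and lam > 0:
        probs = np.where(is_control, clens / ctrl_bp * lam, probs)
    probs = probs / probs.sum()
    ci = rng.choice(len(names), size=n_unique, p=probs)

    flen = np.rint(rng.normal(config.fragment_mean, config.fragment_sd, n_unique)).astype(np.int64)
    flen = np.clip(flen, L, clens[ci])
    start_local = (rng.random(n_unique) * (clens[ci] - flen + 1)).astype(np.int64)
    start = offsets[ci] + start_local
    watson = rng.integers(0, 2, n_unique) == 0

    ar = np.arange(L, dtype=np.int64)
    left_pos = start[:, None] + ar
    right_pos = (start + flen)[:, None] - L + ar
    gl = codes[left_pos].copy()
    gr = codes[right_pos].copy()

    ncv = config.non_conversion_rate

    def convert(window: np.ndarray, pos: np.ndarray) -> None:
        # Watson chemistry: C stays C w.p. m + (1-m)*ncv else reads T.
        mask = (window == C) & watson[:, None]
        m = plus_lv[pos[mask]]
        stays = rng.random(mask.sum()) < m + (1 - m) * ncv
        vals = np.where(stays, np.uint8(C), np.uint8(T))
        window[mask] = vals
        # Crick chemistry in Watson-sense coordinates: G stays G else reads A.
        mask = (window == G) & ~watson[:, None]
        m = minus_lv[pos[mask]]
        stays = rng.random(mask.sum()) < m + (1 - m) * ncv
        window[mask] = np.where(stays, np.uint8(G), np.uint8(A))

    convert(gl, left_pos)
    convert(gr, right_pos)

    rc_gr = dna.revcomp_codes(gr)
    wcol = watson[:, None]
    read1 = np.where(wcol, gl, rc_gr).astype(np.uint8)
    read2 = np.where(wcol, rc_gr, gl).astype(np.uint8)

    q1 = _quality_model(config.seq_error_rate, rng, read1.shape)
    q2 = _quality_model(config.seq_error_rate, rng, read2.shape)
    if config.seq_error_rate > 0:
        for reads, quals in ((read1, q1), (read2, q2)):
            p_err = 10.0 ** (-quals.astype(np.float64) / 10.0)
            err = rng.random(reads.shape) < p_err
            shift = rng.integers(1, 4, int(err.sum())).astype(np.uint8)
            reads[err] = (reads[err] + shift) % 4

    ids = [f"p{i:07d}" for i in range(n_total)]
    dup_src = rng.integers(0, n_unique, n_dup) if n_dup else np.zeros(0, dtype=np.int64)

    r1 = np.concatenate([read1, read1[dup_src]]) if n_dup else read1
    r2 = np.concatenate([read2, read2[dup_src]]) if n_dup else read2
    qq1 = np.concatenate([q1, q1[dup_src]]) if n_dup else q1
    qq2 = np.concatenate([q2, q2[dup_src]]) if n_dup else q2

    contig_col = [names[i] for i in ci] + [names[ci[j]] for j in dup_src]
    start_col = np.concatenate([start_local, start_local[dup_src]])
    end_col = np.concatenate([start_local + flen, (start_local + flen)[dup_src]])
    strand_col = np.concatenate([watson, watson[dup_src]])
    dup_of = [""] * n_unique + [ids[int(j)] for j in dup_src]
    truth = pd.DataFrame(
        {
            "pair_id": ids,
            "contig": contig_col,
            "start": start_col,
            "end": end_col,
            "strand": np.where(strand_col, "W", "C"),
            "duplicate_of": dup_of,
        }
    )
    return ReadPairBatch(ids, r1, qq1, r2, qq2), truth


def replicate_config(base: SimConfig, replicate_id: int, study_seed: int | None = None) -> SimConfig:
    """Per-replicate config: derived read seed, replicate-specific fragments.

    The genome/methylome stay tied to the study seed; only the library
    differs — replicate 1 uses ~200 bp fragments and replicate 2 ~250 bp,
    matching the two sonication batches of the original design.
    """
    seed = base.seed if study_seed is None else study_seed
    derived = int(np.random.SeedSequence([seed, 7000 + replicate_id]).generate_state(1)[0] % (2**31))
    mean = base.fragment_mean if replicate_id == 1 else base.fragment_mean + 50.0
    return replace(base, seed=derived, fragment_mean=mean)
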