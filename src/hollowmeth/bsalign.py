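"""Three-letter bisulfite alignment of paired-end reads.

Because bisulfite treatment converts unmethylated C to T, reads are mapped in
a reduced alphabet: plus-strand (Watson) fragments are C->T transformed and
searched against the C->T reference ("T genome"); minus-strand (Crick)
fragments are G->A transformed and searched against the G->A reference
("A genome"). After placement the original read bases are paired with the
original reference, so a read T over a reference C is a converted
(unmethylated) cytosine observation and a read C over reference C a
potential methylcytosine.

Two search engines share the same pairing/uniqueness logic:

* :class:`KmerIndex` seed-and-extend (three 16-mer seeds per read; with at
  most two mismatches allowed, at least one seed of the first 48 bases is
  exact — pigeonhole), used everywhere;
* :func:`brute_force_candidates`, a full scan of every offset, used as an
  independent oracle on small genomes.

A pair is kept only if a single best-scoring placement (total mismatches
across both mates) exists across both strand rounds; ties are rejected as
multi-mapped, mirroring the "unambiguously mapped" requirement.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import dna
from .dna import A, C, G, N, T

_ALPHABET = set("ACGTN")


@dataclass
class ReferenceSet:
    """Named contig sequences plus the contigs flagged as unmethylated control.

    The control contigs play the lambda spike-in role: fully unmethylated DNA
    whose apparent methylation measures the false-positive rate.
    """

    contigs: dict[str, str]
    control_names: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for name, seq in self.contigs.items():
            s = seq.upper()
            if set(s) - _ALPHABET:
                bad = sorted(set(s) - _ALPHABET)
                raise ValueError(f"contig {name!r} has non-ACGTN characters: {bad}")
            clean[name] = s
        self.contigs = clean
        self.control_names = set(self.control_names)
        unknown = self.control_names - set(self.contigs)
        if unknown:
            raise ValueError(f"control contigs not in reference: {sorted(unknown)}")
        self._codes: dict[str, np.ndarray] = {}

    def codes(self, name: str) -> np.ndarray:
        if name not in self._codes:
            self._codes[name] = dna.seq_to_codes(self.contigs[name])
        return self._codes[name]

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    @property
    def genomic_names(self) -> list[str]:
        return [n for n in self.contigs if n not in self.control_names]

    def length(self, name: str) -> int:
        return len(self.contigs[name])

    def total_length(self, include_control: bool = True) -> int:
        names = self.names if include_control else self.genomic_names
        return sum(len(self.contigs[n]) for n in names)

    @classmethod
    def from_fasta(cls, path, control_names=()) -> "ReferenceSet":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            contigs = {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}
        if not contigs:
            raise ValueError(f"no sequences found in {path}")
        return cls(contigs, set(control_names))

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="unmethylated_control" if name in self.control_names else "")
            for name, seq in self.contigs.items()
        ]
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "wt") as fh:
            SeqIO.write(records, fh, "fasta")


@dataclass
class AlignedFragment:
    """One uniquely placed read pair restored to original base space."""

    pair_id: str
    contig: str
    start: int
    end: int
    bisulfite_strand: str  # "W" (Watson/plus) or "C" (Crick/minus)
    mismatches: int
    unique: bool
    read1_bases: str
    read2_bases: str
    read1_quals: np.ndarray
    read2_quals: np.ndarray


@dataclass
class AlignParams:
    max_mismatches: int = 2
    frag_min: int = 49
    frag_max: int = 400
    seed_length: int = 16

    @classmethod
    def from_fragment_model(cls, mean: float, sd: float, read_length: int = 49) -> "AlignParams":
        # proper-pair window: mean +/- 4 sd, floored at the read length
        return cls(frag_min=max(read_length, int(mean - 4 * sd)), frag_max=int(mean + 4 * sd))


class KmerIndex:
    """Sorted-array exact k-mer index over a concatenated code genome."""

    def __init__(self, codes: np.ndarray, k: int):
        self.k = k
        self.powers = (5 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
        n = len(codes) - k + 1
        h = np.zeros(n, dtype=np.uint64)
        for j in range(k):
            h = h * np.uint64(5) + codes[j : n + j].astype(np.uint64)
        order = np.argsort(h, kind="stable")
        self.sorted_hashes = h[order]
        self.sorted_pos = order.astype(np.int64)

    def hash_reads(self, reads: np.ndarray, offset: int) -> np.ndarray:
        """Hash the k-mer starting at `offset` of every read row."""
        h = np.zeros(len(reads), dtype=np.uint64)
        for j in range(self.k):
            h = h * np.uint64(5) + reads[:, offset + j].astype(np.uint64)
        return h

    def ranges(self, hashes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = np.searchsorted(self.sorted_hashes, hashes, side="left")
        hi = np.searchsorted(self.sorted_hashes, hashes, side="right")
        return lo, hi


class ConvertedReferences:
    """The reference plus its C->T and G->A three-letter views, indexed.

    Contigs are concatenated with N spacers into one coordinate space; the
    spacers and an explicit same-contig containment check prevent placements
    that straddle contig boundaries.
    """

    SPACER = 60

    def __init__(self, ref: ReferenceSet, seed_length: int = 16):
        self.ref = ref
        names = ref.names
        parts = []
        starts = []
        pos = 0
        for name in names:
            starts.append(pos)
            parts.append(ref.codes(name))
            pos += ref.length(name)
            parts.append(np.full(self.SPACER, N, dtype=np.uint8))
            pos += self.SPACER
        self.names = names
        self.starts = np.array(starts, dtype=np.int64)
        self.ends = self.starts + np.array([ref.length(n) for n in names], dtype=np.int64)
        self.original = np.concatenate(parts)
        self.t_genome = dna.ct_transform(self.original)
        self.a_genome = dna.ga_transform(self.original)
        self.t_index = KmerIndex(self.t_genome, seed_length)
        self.a_index = KmerIndex(self.a_genome, seed_length)

    def contig_span(self, pos: int, length: int) -> int:
        """Index of the contig fully containing [pos, pos+length), or -1."""
        i = int(np.searchsorted(self.starts, pos, side="right")) - 1
        if i < 0:
            return -1
        if pos >= self.starts[i] and pos + length <= self.ends[i]:
            return i
        return -1


def build_converted_references(ref: ReferenceSet, seed_length: int = 16) -> ConvertedReferences:
    """Build the "T genome" (C->T) and "A genome" (G->A) with their indexes."""
    return ConvertedReferences(ref, seed_length=seed_length)


class AlignmentSet:
    """A batch of aligned pairs: a coordinate table plus original read arrays.

    `df` columns: pair_id, contig, start, end, strand ("W"/"C"), mm, unique.
    Row i of the read arrays (as-sequenced base codes and Phred scores)
    corresponds to row i of `df`.
    """

    def __init__(self, df: pd.DataFrame, r1, q1, r2, q2, n_input_pairs: int | None = None):
        self.df = df.reset_index(drop=True)
        self.r1, self.q1, self.r2, self.q2 = r1, q1, r2, q2
        self.n_input_pairs = len(df) if n_input_pairs is None else n_input_pairs

    def __len__(self) -> int:
        return len(self.df)

    def select(self, mask) -> "AlignmentSet":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return AlignmentSet(
            self.df.iloc[idx], self.r1[idx], self.q1[idx], self.r2[idx], self.q2[idx],
            n_input_pairs=self.n_input_pairs,
        )

    def fragment(self, i: int) -> AlignedFragment:
        row = self.df.iloc[i]
        return AlignedFragment(
            pair_id=row["pair_id"], contig=row["contig"], start=int(row["start"]), end=int(row["end"]),
            bisulfite_strand=row["strand"], mismatches=int(row["mm"]), unique=bool(row["unique"]),
            read1_bases=dna.codes_to_seq(self.r1[i]), read2_bases=dna.codes_to_seq(self.r2[i]),
            read1_quals=self.q1[i].copy(), read2_quals=self.q2[i].copy(),
        )

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out["r1_seq"] = [dna.codes_to_seq(r) for r in self.r1]
        out["r1_qual"] = [dna.quals_to_ascii(q) for q in self.q1]
        out["r2_seq"] = [dna.codes_to_seq(r) for r in self.r2]
        out["r2_qual"] = [dna.quals_to_ascii(q) for q in self.q2]
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AlignmentSet":
        df = pd.read_csv(path, sep="\t", dtype={"pair_id": str, "contig": str, "strand": str})
        if len(df):
            r1 = np.stack([dna.seq_to_codes(s) for s in df.pop("r1_seq")])
            q1 = np.stack([dna.ascii_to_quals(s) for s in df.pop("r1_qual")])
            r2 = np.stack([dna.seq_to_codes(s) for s in df.pop("r2_seq")])
            q2 = np.stack([dna.ascii_to_quals(s) for s in df.pop("r2_qual")])
        else:
            for col in ("r1_seq", "r1_qual", "r2_seq", "r2_qual"):
                df.pop(col, None)
            r1 = q1 = r2 = q2 = np.zeros((0, 0), dtype=np.uint8)
        return cls(df, r1, q1, r2, q2)


def _mismatches(genome: np.ndarray, pos: int, read_row: np.ndarray, limit: int) -> int:
    """Mismatch count of read_row against genome[pos:]; N never matches N."""
    g = genome[pos : pos + read_row.shape[0]]
    neq = g != read_row
    both_n = (g == N) & (read_row == N)
    m = int(np.count_nonzero(neq | both_n))
    return m


def _seed_offsets(read_length: int, k: int) -> list[int]:
    # three non-overlapping seeds; with <=2 mismatches one of them is exact
    return [0, k, 2 * k] if read_length >= 3 * k else [0]


def brute_force_candidates(genome: np.ndarray, read_row: np.ndarray, max_mm: int) -> list[tuple[int, int]]:
    """All (position, mismatches) placements with <= max_mm, by full scan."""
    L = read_row.shape[0]
    n = len(genome) - L + 1
    if n <= 0:
        return []
    mm = np.zeros(n, dtype=np.int32)
    for j in range(L):
        col = genome[j : n + j]
        mm += (col != read_row[j]) | ((col == N) & (read_row[j] == N))
    hits = np.flatnonzero(mm <= max_mm)
    return [(int(p), int(mm[p])) for p in hits]


class _BatchSeedLookup:
    """Precomputed seed ranges for all reads of a batch against one index."""

    def __init__(self, index: KmerIndex, reads: np.ndarray, offsets: list[int]):
        self.index = index
        self.offsets = offsets
        self.lo = []
        self.hi = []
        for off in offsets:
            lo, hi = index.ranges(index.hash_reads(reads, off))
            self.lo.append(lo)
            self.hi.append(hi)

    def candidates(self, i: int) -> set[int]:
        cands: set[int] = set()
        pos = self.index.sorted_pos
        for s, off in enumerate(self.offsets):
            lo, hi = self.lo[s][i], self.hi[s][i]
            if hi > lo:
                cands.update(int(p) - off for p in pos[lo:hi])
        return cands


def _combine_mates(left_hits, right_hits, strand, conv, read_length, params, out):
    for pl, mml in left_hits:
        for pr, mmr in right_hits:
            flen = pr + read_length - pl
            if flen < params.frag_min or flen > params.frag_max:
                continue
            ci = conv.contig_span(pl, flen)
            if ci < 0:
                continue
            out.append((mml + mmr, pl, pr + read_length, strand, ci))


def align_pairs(
    r1: np.ndarray,
    q1: np.ndarray,
    r2: np.ndarray,
    q2: np.ndarray,
    conv: ConvertedReferences,
    params: AlignParams | None = None,
    pair_ids=None,
    engine: str = "seed",
) -> AlignmentSet:
    """Align a batch of read pairs; returns mapped pairs with a unique flag.

    Pairs with no acceptable placement are dropped (counted via
    ``n_input_pairs``); pairs whose best score is tied across placements are
    kept with ``unique=False`` so the multi-mapper filter can report them.
    """
    params = params or AlignParams()
    n = len(r1)
    if r1.shape != q1.shape or r2.shape != q2.shape or len(r2) != n:
        raise ValueError("read/quality arrays are inconsistent")
    read_length = r1.shape[1] if n else 0
    if n and read_length < 20:
        raise ValueError("reads shorter than 20 bp are not supported")
    if pair_ids is None:
        pair_ids = [f"p{i:07d}" for i in range(n)]

    # Watson round: both mates C->T against the T genome.
    # Crick round: both mates G->A against the A genome. In each round the
    # "left" mate is the one running forward from the fragment start and the
    # "right" mate the reverse-complemented one at the fragment end.
    left_w = dna.ct_transform(r1)
    right_w = dna.ct_transform(dna.revcomp_codes(r2))
    left_c = dna.ga_transform(r2)
    right_c = dna.ga_transform(dna.revcomp_codes(r1))

    if engine == "seed":
        offsets = _seed_offsets(read_length, conv.t_index.k)
        luts = {
            "lw": _BatchSeedLookup(conv.t_index, left_w, offsets),
            "rw": _BatchSeedLookup(conv.t_index, right_w, offsets),
            "lc": _BatchSeedLookup(conv.a_index, left_c, offsets),
            "rc": _BatchSeedLookup(conv.a_index, right_c, offsets),
        }

        def hits(key, i, row, genome):
            out = []
            for p in luts[key].candidates(i):
                if p < 0 or p + read_length > len(genome):
                    continue
                m = _mismatches(genome, p, row, params.max_mismatches)
                if m <= params.max_mismatches:
                    out.append((p, m))
            return out

    elif engine == "brute":

        def hits(key, i, row, genome):
            return brute_force_candidates(genome, row, params.max_mismatches)

    else:
        raise ValueError(f"unknown engine {engine!r}")

    rows = []
    keep_idx = []
    for i in range(n):
        cands: list[tuple[int, int, int, str, int]] = []
        lw = hits("lw", i, left_w[i], conv.t_genome)
        if lw:
            rw = hits("rw", i, right_w[i], conv.t_genome)
            _combine_mates(lw, rw, "W", conv, read_length, params, cands)
        lc = hits("lc", i, left_c[i], conv.a_genome)
        if lc:
            rc = hits("rc", i, right_c[i], conv.a_genome)
            _combine_mates(lc, rc, "C", conv, read_length, params, cands)
        if not cands:
            continue
        # deterministic representative: lowest score, then leftmost span, W<C
        cands.sort()
        best = cands[0][0]
        top = [c for c in cands if c[0] == best]
        mm, s, e, strand, ci = top[0]
        unique = len(top) == 1
        off = int(conv.starts[ci])
        rows.append((pair_ids[i], conv.names[ci], s - off, e - off, strand, mm, unique))
        keep_idx.append(i)

    df = pd.DataFrame(rows, columns=["pair_id", "contig", "start", "end", "strand", "mm", "unique"])
    if not keep_idx:
        shape = (0, read_length)
        return AlignmentSet(df, np.zeros(shape, np.uint8), np.zeros(shape, np.uint8),
                            np.zeros(shape, np.uint8), np.zeros(shape, np.uint8), n_input_pairs=n)
    idx = np.array(keep_idx)
    return AlignmentSet(df, r1[idx].copy(), q1[idx].copy(), r2[idx].copy(), q2[idx].copy(), n_input_pairs=n)


def align_pair(
    read1: str, quals1: np.ndarray, read2: str, quals2: np.ndarray,
    conv: ConvertedReferences, params: AlignParams | None = None,
    pair_id: str = "pair", engine: str = "seed",
) -> AlignedFragment | None:
    """Align a single pair; None if unmapped, unique=False if multi-mapped."""
    if len(read1) != len(quals1) or len(read2) != len(quals2):
        raise ValueError("base/quality length mismatch")
    r1 = dna.seq_to_codes(read1)[None, :]
    r2 = dna.seq_to_codes(read2)[None, :]
    q1 = np.asarray(quals1, dtype=np.uint8)[None, :]
    q2 = np.asarray(quals2, dtype=np.uint8)[None, :]
    out = align_pairs(r1, q1, r2, q2, conv, params, pair_ids=[pair_id], engine=engine)
    if len(out) == 0:
        return None
    return out.fragment(0)


def restore_alignment(fragment: AlignedFragment, ref: ReferenceSet) -> tuple[str, str]:
    """Original-space alignment columns for a placed fragment.

    Returns (reference_segment, fragment_strand); read bases are already held
    untransformed in the fragment, so restoration is the identity on
    coordinates — the three-letter substitutions are length-preserving.
    """
    seg = ref.contigs[fragment.contig][fragment.start : fragment.end]
    return seg, fragment.bisulfite_strand
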