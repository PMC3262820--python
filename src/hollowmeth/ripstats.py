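"""RIP-index statistics over repeat intervals.

RIP (repeat-induced point mutation) converts C->T in duplicated fungal
sequences, enriching TpA dinucleotides; the RIP index is the ratio of
overlapping TpA to ApT counts over a repeat copy. Only repeats of at least
400 bp are scored (shorter homologies are poor RIP substrates). TA and AT
are each self-complementary as dinucleotide classes, so the index is
strand-independent and is computed on the Watson sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bsalign import ReferenceSet


@dataclass
class RepeatInterval:
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.contig}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RIPDistribution:
    species_label: str
    indices: list[float] = field(default_factory=list)
    n_excluded_short: int = 0
    n_excluded_zero_denominator: int = 0


def _dinucleotide_count(seq: str, dinuc: str) -> int:
    # overlapping count; for dinucleotides with two distinct letters
    # occurrences cannot overlap, so str.count is exact
    return seq.count(dinuc)


def rip_index(sequence: str, composite: bool = False) -> float | None:
    """TpA/ApT ratio of a sequence; None when the denominator is zero.

    With ``composite=True``, returns the alternative
    (CpA + TpG) / (ApC + GpT) form instead.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must be at least 2 bp")
    s = sequence.upper()
    if composite:
        num = _dinucleotide_count(s, "CA") + _dinucleotide_count(s, "TG")
        den = _dinucleotide_count(s, "AC") + _dinucleotide_count(s, "GT")
    else:
        num = _dinucleotide_count(s, "TA")
        den = _dinucleotide_count(s, "AT")
    if den == 0:
        return None
    return num / den


def rip_distribution(
    ref: ReferenceSet,
    repeats: list[RepeatInterval],
    min_len: int = 400,
    species_label: str = "",
    composite: bool = False,
) -> RIPDistribution:
    """Per-repeat RIP indices for intervals of length >= min_len.

    Shorter intervals and zero-denominator intervals are excluded but
    counted. Intervals outside contig bounds raise (malformed BED).
    """
    dist = RIPDistribution(species_label)
    for iv in repeats:
        if iv.contig not in ref.contigs:
            raise ValueError(f"repeat on unknown contig {iv.contig!r}")
        if iv.start < 0 or iv.end > ref.length(iv.contig):
            raise ValueError(f"repeat {iv.contig}:{iv.start}-{iv.end} outside contig bounds")
        if iv.length < min_len:
            dist.n_excluded_short += 1
            continue
        idx = rip_index(ref.contigs[iv.contig][iv.start : iv.end], composite=composite)
        if idx is None:
            dist.n_excluded_zero_denominator += 1
        else:
            dist.indices.append(idx)
    return dist


def rip_ttest(a: RIPDistribution, b: RIPDistribution) -> tuple[float, float]:
    """Two-sample two-tailed Welch t-test on per-repeat indices."""
    if len(a.indices) < 2 or len(b.indices) < 2:
        raise ValueError("each distribution needs at least 2 indices for a t-test")
    t, p = stats.ttest_ind(a.indices, b.indices, equal_var=False)
    return float(t), float(p)


def repeat_content_test(
    genome_a: tuple[int, int], genome_b: tuple[int, int]
) -> tuple[float, float, float, float]:
    """Pearson chi-square (1 df, no continuity correction) on repeat content.

    Inputs are (repeat_bp, total_bp) per genome; the 2x2 table is repeat vs
    non-repeat bp by genome. Returns (statistic, pvalue, fraction_a,
    fraction_b).
    """
    (ra, ta), (rb, tb) = genome_a, genome_b
    if ta <= 0 or tb <= 0:
        raise ValueError("total_bp must be positive")
    if not (0 <= ra <= ta and 0 <= rb <= tb):
        raise ValueError("repeat_bp must lie in [0, total_bp]")
    table = np.array([[ra, ta - ra], [rb, tb - rb]], dtype=np.float64)
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        # degenerate margin: identical all-or-nothing content
        return 0.0, 1.0, ra / ta, rb / tb
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), float(res.pvalue), ra / ta, rb / tb


def load_repeats_bed(path) -> list[RepeatInterval]:
    """Read BED3+ repeat intervals (extra columns ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(RepeatInterval(f[0], int(f[1]), int(f[2])))
    return out


def rip_table(dists: list[RIPDistribution]) -> pd.DataFrame:
    """Summary table plus the pairwise Welch t-test p-value matrix."""
    summary = pd.DataFrame(
        {
            "species": [d.species_label for d in dists],
            "n_repeats": [len(d.indices) for d in dists],
            "mean_rip_index": [float(np.mean(d.indices)) if d.indices else np.nan for d in dists],
            "median_rip_index": [float(np.median(d.indices)) if d.indices else np.nan for d in dists],
            "n_excluded_short": [d.n_excluded_short for d in dists],
            "n_excluded_zero_denominator": [d.n_excluded_zero_denominator for d in dists],
        }
    )
    return summary
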