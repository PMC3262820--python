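"""Pre-call filtration of aligned fragments.

Three rules, applied in order: drop multi-mapped pairs, collapse clonal
PCR duplicates (pairs sharing fragment start, end and bisulfite strand),
and mask individual bases below Q20 so they contribute no cytosine
observation. Masking is per-base, not per-read: the quality rule filters
cytosine observations, not fragments.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .bsalign import AlignmentSet
from .dna import N


@dataclass
class FilterReport:
    n_input_pairs: int = 0
    n_multi_removed: int = 0
    n_clonal_removed: int = 0
    n_retained: int = 0
    n_bases_masked_lowq: int = 0

    def check_partition(self) -> None:
        if self.n_input_pairs != self.n_multi_removed + self.n_clonal_removed + self.n_retained:
            raise AssertionError(f"filter accounting does not partition: {self}")
        if min(asdict(self).values()) < 0:
            raise AssertionError(f"negative filter count: {self}")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def drop_multimapped(aln: AlignmentSet) -> tuple[AlignmentSet, int]:
    """Keep only unambiguously mapped pairs."""
    keep = aln.df["unique"].to_numpy(dtype=bool)
    return aln.select(keep), int((~keep).sum())


def remove_clonal_duplicates(aln: AlignmentSet) -> tuple[AlignmentSet, int]:
    """Collapse pairs sharing (contig, start, end, strand) to one.

    The representative is the pair with the highest summed base quality,
    ties broken by lexicographically smallest pair_id — a deterministic
    stand-in for an unspecified choice.
    """
    if len(aln) == 0:
        return aln, 0
    df = aln.df.copy()
    df["_qsum"] = aln.q1.sum(axis=1, dtype=np.int64) + aln.q2.sum(axis=1, dtype=np.int64)
    order = df.sort_values(
        ["contig", "start", "end", "strand", "_qsum", "pair_id"],
        ascending=[True, True, True, True, False, True],
        kind="mergesort",
    )
    keep_rows = order.drop_duplicates(["contig", "start", "end", "strand"], keep="first")
    keep_idx = np.sort(keep_rows.index.to_numpy())
    removed = len(aln) - len(keep_idx)
    return aln.select(keep_idx), removed


def mask_low_quality(aln: AlignmentSet, q_min: int = 20) -> tuple[AlignmentSet, int]:
    """Mask read bases with Phred < q_min (strictly below: Q20 is kept)."""
    out = aln.select(np.arange(len(aln)))  # copy arrays via fancy index
    masked = 0
    for reads, quals in ((out.r1, out.q1), (out.r2, out.q2)):
        low = (quals < q_min) & (reads != N)
        masked += int(low.sum())
        reads[low] = N
    return out, masked


def apply_filters(aln: AlignmentSet, q_min: int = 20) -> tuple[AlignmentSet, FilterReport]:
    """Full filtration pipeline with its accounting report.

    ``n_input_pairs`` counts pairs that produced an alignment record; the
    unmapped remainder never enters the table.
    """
    uniq, n_multi = drop_multimapped(aln)
    dedup, n_clonal = remove_clonal_duplicates(uniq)
    masked, n_masked = mask_low_quality(dedup, q_min=q_min)
    report = FilterReport(
        n_input_pairs=len(aln),
        n_multi_removed=n_multi,
        n_clonal_removed=n_clonal,
        n_retained=len(masked),
        n_bases_masked_lowq=n_masked,
    )
    report.check_partition()
    return masked, report
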