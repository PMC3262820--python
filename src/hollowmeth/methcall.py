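"""Per-cytosine pileups, conversion-rate estimation and methylcytosine calls.

A cytosine observation is strand-specific: Watson-strand fragments report on
reference C positions (read C = potential 5mC, read T = converted), Crick
fragments on reference G positions (read G = potential 5mC, read A =
converted). The spike-in control contig measures the false-positive rate
p (non-conversion plus T->C sequencing error); each site with depth n and
unconverted count k is then tested against Binomial(n, p) with the exact
one-sided tail P(X >= k), at significance threshold q (default 0.01) and
minimum depth 10. True methylcytosines are required to be called in both
biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .bsalign import AlignmentSet, ReferenceSet
from .dna import A, C, G, N, T

CONTEXT2_CLASSES = ("CG", "CA", "CT", "CC")
CONTEXT3_CLASSES = ("CG", "CHG", "CHH")


@dataclass
class CytosinePileup:
    """Counts at one reference cytosine: depth n and unconverted k."""

    contig: str
    position: int
    strand: str
    context2: str
    context3: str
    depth: int
    unconverted: int

    def __post_init__(self) -> None:
        if not 0 <= self.unconverted <= self.depth:
            raise ValueError("unconverted count must lie in [0, depth]")


@dataclass
class CallerConfig:
    """Binomial-caller parameters.

    ``false_positive_rate`` is estimated per replicate from that replicate's
    unmethylated control. ``correction_mode`` chooses between the literal
    per-site threshold (pvalue < q) and step-up FDR control at level q.
    """

    false_positive_rate: float
    significance_threshold: float = 0.01
    min_depth: int = 10
    correction_mode: str = "per_site"

    def __post_init__(self) -> None:
        if not 0.0 < self.false_positive_rate < 1.0:
            raise ValueError("false_positive_rate must be in (0, 1)")
        if not 0.0 < self.significance_threshold < 1.0:
            raise ValueError("significance_threshold must be in (0, 1)")
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.correction_mode not in ("per_site", "fdr_step"):
            raise ValueError("correction_mode must be 'per_site' or 'fdr_step'")


@dataclass
class MethylCall:
    contig: str
    position: int
    strand: str
    level: float
    pvalue: float
    passed: bool


def _context_codes_plus(codes: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    L = len(codes)
    nxt = np.where(pos + 1 < L, codes[np.minimum(pos + 1, L - 1)], N)
    nxt2 = np.where(pos + 2 < L, codes[np.minimum(pos + 2, L - 1)], N)
    return nxt, nxt2


def _context_codes_minus(codes: np.ndarray, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    comp = np.array([T, G, C, A, N], dtype=np.uint8)
    nxt = np.where(pos - 1 >= 0, comp[codes[np.maximum(pos - 1, 0)]], N)
    nxt2 = np.where(pos - 2 >= 0, comp[codes[np.maximum(pos - 2, 0)]], N)
    return nxt, nxt2


_CTX2 = {A: "CA", C: "CC", G: "CG", T: "CT", N: "CN"}


def _context_labels(nxt: np.ndarray, nxt2: np.ndarray) -> tuple[list[str], list[str]]:
    ctx2 = [_CTX2[int(b)] for b in nxt]
    h = (nxt == A) | (nxt == C) | (nxt == T)
    ctx3 = np.where(
        nxt == G, "CG",
        np.where(h & (nxt2 == G), "CHG", np.where(h & (nxt2 != N), "CHH", "CN")),
    )
    return ctx2, list(ctx3)


def pileup(aln: AlignmentSet, ref: ReferenceSet) -> pd.DataFrame:
    """Per-cytosine, per-strand counts over every reference cytosine.

    Fragments shorter than two read lengths have overlapping mates; mate-2
    bases falling inside mate-1's window are dropped so each molecule
    position is counted once. Masked (N) and mismatching bases contribute
    nothing.
    """
    L = aln.r1.shape[1] if len(aln) else 0
    frames = []
    groups = dict(iter(aln.df.groupby("contig", sort=False))) if len(aln) else {}
    for name in ref.names:
        codes = ref.codes(name)
        clen = len(codes)
        depth = {"+": np.zeros(clen, np.int32), "-": np.zeros(clen, np.int32)}
        unconv = {"+": np.zeros(clen, np.int32), "-": np.zeros(clen, np.int32)}
        g = groups.get(name)
        if g is not None and len(g):
            idx = g.index.to_numpy()
            start = g["start"].to_numpy(np.int64)
            end = g["end"].to_numpy(np.int64)
            watson = (g["strand"] == "W").to_numpy()
            ar = np.arange(L)
            r1 = aln.r1[idx]
            r2 = aln.r2[idx]
            from .dna import revcomp_codes

            # watson-sense observation codes and their reference positions
            obs1 = np.where(watson[:, None], r1, revcomp_codes(r1))
            pos1 = np.where(watson[:, None], start[:, None] + ar, end[:, None] - L + ar)
            obs2 = np.where(watson[:, None], revcomp_codes(r2), r2)
            pos2 = np.where(watson[:, None], end[:, None] - L + ar, start[:, None] + ar)
            # drop mate-2 bases inside mate-1's window (short fragments)
            keep2 = np.where(watson[:, None], pos2 >= start[:, None] + L, pos2 < end[:, None] - L)

            for obs, pos, keep in ((obs1, pos1, None), (obs2, pos2, keep2)):
                for strand, refbase, unconv_base, conv_base in (
                    ("+", C, C, T),
                    ("-", G, G, A),
                ):
                    sel = (watson[:, None] if strand == "+" else ~watson[:, None]) & (
                        codes[pos] == refbase
                    )
                    if keep is not None:
                        sel = sel & keep
                    counted = sel & ((obs == unconv_base) | (obs == conv_base))
                    np.add.at(depth[strand], pos[counted], 1)
                    hit = sel & (obs == unconv_base)
                    np.add.at(unconv[strand], pos[hit], 1)

        for strand, refbase in (("+", C), ("-", G)):
            pos = np.flatnonzero(codes == refbase)
            if strand == "+":
                nxt, nxt2 = _context_codes_plus(codes, pos)
            else:
                nxt, nxt2 = _context_codes_minus(codes, pos)
            ctx2, ctx3 = _context_labels(nxt, nxt2)
            frames.append(
                pd.DataFrame(
                    {
                        "contig": name,
                        "position": pos,
                        "strand": strand,
                        "context2": ctx2,
                        "context3": ctx3,
                        "depth": depth[strand][pos],
                        "unconverted": unconv[strand][pos],
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["contig", "position", "strand", "context2", "context3", "depth", "unconverted"]
    )
    return out.sort_values(["contig", "position", "strand"], kind="mergesort").reset_index(drop=True)


def conversion_rate(pile: pd.DataFrame, control_names: set[str]) -> float:
    """Bisulfite conversion rate in percent from the unmethylated control.

    100 x (1 - unconverted/total) over all control-contig cytosine
    observations; its complement is the caller's false-positive rate.
    """
    sub = pile[pile["contig"].isin(control_names)]
    n = int(sub["depth"].sum())
    if n == 0:
        raise ValueError("no cytosine observations on the control contigs")
    k = int(sub["unconverted"].sum())
    return 100.0 * (1.0 - k / n)


def global_methylation_level(
    pile: pd.DataFrame, context2: str | None = None, context3: str | None = None
) -> float:
    """Unconverted / total cytosine observations, optionally per context."""
    sub = pile
    if context2 is not None:
        sub = sub[sub["context2"] == context2]
    if context3 is not None:
        sub = sub[sub["context3"] == context3]
    n = int(sub["depth"].sum())
    if len(sub) == 0 or n == 0:
        raise ValueError("no cytosine observations match the requested context")
    return float(sub["unconverted"].sum() / n)


def binomial_pvalues(k: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    """Exact one-sided binomial tail P(X >= k) for X ~ Binomial(n, p)."""
    return stats.binom.sf(np.asarray(k) - 1, np.asarray(n), p)


def call_methylation(pile: pd.DataFrame, cfg: CallerConfig) -> pd.DataFrame:
    """Apply the binomial correction to a pileup table.

    Sites below ``min_depth`` are never tested (pvalue recorded as 1). In
    ``per_site`` mode a site passes when pvalue < q; in ``fdr_step`` mode
    Benjamini-Hochberg is applied across all tested sites at level q.
    """
    out = pile.copy()
    n = out["depth"].to_numpy(np.int64)
    k = out["unconverted"].to_numpy(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["level"] = np.where(n > 0, k / np.maximum(n, 1), 0.0)
    tested = n >= cfg.min_depth
    pvals = np.ones(len(out))
    pvals[tested] = binomial_pvalues(k[tested], n[tested], cfg.false_positive_rate)
    out["pvalue"] = pvals
    if cfg.correction_mode == "per_site":
        passed = tested & (pvals < cfg.significance_threshold)
    else:
        passed = tested.copy()
        if tested.any():
            adj = stats.false_discovery_control(pvals[tested], method="bh")
            passed[tested] = adj <= cfg.significance_threshold
    out["passed"] = passed
    return out


def binomial_call(site: CytosinePileup, cfg: CallerConfig) -> MethylCall:
    """Single-site form of :func:`call_methylation` (per-site mode)."""
    if site.depth < cfg.min_depth:
        pvalue, passed = 1.0, False
    else:
        pvalue = float(binomial_pvalues(np.array([site.unconverted]), np.array([site.depth]), cfg.false_positive_rate)[0])
        passed = pvalue < cfg.significance_threshold
    level = site.unconverted / site.depth if site.depth else 0.0
    return MethylCall(site.contig, site.position, site.strand, level, pvalue, passed)


def overlap_replicates(calls_rep1: pd.DataFrame, calls_rep2: pd.DataFrame) -> pd.DataFrame:
    """Sites called methylated in both biological replicates."""
    keys = ["contig", "position", "strand"]
    a = calls_rep1.loc[calls_rep1["passed"], keys]
    b = calls_rep2.loc[calls_rep2["passed"], keys]
    return a.merge(b, on=keys).reset_index(drop=True)


def table_levels(pile: pd.DataFrame, control_names: set[str]) -> pd.DataFrame:
    """Global methylation level (%) per dinucleotide class, sample vs control.

    The defined-context classes partition all observations except CN sites
    (contig edges), which appear only in the overall "C" column.
    """
    rows = {}
    for label, sub in (
        ("sample", pile[~pile["contig"].isin(control_names)]),
        ("control", pile[pile["contig"].isin(control_names)]),
    ):
        row = {}
        total_n = int(sub["depth"].sum())
        row["C"] = 100.0 * sub["unconverted"].sum() / total_n if total_n else np.nan
        for ctx in CONTEXT2_CLASSES:
            s = sub[sub["context2"] == ctx]
            n = int(s["depth"].sum())
            row[ctx] = 100.0 * s["unconverted"].sum() / n if n else np.nan
        rows[label] = row
    return pd.DataFrame(rows).T[["C", *CONTEXT2_CLASSES]]


def summarize_replicate(calls: pd.DataFrame, pile: pd.DataFrame, control_names: set[str] = frozenset()) -> dict:
    """Call counts per context, level histogram of passed calls, and the
    per-class global-level table."""
    passed = calls[calls["passed"]]
    ctx_counts = {ctx: int((passed["context3"] == ctx).sum()) for ctx in CONTEXT3_CLASSES}
    hist, edges = np.histogram(passed["level"], bins=np.arange(0.0, 1.05, 0.05))
    return {
        "n_passed": int(len(passed)),
        "calls_per_context3": ctx_counts,
        "level_histogram": {"edges": edges.tolist(), "counts": hist.tolist()},
        "global_levels_pct": table_levels(pile, set(control_names)).to_dict(orient="index"),
    }
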