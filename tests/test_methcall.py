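"""Pileup construction, conversion rate, binomial caller, replicate overlap."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hollowmeth import (
    CallerConfig,
    CytosinePileup,
    ReferenceSet,
    apply_filters,
    binomial_call,
    call_methylation,
    conversion_rate,
    global_methylation_level,
    overlap_replicates,
    pileup,
    summarize_replicate,
    table_levels,
)
from hollowmeth.bsalign import AlignmentSet, AlignParams, align_pairs, build_converted_references
from hollowmeth import dna

from conftest import make_perfect_pair


def enumeration_tail(k: int, n: int, p: float) -> float:
    """Independent oracle: P(X >= k) for X~Binomial(n,p) by exact enumeration."""
    pf = Fraction(p)
    total = sum(comb(n, j) * pf**j * (1 - pf) ** (n - j) for j in range(k, n + 1))
    return float(total)


def _aligned_stack(ref, pairs):
    """Align hand-built perfect pairs into an AlignmentSet."""
    conv = build_converted_references(ref)
    params = AlignParams(frag_min=100, frag_max=300)
    r1 = np.stack([dna.seq_to_codes(p[0]) for p in pairs])
    q1 = np.stack([p[1] for p in pairs])
    r2 = np.stack([dna.seq_to_codes(p[2]) for p in pairs])
    q2 = np.stack([p[3] for p in pairs])
    return align_pairs(r1, q1, r2, q2, conv, params)


def test_pileup_fully_converted_watson_site(random_ref):
    seq = random_ref.contigs["chr1"]
    pairs = [make_perfect_pair(seq, 1000, 200) for _ in range(10)]
    aln = _aligned_stack(random_ref, pairs)
    assert len(aln) == 10
    pile = pileup(aln, random_ref)
    read1_span = pile[(pile.contig == "chr1") & (pile.position >= 1000)
                      & (pile.position < 1049) & (pile.strand == "+")]
    covered = read1_span[read1_span.depth > 0]
    assert (covered.depth == 10).all()
    assert (covered.unconverted == 0).all()


def test_pileup_methylated_crick_site_counts_guanines(random_ref):
    seq = random_ref.contigs["chr1"]
    pairs = [make_perfect_pair(seq, 600, 200, strand="C", methylated=True) for _ in range(6)]
    aln = _aligned_stack(random_ref, pairs)
    pile = pileup(aln, random_ref)
    span = pile[(pile.contig == "chr1") & (pile.position >= 751) & (pile.position < 800)
                & (pile.strand == "-") & (pile.depth > 0)]
    assert len(span) > 0
    assert (span.unconverted == span.depth).all()


def test_contexts_on_acgt_reference():
    ref = ReferenceSet({"c": "ACGT"})
    empty = AlignmentSet(
        pd.DataFrame(columns=["pair_id", "contig", "start", "end", "strand", "mm", "unique"]),
        *(np.zeros((0, 0), np.uint8),) * 4,
    )
    pile = pileup(empty, ref)
    plus = pile[(pile.strand == "+")].iloc[0]
    assert plus.position == 1 and plus.context2 == "CG" and plus.context3 == "CG"
    minus = pile[(pile.strand == "-")].iloc[0]
    assert minus.position == 2 and minus.context2 == "CG" and minus.context3 == "CG"


def test_context_at_contig_edges_is_cn():
    ref = ReferenceSet({"c": "AAC"})  # plus-strand C at the last position
    empty = AlignmentSet(
        pd.DataFrame(columns=["pair_id", "contig", "start", "end", "strand", "mm", "unique"]),
        *(np.zeros((0, 0), np.uint8),) * 4,
    )
    pile = pileup(empty, ref)
    plus = pile[pile.strand == "+"].iloc[0]
    assert plus.context2 == "CN" and plus.context3 == "CN"


def test_conversion_rate_arithmetic():
    pile = pd.DataFrame({
        "contig": ["lambda_control"] * 2, "position": [1, 2], "strand": ["+", "+"],
        "context2": ["CA", "CT"], "context3": ["CHH", "CHH"],
        "depth": [600, 400], "unconverted": [3, 2],
    })
    assert conversion_rate(pile, {"lambda_control"}) == pytest.approx(99.5)
    zero = pile.assign(unconverted=0, depth=[6000, 4000])
    assert conversion_rate(zero, {"lambda_control"}) == 100.0
    with pytest.raises(ValueError, match="control"):
        conversion_rate(pile.assign(depth=0), {"lambda_control"})


def test_global_level_context_decomposition(small_sim, small_alignment):
    _, ref, _, _, _, _ = small_sim
    filtered, _ = apply_filters(small_alignment)
    pile = pileup(filtered, ref)
    genomic = pile[~pile.contig.isin(ref.control_names)]
    overall = global_methylation_level(genomic)
    # overall level is the depth-weighted mean over dinucleotide classes
    num = den = 0.0
    for ctx in ("CG", "CA", "CT", "CC", "CN"):
        sub = genomic[genomic.context2 == ctx]
        if sub.depth.sum() == 0:
            continue
        num += global_methylation_level(genomic, context2=ctx) * sub.depth.sum()
        den += sub.depth.sum()
    assert overall == pytest.approx(num / den)
    with pytest.raises(ValueError, match="context"):
        global_methylation_level(genomic.iloc[0:0])


@pytest.mark.parametrize("p", [0.001, 0.005, 0.01, 0.05])
def test_binomial_tail_against_enumeration_oracle(p):
    cfg = CallerConfig(false_positive_rate=p, min_depth=1)
    for n in (1, 5, 10, 30):
        for k in range(n + 1):
            call = binomial_call(CytosinePileup("c", 0, "+", "CG", "CG", n, k), cfg)
            expected = enumeration_tail(k, n, p)
            assert call.pvalue == pytest.approx(expected, rel=1e-12)


def test_all_unconverted_site_passes_with_closed_form_pvalue():
    cfg = CallerConfig(false_positive_rate=0.005)
    call = binomial_call(CytosinePileup("c", 0, "+", "CG", "CG", 10, 10), cfg)
    assert call.pvalue == pytest.approx(0.005**10, rel=1e-12)
    assert call.passed and call.level == 1.0


def test_zero_unconverted_never_passes():
    cfg = CallerConfig(false_positive_rate=0.005)
    call = binomial_call(CytosinePileup("c", 0, "+", "CG", "CG", 50, 0), cfg)
    assert call.pvalue == 1.0 and not call.passed


def test_below_min_depth_recorded_as_untested():
    cfg = CallerConfig(false_positive_rate=0.005, min_depth=10)
    call = binomial_call(CytosinePileup("c", 0, "+", "CG", "CG", 9, 9), cfg)
    assert call.pvalue == 1.0 and not call.passed


@settings(max_examples=50, deadline=None, derandomize=True)
@given(n=st.integers(1, 60), p=st.floats(1e-4, 0.2))
def test_binomial_pvalue_monotone_in_unconverted_count(n, p):
    from hollowmeth.methcall import binomial_pvalues

    ks = np.arange(0, n + 1)
    pv = binomial_pvalues(ks, np.full(n + 1, n), p)
    assert np.all(np.diff(pv) <= 1e-15)
    assert pv[0] == pytest.approx(1.0)


def test_fdr_mode_is_no_looser_than_per_site():
    rng = np.random.default_rng(0)
    n = rng.integers(10, 30, 500)
    k = rng.binomial(n, 0.005)
    k[:5] = n[:5]  # a few strong sites
    pile = pd.DataFrame({
        "contig": "c", "position": np.arange(500), "strand": "+",
        "context2": "CG", "context3": "CG", "depth": n, "unconverted": k,
    })
    per_site = call_methylation(pile, CallerConfig(0.005, correction_mode="per_site"))
    fdr = call_methylation(pile, CallerConfig(0.005, correction_mode="fdr_step"))
    assert set(fdr[fdr.passed].position) <= set(per_site[per_site.passed].position)
    assert fdr.passed.iloc[:5].all()


def test_overlap_replicates_set_semantics():
    def calls(positions, passed=True):
        return pd.DataFrame({
            "contig": "c", "position": positions, "strand": "+",
            "passed": passed, "pvalue": 0.0, "level": 1.0,
        })

    assert len(overlap_replicates(calls([1, 2, 3]), calls([4, 5]))) == 0
    same = overlap_replicates(calls([1, 2, 3]), calls([1, 2, 3]))
    assert sorted(same.position) == [1, 2, 3]
    # symmetry
    a, b = calls([1, 2, 5]), calls([2, 5, 9])
    ab = overlap_replicates(a, b)
    ba = overlap_replicates(b, a)
    assert sorted(ab.position) == sorted(ba.position) == [2, 5]
    # unpassed calls never intersect
    assert len(overlap_replicates(calls([1]), calls([1], passed=False))) == 0


def test_summary_partitions_calls_across_contexts(small_sim, small_alignment):
    _, ref, _, _, _, _ = small_sim
    filtered, _ = apply_filters(small_alignment)
    pile = pileup(filtered, ref)
    p = 1 - conversion_rate(pile, ref.control_names) / 100
    genomic = pile[~pile.contig.isin(ref.control_names)].reset_index(drop=True)
    calls = call_methylation(genomic, CallerConfig(max(p, 1e-6)))
    summary = summarize_replicate(calls, pile, ref.control_names)
    n_ctx = sum(summary["calls_per_context3"].values())
    n_cn = int((calls.passed & (calls.context3 == "CN")).sum())
    assert n_ctx + n_cn == summary["n_passed"]
    tab = table_levels(pile, ref.control_names)
    assert list(tab.index) == ["sample", "control"]
    assert tab.loc["sample", "C"] == pytest.approx(
        100 * global_methylation_level(genomic), rel=1e-9)


def test_caller_config_validation():
    with pytest.raises(ValueError):
        CallerConfig(false_positive_rate=0.0)
    with pytest.raises(ValueError):
        CallerConfig(false_positive_rate=1.2)
    with pytest.raises(ValueError):
        CallerConfig(0.005, correction_mode="bonferroni")
    with pytest.raises(ValueError):
        CytosinePileup("c", 0, "+", "CG", "CG", 5, 6)
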