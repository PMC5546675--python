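"""Detection semantics, summaries and the two-step subject selection."""
import dataclasses

import numpy as np
import pytest

from autozyg.containers import MISSING, GeneInterval
from autozyg.roh import (ROHParams, ROHSegment, ROHSummary, detect_rohs,
                         select_roh_individuals, summarize_rohs)
from autozyg.simulate import simulate_cohort, simulate_marker_map
from helpers import oracle_rohs, random_roh_fixture, single_sample_matrix

SMALL = ROHParams(min_length=50_000, min_snps=10, window_size=10,
                  max_missing_in_run=2, max_gap=30_000, min_density=50_000,
                  long_threshold=4_000_000)


def test_all_homozygous_chromosome_is_one_run():
    pos = np.arange(600) * 10_000          # 6 Mb span, no gaps
    calls = np.full(600, 2, dtype=np.int8)
    segs = detect_rohs(single_sample_matrix(calls, pos), ROHParams())
    assert len(segs) == 1
    seg = segs[0]
    assert seg.n_snps == 600 and seg.n_het == 0
    assert seg.start == 0 and seg.end == pos[-1] + 1
    assert seg.length == pytest.approx(6_000_000, rel=0.01)


def test_alternating_hets_give_no_runs():
    pos = np.arange(600) * 10_000
    calls = np.tile([0, 1], 300).astype(np.int8)
    assert detect_rohs(single_sample_matrix(calls, pos), ROHParams()) == []


def test_isolated_het_does_not_split_run():
    """One miscalled het inside a long homozygous stretch is absorbed."""
    pos = np.arange(600) * 10_000
    calls = np.full(600, 0, dtype=np.int8)
    calls[300] = 1
    segs = detect_rohs(single_sample_matrix(calls, pos), ROHParams())
    assert len(segs) == 1
    assert segs[0].n_het == 1


def test_oversized_gap_splits_run():
    pos = np.concatenate([np.arange(300) * 10_000,
                          5_000_000 + np.arange(300) * 10_000])
    calls = np.full(600, 2, dtype=np.int8)
    segs = detect_rohs(single_sample_matrix(calls, pos), ROHParams())
    assert len(segs) == 2


def test_empty_matrix_gives_no_runs():
    gm = single_sample_matrix(np.empty(0, dtype=np.int8),
                              np.empty(0, dtype=np.int64))
    assert detect_rohs(gm, ROHParams()) == []


@pytest.mark.parametrize("seed", range(60))
def test_detection_equals_bruteforce_on_random_fixtures(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(20, 200))
    calls, pos = random_roh_fixture(rng, n)
    gm = single_sample_matrix(calls, pos)
    got = [(int(np.searchsorted(pos, s.start)),
            int(np.searchsorted(pos, s.end - 1)))
           for s in detect_rohs(gm, SMALL)]
    assert got == oracle_rohs(calls, pos, SMALL)


def test_implanted_segment_recovered_against_oracle(small_cfg):
    cfg = dataclasses.replace(small_cfg, genotype_error_rate=0.0,
                              missing_rate=0.0, n_samples=8)
    mm = simulate_marker_map(cfg)
    gm, truths = simulate_cohort(cfg, mm)
    params = ROHParams()
    segs = detect_rohs(gm, params)
    # full agreement with the naive oracle on every sample/chromosome
    for si, sample in enumerate(gm.sample_ids):
        for chrom in mm.chromosomes():
            sl = mm.chrom_slice(chrom)
            expect = oracle_rohs(gm.calls[si, sl], mm.pos[sl], params)
            got = [(int(np.searchsorted(mm.pos[sl], s.start)),
                    int(np.searchsorted(mm.pos[sl], s.end - 1)))
                   for s in segs if s.sample == sample and s.chrom == chrom]
            assert got == expect


def test_raising_min_length_never_adds_runs():
    rng = np.random.default_rng(7)
    for _ in range(20):
        calls, pos = random_roh_fixture(rng, 150)
        gm = single_sample_matrix(calls, pos)
        previous = None
        for min_length in (10_000, 50_000, 200_000, 1_000_000):
            n = len(detect_rohs(gm, dataclasses.replace(
                SMALL, min_length=min_length)))
            if previous is not None:
                assert n <= previous
            previous = n


def test_noisy_long_segments_mostly_recovered(small_cfg):
    """At genotype error 0.005 and missing 0.005, at least 95% of
    implanted segments above 4 Mb are still detected (fixed seed)."""
    cfg = dataclasses.replace(small_cfg, genotype_error_rate=0.005,
                              missing_rate=0.005, n_samples=60,
                              inbred_fraction=0.4, seed=99)
    mm = simulate_marker_map(cfg)
    gm, truths = simulate_cohort(cfg, mm)
    segs = detect_rohs(gm, ROHParams())
    n_long = n_found = 0
    for t in truths:
        for chrom, a, b in t.implanted_segments:
            if b - a <= 4_000_000:
                continue
            n_long += 1
            hit = any(s.sample == t.sample and s.chrom == chrom
                      and min(b, s.end) - max(a, s.start) > 0.9 * (b - a)
                      for s in segs)
            n_found += hit
    assert n_long >= 20
    assert n_found / n_long >= 0.95


def _seg(sample, length, chrom="chr1", start=0):
    return ROHSegment(sample=sample, chrom=chrom, start=start,
                      end=start + length, n_snps=100, n_het=0, n_missing=0)


def test_summary_arithmetic():
    segs = [_seg("S1", 4_000_000, start=0),
            _seg("S1", 2_500_000, start=10_000_000),
            _seg("S1", 1_200_000, start=20_000_000)]
    s = summarize_rohs(segs, [], ROHParams())[0]
    assert s.n_rohs == 3
    assert s.median_length == 2_500_000
    assert s.max_length == 4_000_000
    assert s.total_length == 7_700_000
    assert s.n_long_rohs == 0   # strictly greater than 4 Mb


def test_gene_overlap_counting():
    genes = [GeneInterval(f"G{i}", "chr1", i * 1_000_000,
                          i * 1_000_000 + 10_000) for i in range(10)]
    segs = [_seg("S1", 2_500_000, start=500_000)]   # spans G1, G2 starts
    s = summarize_rohs(segs, genes, ROHParams())[0]
    # genes at 1 Mb and 2 Mb fall inside [0.5 Mb, 3.0 Mb)
    assert s.n_genes == 2
    # 1 bp overlap counts
    segs = [ROHSegment("S1", "chr1", 9_999, 10_001, 10, 0, 0)]
    assert summarize_rohs(segs, genes, ROHParams())[0].n_genes == 1


def test_summary_against_naive_oracle(small_cfg):
    from autozyg.simulate import simulate_gene_intervals
    mm = simulate_marker_map(small_cfg)
    gm, _ = simulate_cohort(small_cfg, mm)
    genes = simulate_gene_intervals(small_cfg)
    segs = detect_rohs(gm, ROHParams())
    for s in summarize_rohs(segs, genes, ROHParams(),
                            sample_ids=gm.sample_ids):
        mine = [x for x in segs if x.sample == s.sample]
        lengths = sorted(x.length for x in mine)
        assert s.n_rohs == len(mine)
        assert s.total_length == sum(lengths)
        naive_genes = {g.gene_id for g in genes for x in mine
                       if g.chrom == x.chrom
                       and max(g.start, x.start) < min(g.end, x.end)}
        assert s.n_genes == len(naive_genes)


def _summary(sample, n_long):
    return ROHSummary(sample=sample, n_rohs=n_long, median_length=2e6,
                      max_length=5_000_000, total_length=10_000_000,
                      n_genes=1, n_long_rohs=n_long)


def test_upper_quartile_selection_interpolated():
    summaries = [_summary(f"S{i}", c) for i, c in enumerate(
        [1, 2, 3, 4, 5, 6, 7, 8])]
    # Q3 of 1..8 by linear interpolation is 6.25; strictly above: 7, 8
    assert select_roh_individuals(summaries) == ["S6", "S7"]


def test_selection_reproduces_cohort_shape():
    """27 step-1 subjects, median 2 long runs, top seven above 4."""
    counts = [1] * 6 + [2] * 8 + [3] * 3 + [4] * 3 + [5, 5, 6, 6, 7, 8, 9]
    assert len(counts) == 27
    assert float(np.median(counts)) == 2.0
    summaries = [_summary(f"S{i:02d}", c) for i, c in enumerate(counts)]
    selected = select_roh_individuals(summaries)
    assert len(selected) == 7
    assert all(s.n_long_rohs > 4 for s in summaries
               if s.sample in set(selected))


def test_selection_ties_and_empty_cases(caplog):
    # identical counts: no one strictly exceeds Q3
    summaries = [_summary(f"S{i}", 3) for i in range(5)]
    assert select_roh_individuals(summaries) == []
    # nobody passes step 1
    summaries = [_summary(f"S{i}", 0) for i in range(5)]
    with caplog.at_level("WARNING"):
        assert select_roh_individuals(summaries) == []
    assert "no sample" in caplog.text
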