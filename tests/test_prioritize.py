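"""Filtration cascade: tier rules, flags, ROH context, Ti/Tv, summaries."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from autozyg.containers import CnvInterval
from autozyg.prioritize import (TierParams, apply_blacklist_and_cnv,
                                assign_roh_context, compute_titv,
                                damaging_votes, exclusion_reason_counts,
                                summarize_tiers, tier_variants)
from autozyg.roh import ROHSegment
from helpers import make_variant, table3_variants


def tier_of(variant, params=None):
    return tier_variants([variant], params)[0]


class TestTierRules:
    def test_published_best_candidates_all_pass(self):
        got = {a.key[0]: a.tier for a in tier_variants(table3_variants())}
        assert got == {p: "best_candidate" for p in ("P2", "P3", "P6", "P7")}

    def test_two_of_three_consensus_accepts_tolerated_sift(self):
        megf8 = table3_variants()[0]
        assert megf8.sift == 0.90          # tolerated call
        assert damaging_votes(megf8) == 2
        assert tier_of(megf8).tier == "best_candidate"

    def test_common_variant_stops_at_frequency_filter(self):
        v = make_variant(af_db=(0.2, None, None))
        a = tier_of(v)
        assert a.tier == "in_roh"
        assert "MAF" in a.exclusion_reason

    def test_synonymous_in_long_run_is_not_functional(self):
        v = make_variant(consequence="synonymous", roh_length=6_000_000)
        a = tier_of(v)
        assert a.tier == "in_roh"
        assert "consequence" in a.exclusion_reason

    def test_heterozygous_and_missing_calls(self):
        assert tier_of(make_variant(zygosity="het")).tier == "in_roh"
        a = tier_of(make_variant(zygosity="missing"))
        assert a.tier == "excluded"
        assert "missing" in a.exclusion_reason

    def test_outside_roh_cannot_reach_lff(self):
        assert tier_of(make_variant(roh_length=None)).tier == "excluded"
        assert tier_of(make_variant(roh_length=800_000)).tier == "in_roh"

    def test_best_requires_rarity_and_no_homozygotes(self):
        # database homozygote -> not a best candidate
        v = make_variant(af_db=(5e-5, None, None), nhom_db=(1, None, 0))
        assert tier_of(v).tier == "LFF_D"
        # frequency above the extreme-rarity cut-off
        v = make_variant(af_db=(5e-4, None, None), nhom_db=(0, 0, 0))
        assert tier_of(v).tier == "LFF_D"
        # run not longer than 3 Mb (strict inequality)
        v = make_variant(roh_length=3_000_000)
        assert tier_of(v).tier == "LFF_D"
        # absent homozygote counts behave like zero
        v = make_variant(af_db=(5e-5, None, None), nhom_db=(None, None, None))
        assert tier_of(v).tier == "best_candidate"

    def test_benign_consensus_stays_lff(self):
        v = make_variant(sift=0.9, pp2_hdiv=0.99, mt=0.1)  # one vote
        assert tier_of(v).tier == "LFF"

    def test_brain_expression_flag_is_strictly_greater(self):
        assert tier_of(make_variant(fpkm_brain=1.0)).brain_expressed is False
        assert tier_of(make_variant(fpkm_brain=1.01)).brain_expressed is True


def test_blacklist_and_cnv_flags():
    v1 = make_variant(pos=100)
    v2 = make_variant(pos=200)
    v3 = make_variant(pos=300, sample="S2")
    blacklist = {("chr1", 100, "G", "A")}
    cnvs = [CnvInterval("S1", "chr1", 150, 250, 1),      # hemizygous region
            CnvInterval("S2", "chr1", 250, 350, 3)]      # duplication: fine
    flagged = apply_blacklist_and_cnv([v1, v2, v3], blacklist, cnvs)
    assert [v.in_blacklist for v in flagged] == [True, False, False]
    assert [v.in_cnv for v in flagged] == [False, True, False]
    tiers = tier_variants(flagged)
    assert tiers[0].exclusion_reason == "blacklist"
    assert tiers[1].exclusion_reason == "possible hemizygosity"
    assert tiers[2].tier == "best_candidate"
    # no blacklist, no CNVs: unchanged
    assert apply_blacklist_and_cnv([v1, v2, v3]) == [v1, v2, v3]


class TestRohContext:
    SEGS = [ROHSegment("S1", "chr1", 1_000_000, 7_900_000, 5000, 0, 0)]

    def test_containment_and_length(self):
        v = assign_roh_context([make_variant(pos=5_000_000,
                                             roh_length=None)], self.SEGS)[0]
        assert v.roh_length == 6_900_000

    def test_half_open_boundaries(self):
        inside = make_variant(pos=7_899_999, roh_length=None)
        at_end = make_variant(pos=7_900_000, roh_length=None)
        at_start = make_variant(pos=1_000_000, roh_length=None)
        got = assign_roh_context([inside, at_end, at_start], self.SEGS)
        assert got[0].roh_length == 6_900_000
        assert got[1].roh_length is None
        assert got[2].roh_length == 6_900_000

    def test_matches_naive_containment_sweep(self, rng):
        segs = []
        for sample in ("S1", "S2"):
            start = 0
            for _ in range(8):
                start += int(rng.integers(100_000, 2_000_000))
                length = int(rng.integers(50_000, 3_000_000))
                segs.append(ROHSegment(sample, "chr1", start, start + length,
                                       100, 0, 0))
                start += length
        variants = [make_variant(sample=str(rng.choice(["S1", "S2", "S3"])),
                                 pos=int(rng.integers(0, 40_000_000)),
                                 roh_length=None)
                    for _ in range(300)]
        got = assign_roh_context(variants, segs)
        for v0, v in zip(variants, got):
            naive = [s.length for s in segs if s.sample == v0.sample
                     and s.chrom == v0.chrom and s.start <= v0.pos < s.end]
            assert v.roh_length == (naive[0] if naive else None)


def test_tier_inclusions_on_random_variants(rng):
    """best ⊆ LFF-D ⊆ LFF ⊆ in-ROH, with reasons covering the rest."""
    variants = []
    for i in range(400):
        variants.append(make_variant(
            pos=i * 1000,
            zygosity=str(rng.choice(["hom_alt", "hom_alt", "het",
                                     "missing"])),
            consequence=str(rng.choice(["missense", "synonymous",
                                        "stop_gain", "other"])),
            af_db=tuple(None if rng.random() < 0.4
                        else float(rng.uniform(0, 0.2)) for _ in range(3)),
            nhom_db=tuple(None if rng.random() < 0.5
                          else int(rng.integers(0, 3)) for _ in range(3)),
            sift=float(rng.uniform(0, 1)), pp2_hdiv=float(rng.uniform(0, 1)),
            mt=float(rng.uniform(0, 1)),
            fpkm_brain=float(rng.uniform(0, 5)),
            roh_length=None if rng.random() < 0.2
            else int(rng.integers(100_000, 8_000_000)),
            in_blacklist=bool(rng.random() < 0.05),
            in_cnv=bool(rng.random() < 0.05)))
    assignments = tier_variants(variants)
    keys = {t: {a.key for a in assignments if a.tier == t}
            for t in ("excluded", "in_roh", "LFF", "LFF_D",
                      "best_candidate")}
    lff_up = keys["LFF"] | keys["LFF_D"] | keys["best_candidate"]
    in_roh_up = keys["in_roh"] | lff_up
    assert keys["best_candidate"] <= keys["best_candidate"] | keys["LFF_D"]
    assert len(in_roh_up | keys["excluded"]) == len(variants)
    brain = {a.key for a in assignments if a.brain_expressed}
    # every non-LFF variant carries a reason; reasons tally matches
    reasons = exclusion_reason_counts(assignments)
    assert sum(reasons.values()) == len(variants) - len(lff_up)
    assert all(a.exclusion_reason for a in assignments
               if a.tier in ("excluded", "in_roh"))
    # spot-check: re-derive LFF membership independently
    for v, a in zip(variants, assignments):
        expect_lff = (v.zygosity == "hom_alt" and v.roh_length is not None
                      and v.roh_length >= 1_000_000
                      and v.consequence in ("missense", "stop_gain")
                      and (v.max_af is None or v.max_af < 0.05)
                      and not v.in_blacklist and not v.in_cnv)
        assert (a.key in lff_up) == expect_lff


@st.composite
def variant_strategy(draw):
    opt_af = st.one_of(st.none(), st.floats(0, 0.3, allow_nan=False))
    opt_n = st.one_of(st.none(), st.integers(0, 3))
    return make_variant(
        pos=draw(st.integers(0, 10_000_000)),
        zygosity=draw(st.sampled_from(["hom_alt", "het", "hom_ref",
                                       "missing"])),
        consequence=draw(st.sampled_from(["missense", "synonymous",
                                          "frameshift", "other"])),
        af_db=(draw(opt_af), draw(opt_af), draw(opt_af)),
        nhom_db=(draw(opt_n), draw(opt_n), draw(opt_n)),
        sift=draw(st.floats(0, 1)), pp2_hdiv=draw(st.floats(0, 1)),
        mt=draw(st.floats(0, 1)),
        fpkm_brain=draw(st.floats(0, 10)),
        roh_length=draw(st.one_of(st.none(),
                                  st.integers(10_000, 10_000_000))),
        in_blacklist=draw(st.booleans()), in_cnv=draw(st.booleans()))


@settings(max_examples=200, derandomize=True)
@given(variant_strategy())
def test_tier_chain_invariants_hold_for_any_variant(v):
    """Any input lands in exactly one tier; the chain nests; every
    sub-LFF tier carries a reason; best implies damaging and rarity."""
    a = tier_variants([v])[0]
    assert a.tier in ("excluded", "in_roh", "LFF", "LFF_D",
                      "best_candidate")
    if a.tier in ("excluded", "in_roh"):
        assert a.exclusion_reason
    else:
        assert v.zygosity == "hom_alt" and v.roh_length >= 1_000_000
        assert not v.in_blacklist and not v.in_cnv
        assert v.consequence in ("missense", "frameshift")
        assert v.max_af is None or v.max_af < 0.05
    if a.tier in ("LFF_D", "best_candidate"):
        assert damaging_votes(v) >= 2
    if a.tier == "best_candidate":
        assert v.roh_length > 3_000_000
        assert v.is_novel or v.max_af < 1e-4
        assert all((n or 0) == 0 for n in v.nhom_db)


@settings(max_examples=20, derandomize=True)
@given(st.lists(variant_strategy(), min_size=2, max_size=15),
       st.randoms(use_true_random=False))
def test_tier_assignment_is_order_independent(variants, rnd):
    base = sorted((a.key, a.tier, a.exclusion_reason)
                  for a in tier_variants(variants))
    shuffled = list(variants)
    rnd.shuffle(shuffled)
    got = sorted((a.key, a.tier, a.exclusion_reason)
                 for a in tier_variants(shuffled))
    assert got == base


def test_summarize_dedups_shared_variants():
    shared = dict(chrom="chr9", pos=77, ref="A", alt="T", gene_id="SHARED")
    variants = [make_variant(sample="S1", **shared),
                make_variant(sample="S2", **shared),
                make_variant(sample="S2", pos=99, gene_id="OTHER")]
    df = summarize_tiers(tier_variants(variants))
    all_row = df[df["sample"] == "All"].iloc[0]
    assert all_row["lff_variants"] == 2      # 3 calls, 2 distinct variants
    assert all_row["lff_genes"] == 2
    per = df.set_index("sample")
    assert per.loc["S1", "lff_variants"] == 1
    assert per.loc["S2", "lff_variants"] == 2


@pytest.mark.parametrize("pairs,expected", [
    ([("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")], 1.0),
    ([("A", "G")] * 60 + [("A", "C")] * 12 + [("C", "G")] * 12, 2.5),
])
def test_titv_ratio(pairs, expected):
    variants = [make_variant(pos=i, ref=r, alt=a)
                for i, (r, a) in enumerate(pairs)]
    assert compute_titv(variants) == pytest.approx(expected)


def test_titv_undefined_without_transversions(caplog):
    variants = [make_variant(pos=i, ref="A", alt="G") for i in range(5)]
    with caplog.at_level("WARNING"):
        assert compute_titv(variants) is None
    assert "Ti/Tv" in caplog.text
    # indels are ignored
    variants.append(make_variant(pos=99, ref="AT", alt="A"))
    assert compute_titv(variants) is None
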