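"""Filtration cascade for homozygous variants inside runs of homozygosity.

Tiers (each a subset of the previous):

``in_roh``
    any called variant whose position falls inside one of the sample's
    detected runs;
``LFF``
    low-frequency functional: homozygous for the alternate allele, in a
    run of at least 1 Mb, protein-affecting consequence, maximum
    reported database allele frequency below 0.05, not on the
    false-positive-indel blacklist and not inside a same-sample CNV
    with fewer than two copies (possible hemizygosity);
``LFF_D``
    LFF and called damaging by at least 2 of 3 predictors (SIFT < 0.05,
    PolyPhen-2 HDIV >= 0.957, MutationTaster >= 0.5);
``best_candidate``
    LFF-D, in a run longer than 3 Mb, novel or with every reported
    database frequency below 1e-4, and never reported homozygous in any
    database.

Brain expression (FPKM > 1) is tracked as an orthogonal flag on LFF
variants rather than a step in the main chain, because damaging status
is assessed on all LFF variants.  Every variant that fails to reach LFF
carries a machine-readable exclusion reason.
"""
from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (FUNCTIONAL_CONSEQUENCES, AnnotatedVariant,
                         CnvInterval)
from .roh import ROHSegment

log = logging.getLogger(__name__)


@dataclass
class TierParams:
    """Filtration thresholds; defaults follow the tier definitions above."""

    max_af: float = 0.05               # LFF frequency cut-off
    rare_af: float = 1e-4              # "extremely rare" cut-off
    min_roh: int = 1_000_000           # LFF run-length requirement
    best_min_roh: int = 3_000_000      # best-candidate requirement (strict >)
    fpkm_min: float = 1.0              # brain expression (strict >)
    damaging_min_votes: int = 2        # of the three predictors
    sift_damaging: float = 0.05        # SIFT call D iff score < this
    pp2_damaging: float = 0.957        # PP2 HDIV call D iff score >= this
    mt_damaging: float = 0.5           # MutationTaster call D iff score >= this
    functional: frozenset[str] = FUNCTIONAL_CONSEQUENCES


@dataclass(frozen=True)
class TierAssignment:
    """Tier call for one (sample, variant) pair."""

    key: tuple[str, str, int, str, str]   # sample, chrom, pos, ref, alt
    gene_id: Optional[str]
    tier: str                             # excluded|in_roh|LFF|LFF_D|best_candidate
    brain_expressed: bool
    exclusion_reason: str = ""

    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return self.key[1:]

    @property
    def sample(self) -> str:
        return self.key[0]


def predictor_calls(v: AnnotatedVariant,
                    params: Optional[TierParams] = None
                    ) -> tuple[Optional[str], Optional[str], Optional[str]]:
    """(SIFT, PP2, MT) calls as 'D'/'T', or None when a score is absent."""
    p = params or TierParams()
    sift = None if v.sift is None else ("D" if v.sift < p.sift_damaging else "T")
    pp2 = None if v.pp2_hdiv is None else (
        "D" if v.pp2_hdiv >= p.pp2_damaging else "T")
    mt = None if v.mt is None else ("D" if v.mt >= p.mt_damaging else "T")
    return sift, pp2, mt


def damaging_votes(v: AnnotatedVariant,
                   params: Optional[TierParams] = None) -> int:
    return sum(c == "D" for c in predictor_calls(v, params))


def apply_blacklist_and_cnv(variants: Sequence[AnnotatedVariant],
                            blacklist: set[tuple[str, int, str, str]] = frozenset(),
                            cnvs: Sequence[CnvInterval] = ()
                            ) -> list[AnnotatedVariant]:
    """Flag blacklisted calls and calls inside reduced-copy CNVs.

    The blacklist matches on (chrom, pos, ref, alt).  A variant is
    flagged ``in_cnv`` when its position lies inside a CNV of the same
    sample with copy number below 2, where an apparently homozygous
    call may in fact be hemizygous.
    """
    cnv_by_sample: dict[str, list[CnvInterval]] = {}
    for c in cnvs:
        cnv_by_sample.setdefault(c.sample, []).append(c)
    out = []
    for v in variants:
        in_bl = (v.chrom, v.pos, v.ref, v.alt) in blacklist
        in_cnv = any(c.chrom == v.chrom and c.start <= v.pos < c.end
                     and c.copy_number < 2
                     for c in cnv_by_sample.get(v.sample, ()))
        if in_bl != v.in_blacklist or in_cnv != v.in_cnv:
            v = AnnotatedVariant(**{**v.__dict__,
                                    "in_blacklist": in_bl, "in_cnv": in_cnv})
        out.append(v)
    return out


def assign_roh_context(variants: Sequence[AnnotatedVariant],
                       segments: Sequence[ROHSegment]
                       ) -> list[AnnotatedVariant]:
    """Attach the containing same-sample run length to each variant.

    Containment is half-open: a variant at the run's ``end`` coordinate
    is outside it.  Variants in no run get ``roh_length`` None.
    """
    by_key: dict[tuple[str, str], tuple[list[int], list[int]]] = {}
    for seg in sorted(segments, key=lambda s: (s.sample, s.chrom, s.start)):
        starts, ends = by_key.setdefault((seg.sample, seg.chrom), ([], []))
        starts.append(seg.start)
        ends.append(seg.end)
    out = []
    for v in variants:
        roh_len: Optional[int] = None
        entry = by_key.get((v.sample, v.chrom))
        if entry is not None:
            starts, ends = entry
            i = bisect_right(starts, v.pos) - 1
            if i >= 0 and v.pos < ends[i]:
                roh_len = ends[i] - starts[i]
        if roh_len != v.roh_length:
            v = AnnotatedVariant(**{**v.__dict__, "roh_length": roh_len})
        out.append(v)
    return out


def _classify(v: AnnotatedVariant, p: TierParams) -> TierAssignment:
    brain = v.fpkm_brain is not None and v.fpkm_brain > p.fpkm_min

    def make(tier: str, reason: str = "") -> TierAssignment:
        return TierAssignment(key=v.key(), gene_id=v.gene_id, tier=tier,
                              brain_expressed=brain and tier not in
                              ("excluded",), exclusion_reason=reason)

    if v.zygosity == "missing":
        return make("excluded", "missing genotype")
    if v.roh_length is None:
        return make("excluded", "outside ROH")
    # inside a run: at least tier in_roh
    if v.zygosity != "hom_alt":
        return make("in_roh", "not homozygous for the alternate allele")
    if v.in_blacklist:
        return make("in_roh", "blacklist")
    if v.in_cnv:
        return make("in_roh", "possible hemizygosity")
    if v.roh_length < p.min_roh:
        return make("in_roh", "ROH shorter than minimum")
    if v.consequence not in p.functional:
        return make("in_roh", "non-functional consequence")
    max_af = v.max_af
    if max_af is not None and max_af >= p.max_af:
        return make("in_roh", f"MAF >= {p.max_af:g}")
    # LFF reached; damaging consensus?
    if damaging_votes(v, p) < p.damaging_min_votes:
        return make("LFF")
    # best candidate?
    rare = v.is_novel or (max_af is not None and max_af < p.rare_af)
    never_hom = all((n or 0) == 0 for n in v.nhom_db)
    if v.roh_length > p.best_min_roh and rare and never_hom:
        return make("best_candidate")
    return make("LFF_D")


def tier_variants(variants: Sequence[AnnotatedVariant],
                  params: Optional[TierParams] = None
                  ) -> list[TierAssignment]:
    """Classify every variant into the tier cascade.

    The tier is a pure conjunction of per-variant predicates, so the
    result does not depend on any evaluation order; the exclusion
    reason reports the first unmet requirement in a canonical order.
    """
    p = params or TierParams()
    return [_classify(v, p) for v in variants]


TIER_RANK = {"excluded": 0, "in_roh": 1, "LFF": 2, "LFF_D": 3,
             "best_candidate": 4}


def summarize_tiers(assignments: Sequence[TierAssignment],
                    sample_ids: Optional[Sequence[str]] = None
                    ) -> pd.DataFrame:
    """Per-sample tier counts plus an 'All' row with distinct counts.

    Variant columns count (sample, variant) calls per row; the 'All'
    row counts distinct variants (by chrom/pos/ref/alt) and distinct
    genes across the cohort, so a variant shared by two samples counts
    once.
    """
    samples = list(sample_ids) if sample_ids is not None else \
        sorted({a.sample for a in assignments})
    per = {s: [] for s in samples}
    for a in assignments:
        per.setdefault(a.sample, []).append(a)

    def count(rows: list[TierAssignment], min_tier: str,
              brain: Optional[bool] = None) -> tuple[int, int]:
        keep = [a for a in rows if TIER_RANK[a.tier] >= TIER_RANK[min_tier]
                and (brain is None or a.brain_expressed == brain)]
        n_var = len({a.site_key for a in keep})
        n_gene = len({a.gene_id for a in keep if a.gene_id is not None})
        return n_var, n_gene

    records = []
    for s in samples:
        rows = per.get(s, [])
        nv_roh, _ = count(rows, "in_roh")
        nv_lff, ng_lff = count(rows, "LFF")
        nv_brain, ng_brain = count(rows, "LFF", brain=True)
        nv_d, ng_d = count(rows, "LFF_D")
        nv_best, _ = count(rows, "best_candidate")
        records.append((s, nv_roh, nv_lff, ng_lff, nv_brain, ng_brain,
                        nv_d, ng_d, nv_best))
    all_rows = [a for s in samples for a in per.get(s, [])]
    nv_roh, _ = count(all_rows, "in_roh")
    nv_lff, ng_lff = count(all_rows, "LFF")
    nv_brain, ng_brain = count(all_rows, "LFF", brain=True)
    nv_d, ng_d = count(all_rows, "LFF_D")
    nv_best, _ = count(all_rows, "best_candidate")
    records.append(("All", nv_roh, nv_lff, ng_lff, nv_brain, ng_brain,
                    nv_d, ng_d, nv_best))
    return pd.DataFrame(records, columns=[
        "sample", "variants_in_roh",
        "lff_variants", "lff_genes",
        "lff_brain_variants", "lff_brain_genes",
        "lffd_variants", "lffd_genes",
        "best_candidate_variants"])


def compute_titv(variants: Sequence[AnnotatedVariant]) -> Optional[float]:
    """Transition / transversion ratio over SNVs; None when undefined."""
    transitions = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
    ts = tv = 0
    for v in variants:
        if not v.is_snv():
            continue
        if (v.ref, v.alt) in transitions:
            ts += 1
        else:
            tv += 1
    if tv == 0:
        log.warning("no transversions observed; Ti/Tv undefined")
        return None
    return ts / tv


def exclusion_reason_counts(assignments: Sequence[TierAssignment]
                            ) -> dict[str, int]:
    """Tally of exclusion reasons among variants that did not reach LFF."""
    out: dict[str, int] = {}
    for a in assignments:
        if TIER_RANK[a.tier] < TIER_RANK["LFF"]:
            out[a.exclusion_reason] = out.get(a.exclusion_reason, 0) + 1
    return out
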