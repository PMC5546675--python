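"""Gene-list and interval enrichment statistics.

Three complementary tests:

* :func:`permutation_overlap_test` — the empirical test of whether a
  candidate gene list overlaps a disease gene set more than random
  lists of the same size drawn from a background universe.  The
  background should be the genes a candidate could have come from
  (e.g. genes inside the cohort's runs of homozygosity), which makes
  the null density-aware.  The empirical p-value uses the add-one
  (permutation-inclusive) correction and is never zero; when the
  number of possible draws is small the test enumerates them all and
  the p-value is exact.
* :func:`interval_enrichment_test` — an interval-relocation test in the
  spirit of region-based enrichment tools: each query interval is
  relocated uniformly within its chromosome, preserving length and
  approximately matching the number of genes it covers, and the number
  of intervals hitting at least one target gene is compared with the
  relocated null.
* :func:`hypergeometric_ora` — classical over-representation analysis
  with Benjamini-Hochberg correction across sets.

Gene identifiers are matched case-insensitively by uppercasing both
sides; no alias resolution is attempted.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import GeneInterval, GeneSet, genes_by_chrom
from .errors import ConfigurationError
from .roh import ROHSegment

log = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 10_000


def normalize_genes(genes: Sequence[str]) -> list[str]:
    """Uppercase, strip and de-duplicate while preserving order."""
    return list(dict.fromkeys(g.strip().upper() for g in genes if g.strip()))


@dataclass
class EnrichmentResult:
    query_name: str
    target_name: str
    n_query: int
    n_overlap: int
    overlap_fraction: float
    n_perm: int
    n_as_extreme: int
    empirical_p: float
    background_name: str
    seed: Optional[int]
    exhaustive: bool = False


@dataclass
class IntervalEnrichmentResult:
    target_name: str
    n_intervals: int
    statistic: int              # intervals overlapping >= 1 target gene
    n_perm: int
    n_as_extreme: int
    empirical_p: float
    relocation_scheme: str
    seed: Optional[int]


def overlap_fraction(query: Sequence[str], target: GeneSet
                     ) -> tuple[int, float]:
    """Size and fraction of the query that belongs to the target set."""
    q = normalize_genes(query)
    if not q:
        raise ConfigurationError("empty query gene list")
    members = {g.upper() for g in target.members}
    n = sum(g in members for g in q)
    return n, n / len(q)


def _sample_overlaps(member: np.ndarray, q: int, n_perm: int,
                     rng: np.random.Generator,
                     chunk: int = 512) -> np.ndarray:
    """Overlap counts of ``n_perm`` uniform size-``q`` draws (no replacement)."""
    n = member.size
    out = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        u = rng.random((m, n))
        idx = np.argpartition(u, q - 1, axis=1)[:, :q]
        out[done:done + m] = member[idx].sum(axis=1)
        done += m
    return out


def permutation_overlap_test(query: Sequence[str], target: GeneSet,
                             background: Sequence[str],
                             n_perm: int = 9_999,
                             seed: int = 0,
                             match_to_roh_background: bool = False,
                             query_name: str = "query",
                             background_name: str = "") -> EnrichmentResult:
    """Permutation test of query/target overlap against a background.

    Draws ``n_perm`` uniform samples of ``len(query)`` genes without
    replacement from the background and counts how many overlap the
    target at least as much as the query does.  When the number of
    distinct draws C(|background|, |query|) is at most 10,000 the test
    enumerates all of them instead and the returned p-value is exact
    (``exhaustive=True``); otherwise ``empirical_p`` is the add-one
    estimate (n_as_extreme + 1) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    q = normalize_genes(query)
    bg = normalize_genes(background)
    bg_set = set(bg)
    offenders = [g for g in q if g not in bg_set]
    if offenders:
        raise ConfigurationError(
            f"query genes missing from background: {offenders[:10]}")
    members = {g.upper() for g in target.members}
    if not members & bg_set:
        raise ConfigurationError(
            f"target set {target.name} shares no gene with the background")
    n_overlap = sum(g in members for g in q)
    frac = n_overlap / len(q)
    bg_arr = np.array(bg, dtype=object)
    member = np.fromiter((g in members for g in bg), dtype=bool,
                         count=len(bg))
    nq = len(q)
    total = math.comb(len(bg), nq)
    if total <= EXHAUSTIVE_LIMIT:
        member_idx = np.flatnonzero(member)
        n_extreme = 0
        for combo in combinations(range(len(bg)), nq):
            ov = len(np.intersect1d(combo, member_idx, assume_unique=True))
            if ov >= n_overlap:
                n_extreme += 1
        return EnrichmentResult(
            query_name=query_name, target_name=target.name, n_query=nq,
            n_overlap=n_overlap, overlap_fraction=frac, n_perm=total,
            n_as_extreme=n_extreme, empirical_p=n_extreme / total,
            background_name=background_name
            or ("roh" if match_to_roh_background else "all"),
            seed=seed, exhaustive=True)
    rng = np.random.default_rng(seed)
    overlaps = _sample_overlaps(member, nq, n_perm, rng)
    n_extreme = int(np.count_nonzero(overlaps >= n_overlap))
    return EnrichmentResult(
        query_name=query_name, target_name=target.name, n_query=nq,
        n_overlap=n_overlap, overlap_fraction=frac, n_perm=n_perm,
        n_as_extreme=n_extreme,
        empirical_p=(n_extreme + 1) / (n_perm + 1),
        background_name=background_name
        or ("roh" if match_to_roh_background else "all"),
        seed=seed, exhaustive=False)


def _count_genes_hit(start: int, end: int, starts: np.ndarray,
                     ends: np.ndarray) -> int:
    """Number of (sorted, non-overlapping) genes overlapping [start, end)."""
    lo = int(np.searchsorted(ends, start, side="right"))
    hi = int(np.searchsorted(starts, end, side="left"))
    return max(hi - lo, 0)


def interval_enrichment_test(intervals: Sequence[ROHSegment],
                             target: GeneSet,
                             genes: Sequence[GeneInterval],
                             n_perm: int = 999,
                             seed: int = 0,
                             chrom_lengths: Optional[dict[str, int]] = None,
                             density_tolerance: Optional[float] = 0.2,
                             max_resample: int = 200
                             ) -> IntervalEnrichmentResult:
    """Interval-relocation enrichment of target genes in query intervals.

    The statistic is the number of intervals overlapping at least one
    target gene.  Each permutation relocates every interval uniformly
    within its chromosome (length preserved); when
    ``density_tolerance`` is set, a relocation is resampled until the
    relocated interval covers a gene count within that fraction of the
    original interval's count, which matches the null on local gene
    density.  After ``max_resample`` failures the closest attempt is
    kept with a logged note.
    """
    if n_perm < 1:
        raise ConfigurationError("n_perm must be >= 1")
    by_chrom = genes_by_chrom(genes)
    starts_e: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    members = {g.upper() for g in target.members}
    for chrom, gl in by_chrom.items():
        starts = np.array([g.start for g in gl])
        ends = np.array([g.end for g in gl])
        is_t = np.array([g.gene_id.upper() in members for g in gl])
        starts_e[chrom] = (starts, ends, is_t)
    if chrom_lengths is None:
        chrom_lengths = {}
        for chrom, gl in by_chrom.items():
            chrom_lengths[chrom] = max(g.end for g in gl)
        for iv in intervals:
            chrom_lengths[iv.chrom] = max(chrom_lengths.get(iv.chrom, 0),
                                          iv.end)

    def hits_target(chrom: str, s: int, e: int) -> bool:
        entry = starts_e.get(chrom)
        if entry is None:
            return False
        starts, ends, is_t = entry
        lo = int(np.searchsorted(ends, s, side="right"))
        hi = int(np.searchsorted(starts, e, side="left"))
        return bool(is_t[lo:hi].any())

    def gene_count(chrom: str, s: int, e: int) -> int:
        entry = starts_e.get(chrom)
        if entry is None:
            return 0
        return _count_genes_hit(s, e, entry[0], entry[1])

    ivs = []
    for iv in intervals:
        clen = chrom_lengths[iv.chrom]
        if iv.length > clen:
            raise ConfigurationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} longer than its "
                f"chromosome ({clen} bp)")
        ivs.append((iv.chrom, iv.start, iv.end, iv.length,
                    gene_count(iv.chrom, iv.start, iv.end)))
    observed = sum(hits_target(c, s, e) for c, s, e, _, _ in ivs)

    rng = np.random.default_rng(seed)
    n_extreme = 0
    n_unmatched = 0
    for _ in range(n_perm):
        stat = 0
        for chrom, _s, _e, length, g0 in ivs:
            clen = chrom_lengths[chrom]
            best = None
            for _t in range(max_resample):
                ns = int(rng.integers(0, clen - length + 1))
                gc = gene_count(chrom, ns, ns + length)
                if density_tolerance is None or \
                        abs(gc - g0) <= density_tolerance * max(g0, 1):
                    best = ns
                    break
                if best is None or abs(gc - g0) < best[1]:
                    best = (ns, abs(gc - g0))
            if isinstance(best, tuple):
                n_unmatched += 1
                best = best[0]
            stat += hits_target(chrom, best, best + length)
        if stat >= observed:
            n_extreme += 1
    if n_unmatched:
        log.info("interval relocation: %d placements kept without meeting "
                 "the gene-density tolerance", n_unmatched)
    return IntervalEnrichmentResult(
        target_name=target.name, n_intervals=len(ivs), statistic=observed,
        n_perm=n_perm, n_as_extreme=n_extreme,
        empirical_p=(n_extreme + 1) / (n_perm + 1),
        relocation_scheme="uniform-within-chromosome"
        + ("" if density_tolerance is None
           else f"; gene count +/-{density_tolerance:.0%}"),
        seed=seed)


def hypergeometric_ora(query: Sequence[str], sets: Sequence[GeneSet],
                       background: Sequence[str],
                       min_overlap_report: int = 2) -> pd.DataFrame:
    """Hypergeometric over-representation of the query in each set.

    Upper-tail p on the 2x2 table restricted to the background,
    Benjamini-Hochberg q-values across sets.  Sets overlapping the
    query in fewer than ``min_overlap_report`` genes are kept in the
    table but flagged ``below_min_overlap``.
    """
    q = normalize_genes(query)
    bg = normalize_genes(background)
    bg_set = set(bg)
    offenders = [g for g in q if g not in bg_set]
    if offenders:
        raise ConfigurationError(
            f"query genes missing from background: {offenders[:10]}")
    rows = []
    for s in sets:
        members = {g.upper() for g in s.members} & bg_set
        if not members:
            log.warning("set %s has no background member; skipped", s.name)
            continue
        k = sum(g in members for g in q)
        n_bg, n_set, n_q = len(bg), len(members), len(q)
        p = float(stats.hypergeom.sf(k - 1, n_bg, n_set, n_q))
        expected = n_q * n_set / n_bg
        rows.append((s.name, n_set, k, k / expected if expected else np.nan,
                     p, k < min_overlap_report))
    if not rows:
        return pd.DataFrame(columns=["set", "n_set", "overlap", "fold",
                                     "p", "q", "below_min_overlap"])
    df = pd.DataFrame(rows, columns=["set", "n_set", "overlap", "fold",
                                     "p", "below_min_overlap"])
    df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df[["set", "n_set", "overlap", "fold", "p", "q",
               "below_min_overlap"]]
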