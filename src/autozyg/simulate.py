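"""Synthetic cohort generator with implanted autozygous segments.

The generator emulates the data a recent-inbreeding exome study consumes:

* a genotyping-array marker map with Beta-distributed allele frequencies;
* a cohort genotyped under Hardy-Weinberg equilibrium, a fraction of
  which carries multi-Mb autozygous segments (homozygous for one allele
  drawn by its population frequency) perturbed by per-call genotype
  error and missingness;
* annotated exome variant calls planted at configurable densities
  inside and outside those segments, with database frequencies,
  homozygote counts, predictor scores and brain expression realised so
  that each variant's intended prioritization tier is known;
* gene intervals, gene sets with controllable enrichment, and a truth
  record per sample for recovery testing.

Everything is driven by a single seed; identical (seed, config) pairs
reproduce identical outputs.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import (MISSING, AnnotatedVariant, GeneInterval, GeneSet,
                         GenotypeMatrix, MarkerMap)
from .errors import ConfigurationError

log = logging.getLogger(__name__)

# deterministic per-stage RNG sub-streams
_STAGE = {"map": 11, "cohort": 23, "genes": 37, "variants": 53, "sets": 71}

#: tier labels used in truth records (matching the prioritization output)
TIERS = ("non_candidate", "LFF", "LFF_D", "best_candidate")

#: minimum truth-segment length for planting LFF/LFF-D tier variants.
#: Detected run boundaries differ from the implanted segment by a few
#: marker spacings, so candidates are planted only in segments with a
#: safety margin over the 1 Mb / 3 Mb tier cut-offs.
LFF_SEGMENT_MARGIN = 1_200_000
BEST_SEGMENT_MARGIN = 3_500_000

#: minimum separation enforced between implanted segments of one sample,
#: so adjacent segments are never merged by the detector.
SEGMENT_SEPARATION = 500_000

#: candidate-tier variants are planted at least this far from segment
#: edges; detected run boundaries wander a few marker spacings around
#: the implanted boundary.
EDGE_MARGIN = 10_000


@dataclass
class SimulationConfig:
    """Study-shaped defaults for the synthetic cohort.

    The cohort mirrors the shape of an array-genotyped schizophrenia
    case series: 180 unrelated subjects, ~15% of whom carry recent-
    inbreeding autozygous segments (Poisson-many per carrier, mean 5,
    exponentially distributed lengths with mean 8 Mb).  The simulated
    genome is four 40 Mb chromosomes at one marker per kb — a
    desk-scale stand-in for a dense genotyping array.
    """

    n_samples: int = 180
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chr1", 40_000_000), ("chr2", 40_000_000),
        ("chr3", 40_000_000), ("chr4", 40_000_000))
    marker_density: float = 1e-3           # markers per bp
    allele_freq_dist: tuple[float, float] = (3.0, 3.0)
    inbred_fraction: float = 0.15
    segments_per_inbred: float = 5.0       # Poisson mean (>= 1 enforced)
    segment_length_mean: float = 8_000_000.0
    genotype_error_rate: float = 0.002     # hom call rendered het
    missing_rate: float = 0.002
    variant_rate_in_roh: float = 10.0      # planted variants per Mb
    variant_rate_outside: float = 2.0
    rare_af_range: tuple[float, float] = (1e-6, 1e-4)
    gene_density: float = 1.0 / 150_000    # genes per bp
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be positive")
        if not self.chrom_lengths:
            raise ConfigurationError("chrom_lengths must be non-empty")
        for name, length in self.chrom_lengths:
            if length <= 0:
                raise ConfigurationError(f"chromosome {name} length must be "
                                         "positive")
        if self.marker_density <= 0:
            raise ConfigurationError("marker_density must be positive")
        for rate in ("inbred_fraction", "genotype_error_rate",
                     "missing_rate"):
            v = getattr(self, rate)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{rate} must be in [0, 1]")
        if self.segments_per_inbred <= 0 or self.segment_length_mean <= 0:
            raise ConfigurationError("segment parameters must be positive")
        if self.variant_rate_in_roh < 0 or self.variant_rate_outside < 0:
            raise ConfigurationError("variant rates must be >= 0")
        lo, hi = self.rare_af_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("rare_af_range must satisfy "
                                     "0 <= lo <= hi <= 1")
        a, b = self.allele_freq_dist
        if a <= 0 or b <= 0:
            raise ConfigurationError("Beta parameters must be positive")


@dataclass
class TruthRecord:
    """Ground truth for one sample: implanted segments and planted tiers."""

    sample: str
    implanted_segments: list[tuple[str, int, int]] = field(default_factory=list)
    planted_variants: list[tuple[tuple[str, str, int, str, str], str]] = \
        field(default_factory=list)   # (variant key, intended tier)


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((int(config.seed), _STAGE[stage])))


def simulate_marker_map(config: SimulationConfig) -> MarkerMap:
    """Place jittered-grid markers along each chromosome.

    The expected count per chromosome is ``round(length * density)``;
    one marker is dropped into each grid cell at a uniform offset, so
    counts are exact and positions strictly increasing.
    """
    config.validate()
    rng = _rng(config, "map")
    a, b = config.allele_freq_dist
    chroms, poss, ids, freqs = [], [], [], []
    for name, length in config.chrom_lengths:
        n = int(round(length * config.marker_density))
        if n == 0:
            log.warning("chromosome %s gets 0 markers at density %g",
                        name, config.marker_density)
            continue
        spacing = length / n
        offs = rng.random(n)
        pos = (np.arange(n) * spacing + offs * (spacing - 1)).astype(np.int64)
        pos = np.maximum.accumulate(pos - np.arange(n)) + np.arange(n)
        chroms.extend([name] * n)
        poss.append(pos)
        ids.extend(f"{name}_m{i}" for i in range(n))
        freqs.append(rng.beta(a, b, n))
    if not poss:
        raise ConfigurationError("no chromosome received any marker")
    pos_all = np.concatenate(poss)
    n_all = pos_all.size
    base_pairs = np.array([("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")],
                          dtype=object)
    pick = rng.integers(0, len(base_pairs), n_all)
    return MarkerMap(chrom=chroms, pos=pos_all, ids=ids,
                     a1=base_pairs[pick, 0], a2=base_pairs[pick, 1],
                     freq=np.concatenate(freqs))


def _draw_segments(rng: np.random.Generator, config: SimulationConfig
                   ) -> list[tuple[str, int, int]]:
    """Non-overlapping autozygous segments for one inbred sample."""
    names = [c[0] for c in config.chrom_lengths]
    lengths = np.array([c[1] for c in config.chrom_lengths], dtype=float)
    weights = lengths / lengths.sum()
    n_seg = max(1, int(rng.poisson(config.segments_per_inbred)))
    placed: list[tuple[str, int, int]] = []
    for _ in range(n_seg):
        seg_len = max(1, int(rng.exponential(config.segment_length_mean)))
        ci = int(rng.choice(len(names), p=weights))
        chrom, clen = names[ci], int(lengths[ci])
        if seg_len >= clen:
            seg_len = clen  # truncated to the chromosome
        for _attempt in range(50):
            start = int(rng.integers(0, max(1, clen - seg_len + 1)))
            end = min(start + seg_len, clen)
            ok = all(not (chrom == c and start - SEGMENT_SEPARATION < e
                          and end + SEGMENT_SEPARATION > s)
                     for c, s, e in placed)
            if ok:
                placed.append((chrom, start, end))
                break
    placed.sort()
    return placed


def simulate_cohort(config: SimulationConfig, markers: MarkerMap
                    ) -> tuple[GenotypeMatrix, list[TruthRecord]]:
    """Genotype the cohort: HWE background plus implanted autozygosity.

    Outside implanted segments each genotype is Binomial(2, p) at the
    marker's allele frequency (Hardy-Weinberg).  Inside a segment the
    sample is homozygous for one allele drawn by its frequency.
    Genotype error renders truly homozygous calls inside segments
    heterozygous; missingness applies to every call.
    """
    config.validate()
    rng = _rng(config, "cohort")
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    n_inbred = int(round(config.inbred_fraction * n))
    inbred_idx = rng.choice(n, size=n_inbred, replace=False)
    freq = markers.freq
    nm = markers.n_markers
    chrom_slices = {c: markers.chrom_slice(c) for c in markers.chromosomes()}

    calls = np.empty((n, nm), dtype=np.int8)
    truths = []
    for si, sid in enumerate(sample_ids):
        row = rng.binomial(2, freq).astype(np.int8)
        truth = TruthRecord(sample=sid)
        if si in inbred_idx:
            for chrom, start, end in _draw_segments(rng, config):
                sl = chrom_slices.get(chrom)
                if sl is None:
                    continue
                pos = markers.pos[sl]
                lo = sl.start + int(np.searchsorted(pos, start, "left"))
                hi = sl.start + int(np.searchsorted(pos, end, "left"))
                if hi > lo:
                    hom = 2 * (rng.random(hi - lo) < freq[lo:hi])
                    row[lo:hi] = hom.astype(np.int8)
                    if config.genotype_error_rate > 0:
                        flip = rng.random(hi - lo) < config.genotype_error_rate
                        row[lo:hi][flip] = 1
                truth.implanted_segments.append((chrom, start, end))
        if config.missing_rate > 0:
            miss = rng.random(nm) < config.missing_rate
            row[miss] = MISSING
        calls[si] = row
        truths.append(truth)
    return GenotypeMatrix(sample_ids, calls, markers), truths


def simulate_gene_intervals(config: SimulationConfig) -> list[GeneInterval]:
    """Tile each chromosome with non-overlapping gene intervals."""
    config.validate()
    rng = _rng(config, "genes")
    out = []
    gi = 0
    for name, length in config.chrom_lengths:
        n = int(length * config.gene_density)
        if n == 0:
            continue
        cell = length / n
        for k in range(n):
            glen = int(min(cell * 0.8,
                           rng.lognormal(mean=math.log(20_000), sigma=0.6)))
            glen = max(glen, 1_000)
            lo = int(k * cell)
            start = lo + int(rng.integers(0, max(1, int(cell) - glen)))
            gi += 1
            out.append(GeneInterval(gene_id=f"GENE{gi:05d}", chrom=name,
                                    start=start, end=start + glen))
    return out


# ---------------------------------------------------------------------------
# exome variant simulation
# ---------------------------------------------------------------------------

_TS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
_TV = [("A", "C"), ("A", "T"), ("C", "A"), ("C", "G"),
       ("G", "C"), ("G", "T"), ("T", "A"), ("T", "G")]


def _alleles(rng: np.random.Generator) -> tuple[str, str]:
    # transition:transversion ~ 2.5 overall, as in exome calls
    if rng.random() < 0.715:
        return tuple(rng.choice(sorted(_TS)))
    return tuple(_TV[int(rng.integers(0, len(_TV)))])


def _damaging_scores(rng: np.random.Generator) -> tuple[float, float, float]:
    """SIFT/PP2/MT triple with >= 2 damaging votes (each damaging w.p. 0.9)."""
    while True:
        d = rng.random(3) < 0.9
        if d.sum() >= 2:
            break
    sift = rng.uniform(0.0, 0.049) if d[0] else rng.uniform(0.06, 1.0)
    pp2 = rng.uniform(0.957, 1.0) if d[1] else rng.uniform(0.0, 0.95)
    mt = rng.uniform(0.5, 1.0) if d[2] else rng.uniform(0.0, 0.49)
    return float(sift), float(pp2), float(mt)


def _benign_scores(rng: np.random.Generator) -> tuple[float, float, float]:
    """At most one damaging vote."""
    d = np.zeros(3, dtype=bool)
    if rng.random() < 0.3:
        d[int(rng.integers(0, 3))] = True
    sift = rng.uniform(0.0, 0.049) if d[0] else rng.uniform(0.06, 1.0)
    pp2 = rng.uniform(0.957, 1.0) if d[1] else rng.uniform(0.0, 0.95)
    mt = rng.uniform(0.5, 1.0) if d[2] else rng.uniform(0.0, 0.49)
    return float(sift), float(pp2), float(mt)


def _rare_af(rng: np.random.Generator, config: SimulationConfig) -> float:
    lo, hi = config.rare_af_range
    lo = max(lo, 1e-8)
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _fpkm(rng: np.random.Generator, brain: bool) -> float:
    if brain:
        return float(np.exp(rng.uniform(np.log(1.5), np.log(100.0))))
    return float(rng.uniform(0.0, 0.9))


def _containing_gene(genes_c: list[GeneInterval], pos: int
                     ) -> Optional[GeneInterval]:
    for g in genes_c:
        if g.start <= pos < g.end:
            return g
    return None


def _make_variant(rng: np.random.Generator, config: SimulationConfig,
                  sample: str, chrom: str, pos: int,
                  gene: Optional[GeneInterval], tier: str,
                  beta: tuple[float, float]) -> AnnotatedVariant:
    """Realise annotation fields consistent with the intended tier."""
    ref, alt = _alleles(rng)
    a, b = beta
    if gene is None:
        tier = "non_candidate"
    if tier == "non_candidate":
        # disqualify decisively, independent of ROH length
        mode = rng.random()
        zyg = "hom_alt"
        if gene is None:
            consequence = "other"
            af = float(rng.beta(a, b))
        elif mode < 0.45:
            consequence = "synonymous"
            af = float(rng.beta(a, b))
        elif mode < 0.80:
            consequence = "missense"
            af = float(np.clip(rng.beta(a, b), 0.06, 0.94))  # common
        else:
            consequence = "missense"
            af = float(rng.uniform(0.001, 0.049))
            zyg = "het"
        sift, pp2, mt = _benign_scores(rng)
        nh = int(rng.poisson(5 * af * af * 1000)) if af > 0.01 else 0
        return AnnotatedVariant(
            sample=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
            zygosity=zyg, gene_id=gene.gene_id if gene else None,
            transcript=f"NM_{rng.integers(1, 999999):06d}" if gene else None,
            consequence=consequence,
            af_db=(af, min(1.0, af * float(rng.uniform(0.8, 1.2))), af),
            nhom_db=(nh, nh, nh),
            sift=sift, pp2_hdiv=pp2, mt=mt,
            phylop=float(rng.uniform(-2, 4)),
            fpkm_brain=_fpkm(rng, rng.random() < 0.5))
    # candidate tiers: homozygous, functional, low frequency
    consequence = str(rng.choice(
        ["missense", "stop_gain", "splice_site", "frameshift"],
        p=[0.7, 0.1, 0.1, 0.1]))
    brain = rng.random() < 0.5
    if tier == "LFF":
        sift, pp2, mt = _benign_scores(rng)
        af = float(rng.uniform(0.001, 0.049))
        nh = int(rng.integers(0, 5))
        af_db = (af, af, af)
        nhom = (nh, nh, nh)
    elif tier == "LFF_D":
        sift, pp2, mt = _damaging_scores(rng)
        # fail exactly one best-candidate requirement: frequency or
        # homozygote count
        if rng.random() < 0.5:
            af = float(rng.uniform(2e-4, 0.049))
            af_db = (af, af, af)
            nhom = (0, 0, 0)
        else:
            af = _rare_af(rng, config)
            af_db = (af, None, af)
            nhom = (1, None, 0)
    else:  # best_candidate
        sift, pp2, mt = _damaging_scores(rng)
        if rng.random() < 0.5:
            af_db = (None, None, None)   # novel
            nhom = (None, None, None)
        else:
            af = _rare_af(rng, config)
            af_db = (af, None, None)
            nhom = (0, None, None)
    return AnnotatedVariant(
        sample=sample, chrom=chrom, pos=pos, ref=ref, alt=alt,
        zygosity="hom_alt", gene_id=gene.gene_id,
        transcript=f"NM_{rng.integers(1, 999999):06d}",
        consequence=consequence, af_db=af_db, nhom_db=nhom,
        sift=sift, pp2_hdiv=pp2, mt=mt,
        phylop=float(rng.uniform(2, 10)),
        fpkm_brain=_fpkm(rng, True if tier == "best_candidate" else brain))


def simulate_exome_variants(truths: Sequence[TruthRecord],
                            genes: Sequence[GeneInterval],
                            config: SimulationConfig
                            ) -> list[AnnotatedVariant]:
    """Plant annotated homozygous variants inside and outside segments.

    In-segment variants are Poisson at ``variant_rate_in_roh`` per Mb
    with intended tiers drawn from a mixture (90% non-candidate, 6% LFF,
    4% LFF-D); one best-candidate variant is additionally planted per
    inbred sample that has a segment longer than 3.5 Mb.  Candidate
    tiers are planted only with a margin over the 1 Mb / 3 Mb run-length
    cut-offs (see :data:`LFF_SEGMENT_MARGIN`).  Variants falling outside
    any gene are forced non-candidate.  Intended tiers are appended to
    each sample's truth record.
    """
    config.validate()
    rng = _rng(config, "variants")
    by_chrom: dict[str, list[GeneInterval]] = {}
    for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
        by_chrom.setdefault(g.chrom, []).append(g)
    chrom_len = dict(config.chrom_lengths)
    genome = sum(chrom_len.values())
    out: list[AnnotatedVariant] = []
    used_pos: set[tuple[str, int]] = set()

    def fresh_pos(chrom: str, lo: int, hi: int) -> Optional[int]:
        for _ in range(20):
            p = int(rng.integers(lo, hi))
            if (chrom, p) not in used_pos:
                used_pos.add((chrom, p))
                return p
        return None

    for truth in truths:
        segs = truth.implanted_segments
        roh_mb = sum((e - s) for _, s, e in segs) / 1e6
        # --- inside segments ---
        for chrom, s, e in segs:
            n_v = rng.poisson(config.variant_rate_in_roh * (e - s) / 1e6)
            for _ in range(n_v):
                p = fresh_pos(chrom, s, e)
                if p is None:
                    continue
                gene = _containing_gene(by_chrom.get(chrom, []), p)
                tier = str(rng.choice(["non_candidate", "LFF", "LFF_D"],
                                      p=[0.90, 0.06, 0.04]))
                if ((e - s) < LFF_SEGMENT_MARGIN or gene is None
                        or p < s + EDGE_MARGIN or p >= e - EDGE_MARGIN):
                    tier = "non_candidate"
                v = _make_variant(rng, config, truth.sample, chrom, p,
                                  gene, tier, config.allele_freq_dist)
                out.append(v)
                truth.planted_variants.append((v.key(), tier))
        # --- one best candidate per inbred sample, if a long segment exists
        long_segs = [(c, s, e) for c, s, e in segs
                     if (e - s) >= BEST_SEGMENT_MARGIN]
        if long_segs:
            chrom, s, e = long_segs[int(rng.integers(0, len(long_segs)))]
            inner = [g for g in by_chrom.get(chrom, [])
                     if g.start >= s + EDGE_MARGIN
                     and g.end <= e - EDGE_MARGIN]
            if inner:
                gene = inner[int(rng.integers(0, len(inner)))]
                p = fresh_pos(chrom, gene.start, gene.end)
                if p is not None:
                    v = _make_variant(rng, config, truth.sample, chrom, p,
                                      gene, "best_candidate",
                                      config.allele_freq_dist)
                    out.append(v)
                    truth.planted_variants.append((v.key(), "best_candidate"))
        # --- outside segments ---
        n_out = rng.poisson(config.variant_rate_outside
                            * max(genome / 1e6 - roh_mb, 0.0))
        names = list(chrom_len)
        weights = np.array([chrom_len[c] for c in names], dtype=float)
        weights /= weights.sum()
        for _ in range(n_out):
            chrom = names[int(rng.choice(len(names), p=weights))]
            p = fresh_pos(chrom, 0, chrom_len[chrom])
            if p is None or any(c == chrom and s <= p < e
                                for c, s, e in segs):
                continue
            gene = _containing_gene(by_chrom.get(chrom, []), p)
            v = _make_variant(rng, config, truth.sample, chrom, p, gene,
                              "non_candidate", config.allele_freq_dist)
            out.append(v)
            truth.planted_variants.append((v.key(), "non_candidate"))
    out.sort(key=lambda v: (v.sample, v.chrom, v.pos))
    return out


def simulate_gene_sets(universe: Sequence[str], set_size: int,
                       enrichment: float = 0.0, seed: int = 0,
                       query: Optional[Sequence[str]] = None,
                       name: str = "SIMSET") -> GeneSet:
    """Draw a gene set, optionally forcing overlap with a query list.

    When ``enrichment > 0`` and a query is given,
    ``ceil(enrichment * len(query))`` query genes are made members; the
    remaining members are drawn uniformly from the rest of the universe.
    """
    uni = list(dict.fromkeys(universe))
    if set_size > len(uni):
        raise ConfigurationError(f"set_size {set_size} exceeds universe "
                                 f"size {len(uni)}")
    if not 0.0 <= enrichment <= 1.0:
        raise ConfigurationError("enrichment must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((int(seed),
                                                        _STAGE["sets"])))
    members: list[str] = []
    if enrichment > 0 and query:
        q = [g for g in dict.fromkeys(query) if g in set(uni)]
        k = min(math.ceil(enrichment * len(q)), len(q), set_size)
        members = list(rng.choice(q, size=k, replace=False)) if k else []
    rest = [g for g in uni if g not in set(members)]
    n_more = set_size - len(members)
    if n_more > 0:
        members += list(rng.choice(rest, size=n_more, replace=False))
    return GeneSet(name=name, description="synthetic gene set",
                   members=frozenset(members))


def write_truth(truths: Sequence[TruthRecord], path: str) -> str:
    """Write truth records as a flat TSV (segments and planted tiers)."""
    with open(path, "w") as fh:
        fh.write("sample\trecord\tchrom\tstart\tend\tref\talt\ttier\n")
        for t in truths:
            for chrom, s, e in t.implanted_segments:
                fh.write(f"{t.sample}\tsegment\t{chrom}\t{s}\t{e}\t.\t.\t.\n")
            for (sample, chrom, pos, ref, alt), tier in t.planted_variants:
                fh.write(f"{t.sample}\tvariant\t{chrom}\t{pos}\t{pos + 1}\t"
                         f"{ref}\t{alt}\t{tier}\n")
    return path
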