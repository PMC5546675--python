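"""Run-of-homozygosity detection, summaries and subject selection.

Detection semantics (scanning-window algorithm)
-----------------------------------------------
A window of ``window_size`` consecutive markers is *homozygous* when it
contains at most ``max_het_in_run`` heterozygous and at most
``max_missing_in_run`` missing calls.  Every marker receives a vote:
the fraction of the windows covering it (windows are clipped to the
chromosome) that are homozygous.  A marker is *in a run* when its vote
exceeds ``window_vote_threshold``.  Runs are the maximal stretches of
in-run markers, split wherever the gap between consecutive markers
exceeds ``max_gap``, trimmed at both ends to homozygous non-missing
calls, and reported when they pass the thresholds: at least
``min_snps`` markers, physical length at least ``min_length``, and
average marker spacing at most ``min_density`` bp per marker.
Stretches separated by at most ``window_size`` markers (and no
oversized positional gap) are merged first: two genotyping errors
falling within one window span veto every window covering the markers
between them, and the resulting break is an artifact of the window
geometry, not evidence of heterozygous background.

Budgeting het/missing calls per window rather than per run is what
makes detection robust to realistic genotyping error: an isolated
miscalled het sits in windows that are still homozygous, while genuine
heterozygous background puts two or more hets in every window.  The
definition is constructive and deterministic, so it can be checked
against a naive marker-by-marker re-implementation.

Long runs (above ``long_threshold``, 4 Mb by default) are the signature
of recent parental relatedness: autozygous segments inherited identical
by descent from a recent common ancestor.  Subject selection keeps the
samples with at least one such run and, of those, the ones whose
long-run count strictly exceeds the upper quartile of the survivors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .containers import MISSING, GeneInterval, GenotypeMatrix, genes_by_chrom
from .errors import ConfigurationError

log = logging.getLogger(__name__)


@dataclass
class ROHParams:
    """Detection and selection thresholds (bp unless noted).

    ``max_het_in_run`` and ``max_missing_in_run`` are per-window
    allowances (see the module docstring), not totals over a whole run.
    """

    min_length: int = 1_000_000
    min_snps: int = 50
    max_het_in_run: int = 1
    max_missing_in_run: int = 5
    max_gap: int = 100_000
    min_density: int = 50_000          # max bp per marker within a run
    long_threshold: int = 4_000_000    # "large ROH" cut-off
    window_size: int = 50              # markers per scanning window
    window_vote_threshold: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_length", "min_snps", "max_gap", "min_density",
                     "long_threshold", "window_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.max_het_in_run < 0 or self.max_missing_in_run < 0:
            raise ConfigurationError("het/missing allowances must be >= 0")
        if not 0.0 <= self.window_vote_threshold < 1.0:
            raise ConfigurationError("window_vote_threshold must be in "
                                     "[0, 1)")


@dataclass(frozen=True)
class ROHSegment:
    """One homozygous run for one sample (0-based half-open)."""

    sample: str
    chrom: str
    start: int
    end: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ROHSummary:
    """Per-sample roll-up of detected runs (one table row)."""

    sample: str
    n_rohs: int
    median_length: float
    max_length: int
    total_length: int
    n_genes: int
    n_long_rohs: int
    froh: Optional[float] = None   # total_length / genome_length convenience


def _sample_chrom_runs(calls: np.ndarray, pos: np.ndarray,
                       params: ROHParams) -> list[tuple[int, int]]:
    """Scanning-window run detection for one sample, one chromosome.

    Returns (first, last) marker index pairs of accepted runs.
    """
    n = calls.size
    W = params.window_size
    if n < W:
        return []
    hom = (calls == 0) | (calls == 2)
    idx = np.arange(n)
    het = (calls == 1).astype(np.int64)
    mis = (calls == MISSING).astype(np.int64)
    ch = np.concatenate(([0], np.cumsum(het)))
    cm = np.concatenate(([0], np.cumsum(mis)))
    nw = n - W + 1
    hom_win = ((ch[W:] - ch[:-W] <= params.max_het_in_run)
               & (cm[W:] - cm[:-W] <= params.max_missing_in_run))
    cw = np.concatenate(([0], np.cumsum(hom_win)))
    lo = np.clip(idx - W + 1, 0, nw - 1)
    hi = np.minimum(idx, nw - 1)
    votes = cw[hi + 1] - cw[lo]
    denom = hi - lo + 1
    in_run = votes > params.window_vote_threshold * denom

    prev_hom = np.maximum.accumulate(np.where(hom, idx, -1))
    next_hom = np.minimum.accumulate(np.where(hom, idx, n)[::-1])[::-1]
    gap_break = np.diff(pos) > params.max_gap      # between t and t+1

    runs: list[tuple[int, int]] = []

    def consider(a: int, b: int) -> None:
        """Trim [a, b] to homozygous ends and emit if it qualifies."""
        a2, b2 = int(next_hom[a]), int(prev_hom[b])
        if a2 > b2:
            return
        n_snps = b2 - a2 + 1
        length = int(pos[b2]) - int(pos[a2]) + 1
        if (n_snps >= params.min_snps and length >= params.min_length
                and length <= n_snps * params.min_density):
            runs.append((a2, b2))

    # maximal in-run stretches, split at oversized gaps
    padded = np.concatenate(([False], in_run, [False])).astype(np.int8)
    d = np.diff(padded)
    stretch_starts = np.flatnonzero(d == 1)
    stretch_ends = np.flatnonzero(d == -1) - 1
    # merge window-span artifacts (see module docstring)
    merged: list[list[int]] = []
    for a, b in zip(stretch_starts, stretch_ends):
        if (merged and a - merged[-1][1] - 1 <= W
                and pos[a] - pos[merged[-1][1]] <= params.max_gap):
            merged[-1][1] = int(b)
        else:
            merged.append([int(a), int(b)])
    for a, b in merged:
        cut = int(a)
        for t in np.flatnonzero(gap_break[a:b]) + a:
            consider(cut, int(t))
            cut = int(t) + 1
        consider(cut, int(b))
    return runs


def detect_rohs(gm: GenotypeMatrix, params: Optional[ROHParams] = None
                ) -> list[ROHSegment]:
    """Detect runs of homozygosity for every sample in a genotype panel."""
    params = params or ROHParams()
    mm = gm.markers
    out: list[ROHSegment] = []
    chrom_slices = [(c, mm.chrom_slice(c)) for c in mm.chromosomes()]
    for si, sample in enumerate(gm.sample_ids):
        row = gm.calls[si]
        for chrom, sl in chrom_slices:
            calls = row[sl]
            pos = mm.pos[sl]
            for i, j in _sample_chrom_runs(calls, pos, params):
                seg = calls[i:j + 1]
                out.append(ROHSegment(
                    sample=sample, chrom=chrom,
                    start=int(pos[i]), end=int(pos[j]) + 1,
                    n_snps=j - i + 1,
                    n_het=int(np.count_nonzero(seg == 1)),
                    n_missing=int(np.count_nonzero(seg == MISSING))))
    out.sort(key=lambda s: (s.sample, s.chrom, s.start))
    return out


def _genes_hit(segments: Sequence[ROHSegment],
               by_chrom: dict[str, list[GeneInterval]]) -> set[str]:
    hit: set[str] = set()
    for seg in segments:
        for g in by_chrom.get(seg.chrom, ()):
            if g.start < seg.end and g.end > seg.start:
                hit.add(g.gene_id)
    return hit


def summarize_rohs(segments: Sequence[ROHSegment],
                   genes: Sequence[GeneInterval] = (),
                   params: Optional[ROHParams] = None,
                   sample_ids: Optional[Sequence[str]] = None,
                   genome_length: Optional[int] = None) -> list[ROHSummary]:
    """Per-sample summary of detected runs.

    A gene counts as "within ROHs" when its interval overlaps any of the
    sample's runs by at least 1 bp.  The median is the standard
    interpolated median (mean of the middle two lengths for even counts).
    ``sample_ids`` forces a row (of zeros) for samples with no runs.
    """
    params = params or ROHParams()
    by_chrom = genes_by_chrom(genes)
    per_sample: dict[str, list[ROHSegment]] = {}
    for seg in segments:
        per_sample.setdefault(seg.sample, []).append(seg)
    ids = list(sample_ids) if sample_ids is not None \
        else sorted(per_sample)
    out = []
    for s in ids:
        segs = per_sample.get(s, [])
        lengths = np.array([g.length for g in segs], dtype=np.int64)
        froh = None
        if genome_length:
            froh = float(lengths.sum()) / genome_length
        out.append(ROHSummary(
            sample=s,
            n_rohs=len(segs),
            median_length=float(np.median(lengths)) if len(segs) else 0.0,
            max_length=int(lengths.max()) if len(segs) else 0,
            total_length=int(lengths.sum()) if len(segs) else 0,
            n_genes=len(_genes_hit(segs, by_chrom)),
            n_long_rohs=int(np.count_nonzero(
                lengths > params.long_threshold)),
            froh=froh))
    return out


def select_roh_individuals(summaries: Sequence[ROHSummary],
                           params: Optional[ROHParams] = None) -> list[str]:
    """Two-step selection of subjects with recent-inbreeding signatures.

    Step 1 keeps samples with at least one run longer than
    ``long_threshold``; step 2 keeps, of those, the samples whose
    long-run count strictly exceeds the linearly interpolated third
    quartile of the step-1 counts.  With ties at the quartile the strict
    inequality excludes them all, so the rule is reproducible.
    """
    params = params or ROHParams()
    step1 = [s for s in summaries if s.n_long_rohs >= 1]
    if not step1:
        log.warning("no sample has a ROH longer than %d bp",
                    params.long_threshold)
        return []
    counts = np.array([s.n_long_rohs for s in step1], dtype=float)
    q3 = float(np.percentile(counts, 75))  # linear interpolation
    return [s.sample for s in step1 if s.n_long_rohs > q3]


def write_segments_bed(segments: Sequence[ROHSegment], path: str) -> str:
    """Emit runs as BED with the sample id in the name column."""
    with open(path, "w") as fh:
        for s in sorted(segments, key=lambda x: (x.chrom, x.start, x.sample)):
            fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.sample}\t"
                     f"{s.n_snps}\n")
    return path


def read_segments_bed(path: str) -> list[ROHSegment]:
    """Read runs back from the BED written by :func:`write_segments_bed`."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            f = line.split()
            if not f or line.startswith("#"):
                continue
            if len(f) < 4:
                raise ConfigurationError(f"{path}:{ln}: need 4+ columns")
            n_snps = int(f[4]) if len(f) > 4 else 0
            out.append(ROHSegment(sample=f[3], chrom=f[0], start=int(f[1]),
                                  end=int(f[2]), n_snps=n_snps,
                                  n_het=0, n_missing=0))
    out.sort(key=lambda s: (s.sample, s.chrom, s.start))
    return out
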