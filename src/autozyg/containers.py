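"""Core in-memory containers shared by every pipeline stage.

All genomic coordinates are stored 0-based half-open.  1-based formats
(VCF, PLINK MAP) are converted at the I/O boundary, never inside the
analysis code, so interval containment and overlap tests are unambiguous.

Genotype calls are coded ``0`` hom-ref, ``1`` het, ``2`` hom-alt and
``-9`` missing (:data:`MISSING`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import FormatError

#: genotype code for a missing call
MISSING = -9

VALID_CALLS = frozenset({0, 1, 2, MISSING})

ZYGOSITIES = ("hom_ref", "het", "hom_alt", "missing")

CONSEQUENCES = (
    "missense",
    "stop_gain",
    "stop_loss",
    "start_loss",
    "splice_site",
    "frameshift",
    "inframe_indel",
    "synonymous",
    "other",
)

#: consequence classes counted as protein-affecting ("functional")
FUNCTIONAL_CONSEQUENCES = frozenset(CONSEQUENCES[:7])


@dataclass
class MarkerMap:
    """Ordered genotyping-array loci with population allele frequencies.

    Parameters
    ----------
    chrom, pos
        Per-marker chromosome name and 0-based position.  Markers must be
        grouped by chromosome and strictly increasing in position within
        each chromosome.
    ids
        Marker identifiers (e.g. array probe names).
    a1, a2
        The two alleles; ``freq`` is the population frequency of ``a2``.
    """

    chrom: np.ndarray
    pos: np.ndarray
    ids: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    freq: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ids = np.asarray(self.ids, dtype=object)
        self.a1 = np.asarray(self.a1, dtype=object)
        self.a2 = np.asarray(self.a2, dtype=object)
        self.freq = np.asarray(self.freq, dtype=float)
        n = len(self.pos)
        for arr, name in ((self.chrom, "chrom"), (self.ids, "ids"),
                          (self.a1, "a1"), (self.a2, "a2"), (self.freq, "freq")):
            if len(arr) != n:
                raise FormatError(f"marker map field '{name}' has length "
                                  f"{len(arr)}, expected {n}")
        self._validate_order()

    def _validate_order(self) -> None:
        seen: dict[str, int] = {}
        order = 0
        prev_chrom: Optional[str] = None
        prev_pos = -1
        for c, p in zip(self.chrom, self.pos):
            if c != prev_chrom:
                if c in seen:
                    raise FormatError(f"markers for chromosome {c} are not "
                                      "contiguous")
                seen[c] = order
                order += 1
                prev_pos = -1
                prev_chrom = c
            if p <= prev_pos:
                raise FormatError(
                    f"marker positions not strictly increasing at {c}:{p}")
            prev_pos = p

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    def chromosomes(self) -> list[str]:
        """Chromosome names in order of appearance."""
        out: list[str] = []
        for c in self.chrom:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def chrom_slice(self, chrom: str) -> slice:
        """Index slice covering one chromosome's markers."""
        idx = np.flatnonzero(self.chrom == chrom)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class GenotypeMatrix:
    """Samples x markers genotype calls over a :class:`MarkerMap`."""

    sample_ids: list[str]
    calls: np.ndarray
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise FormatError("genotype calls must be a 2-D array")
        ns, nm = self.calls.shape
        if ns != len(self.sample_ids):
            raise FormatError(f"{len(self.sample_ids)} sample ids but "
                              f"{ns} call rows")
        if nm != self.markers.n_markers:
            raise FormatError(f"{self.markers.n_markers} markers but "
                              f"{nm} call columns")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"invalid genotype code {self.calls[i, j]} for sample "
                f"{self.sample_ids[i]} at marker {self.markers.ids[j]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic footprint (0-based half-open)."""

    gene_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"gene {self.gene_id}: start {self.start} >= end {self.end}")


@dataclass
class GeneSet:
    """A named collection of gene symbols (GMT record)."""

    name: str
    description: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise FormatError(f"gene set {self.name} has no members")


@dataclass(frozen=True)
class CnvInterval:
    """A per-sample copy-number variant call."""

    sample: str
    chrom: str
    start: int
    end: int
    copy_number: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(f"CNV {self.sample} {self.chrom}: start >= end")
        if self.copy_number < 0:
            raise FormatError("copy number must be >= 0")


@dataclass
class AnnotatedVariant:
    """One called exome variant for one sample, with its annotation.

    ``af_db`` / ``nhom_db`` hold the allele frequency and homozygote count
    from three reference databases; ``None`` means the variant is absent
    from (not reported by) that database, which is distinct from a
    reported value of 0.  A variant absent from all three databases is
    "novel".  Prediction scores follow the tools' native scales: SIFT is
    damaging below 0.05, PolyPhen-2 HDIV probably damaging at >= 0.957,
    MutationTaster disease-causing at >= 0.5.
    """

    sample: str
    chrom: str
    pos: int                       # 0-based
    ref: str
    alt: str
    zygosity: str
    gene_id: Optional[str] = None
    transcript: Optional[str] = None
    consequence: str = "other"
    af_db: tuple[Optional[float], Optional[float], Optional[float]] = (None, None, None)
    nhom_db: tuple[Optional[int], Optional[int], Optional[int]] = (None, None, None)
    sift: Optional[float] = None
    pp2_hdiv: Optional[float] = None
    mt: Optional[float] = None
    phylop: Optional[float] = None
    fpkm_brain: Optional[float] = None
    roh_length: Optional[int] = None
    in_blacklist: bool = False
    in_cnv: bool = False
    cdna_change: Optional[str] = None
    aa_change: Optional[str] = None

    def __post_init__(self) -> None:
        if self.zygosity not in ZYGOSITIES:
            raise FormatError(f"unknown zygosity '{self.zygosity}'")
        if self.consequence not in CONSEQUENCES:
            raise FormatError(f"unknown consequence '{self.consequence}'")

    def key(self) -> tuple[str, str, int, str, str]:
        """Per-sample variant key."""
        return (self.sample, self.chrom, self.pos, self.ref, self.alt)

    def site_key(self) -> tuple[str, int, str, str]:
        """Sample-independent site key used for distinct-variant counts."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def max_af(self) -> Optional[float]:
        """Maximum reported database allele frequency, or None if novel."""
        reported = [a for a in self.af_db if a is not None]
        return max(reported) if reported else None

    @property
    def is_novel(self) -> bool:
        return all(a is None for a in self.af_db)

    def is_snv(self) -> bool:
        return (len(self.ref) == 1 and len(self.alt) == 1
                and self.ref in "ACGT" and self.alt in "ACGT")


def sort_intervals(genes: Iterable[GeneInterval]) -> list[GeneInterval]:
    """Sort gene intervals by (chrom, start, end)."""
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.end))


def genes_by_chrom(genes: Sequence[GeneInterval]) -> dict[str, list[GeneInterval]]:
    out: dict[str, list[GeneInterval]] = {}
    for g in sort_intervals(genes):
        out.setdefault(g.chrom, []).append(g)
    return out
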