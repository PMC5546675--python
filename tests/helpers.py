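"""Shared test utilities: independent oracles and fixture builders."""
from __future__ import annotations

import numpy as np

from autozyg.containers import (MISSING, AnnotatedVariant, GenotypeMatrix,
                                MarkerMap)
from autozyg.roh import ROHParams


def oracle_rohs(calls, pos, params: ROHParams) -> list[tuple[int, int]]:
    """Naive marker-by-marker re-implementation of run detection.

    Recomputes window homozygosity, per-marker votes, stretch finding,
    gap splitting, end trimming and thresholds with plain Python loops;
    shares no code with the production scan.
    """
    calls = list(int(c) for c in calls)
    pos = list(int(p) for p in pos)
    n = len(calls)
    W = params.window_size
    if n < W:
        return []
    nw = n - W + 1
    hom_win = []
    for t in range(nw):
        win = calls[t:t + W]
        n_het = sum(1 for c in win if c == 1)
        n_mis = sum(1 for c in win if c == MISSING)
        hom_win.append(n_het <= params.max_het_in_run
                       and n_mis <= params.max_missing_in_run)
    in_run = []
    for i in range(n):
        ts = range(max(0, i - W + 1), min(i, nw - 1) + 1)
        votes = sum(1 for t in ts if hom_win[t])
        in_run.append(votes > params.window_vote_threshold * len(ts))
    stretches = []
    i = 0
    while i < n:
        if not in_run[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and in_run[j + 1]:
            j += 1
        stretches.append((i, j))
        i = j + 1
    merged = []
    for a, b in stretches:
        if (merged and a - merged[-1][1] - 1 <= W
                and pos[a] - pos[merged[-1][1]] <= params.max_gap):
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))
    runs = []
    for i, j in merged:
        pieces, cut = [], i
        for t in range(i, j):
            if pos[t + 1] - pos[t] > params.max_gap:
                pieces.append((cut, t))
                cut = t + 1
        pieces.append((cut, j))
        for a, b in pieces:
            while a <= b and calls[a] not in (0, 2):
                a += 1
            while b >= a and calls[b] not in (0, 2):
                b -= 1
            if a > b:
                continue
            n_snps = b - a + 1
            length = pos[b] - pos[a] + 1
            if (n_snps >= params.min_snps and length >= params.min_length
                    and length <= n_snps * params.min_density):
                runs.append((a, b))
    return runs


def single_sample_matrix(calls, pos, chrom: str = "chr1",
                         sample: str = "S1") -> GenotypeMatrix:
    calls = np.asarray(calls, dtype=np.int8)
    pos = np.asarray(pos, dtype=np.int64)
    n = calls.size
    mm = MarkerMap(chrom=[chrom] * n, pos=pos,
                   ids=[f"m{i}" for i in range(n)],
                   a1=["A"] * n, a2=["G"] * n, freq=np.full(n, 0.5))
    return GenotypeMatrix([sample], calls[None, :], mm)


def random_roh_fixture(rng: np.random.Generator,
                       n_markers: int) -> tuple[np.ndarray, np.ndarray]:
    """Random calls with homozygosity-rich patches plus random spacing."""
    p_hom = rng.uniform(0.55, 0.95)
    probs = np.array([p_hom * 0.6, 1 - p_hom - 0.05, p_hom * 0.4, 0.05])
    calls = rng.choice(np.array([0, 1, 2, MISSING], dtype=np.int8),
                       size=n_markers, p=probs / probs.sum())
    if rng.random() < 0.7:   # implant an all-hom patch
        a = int(rng.integers(0, max(1, n_markers - 30)))
        b = min(n_markers, a + int(rng.integers(20, 120)))
        calls[a:b] = rng.choice(np.array([0, 2], dtype=np.int8), size=b - a)
    gaps = rng.integers(200, 3_000, size=n_markers)
    if rng.random() < 0.3:   # one oversized gap
        gaps[int(rng.integers(0, n_markers))] = 60_000
    pos = np.cumsum(gaps)
    return calls, pos


def make_variant(**overrides) -> AnnotatedVariant:
    """An AnnotatedVariant that is a best candidate unless overridden."""
    base = dict(
        sample="S1", chrom="chr1", pos=5_000_000, ref="G", alt="A",
        zygosity="hom_alt", gene_id="GENE1", transcript="NM_000001",
        consequence="missense", af_db=(None, None, None),
        nhom_db=(None, None, None), sift=0.01, pp2_hdiv=0.99, mt=0.9,
        phylop=5.0, fpkm_brain=10.0, roh_length=5_000_000)
    base.update(overrides)
    return AnnotatedVariant(**base)


def table3_variants() -> list[AnnotatedVariant]:
    """The four published best-candidate rows as annotated inputs.

    Positions are the printed 1-based coordinates (stored 0-based);
    scores, frequencies and containing-run sizes are the printed
    values.  'Novel' is encoded as absent from all three databases.
    """
    return [
        make_variant(sample="P2", chrom="chr19", pos=42840266 - 1,
                     ref="G", alt="A", gene_id="MEGF8",
                     transcript="NM_001271938",
                     cdna_change="c.1012G>A", aa_change="p.Ala338Thr",
                     sift=0.90, pp2_hdiv=0.999, mt=1.0, phylop=5.141,
                     af_db=(None, None, None), nhom_db=(None, None, None),
                     roh_length=3_300_000),
        make_variant(sample="P3", chrom="chr12", pos=5963280 - 1,
                     ref="G", alt="A", gene_id="ANO2",
                     transcript="NM_001278596",
                     cdna_change="c.562C>T", aa_change="p.Arg188Trp",
                     sift=0.00, pp2_hdiv=1.000, mt=1.0, phylop=4.955,
                     af_db=(6.64e-5, None, None), nhom_db=(0, 0, 0),
                     roh_length=6_900_000),
        make_variant(sample="P6", chrom="chr2", pos=171687546 - 1,
                     ref="A", alt="G", gene_id="GAD1",
                     transcript="NM_000817",
                     cdna_change="c.391A>G", aa_change="p.Thr131Ala",
                     sift=0.02, pp2_hdiv=0.986, mt=1.0, phylop=8.962,
                     af_db=(None, None, None), nhom_db=(None, None, None),
                     roh_length=5_800_000),
        make_variant(sample="P7", chrom="chr15", pos=33256378 - 1,
                     ref="G", alt="C", gene_id="FMN1",
                     transcript="NM_001103184",
                     cdna_change="c.2399C>G", aa_change="p.Ser800Cys",
                     sift=0.06, pp2_hdiv=1.00, mt=0.99, phylop=9.435,
                     af_db=(8.28e-6, None, None), nhom_db=(0, 0, 0),
                     roh_length=4_000_000),
    ]


# Per-patient published tier counts:
# (variants_in_roh, lff_v, lff_g, brain_v, brain_g, lffd_v, lffd_g, best)
TABLE2_ROWS = {
    "P1": (1064, 15, 15, 6, 6, 7, 7, 0),
    "P2": (1561, 27, 25, 14, 14, 14, 14, 1),
    "P3": (1217, 24, 16, 7, 7, 4, 4, 1),
    "P4": (991, 7, 7, 3, 3, 3, 3, 0),
    "P5": (1988, 24, 21, 13, 11, 9, 9, 0),
    "P6": (1711, 9, 9, 5, 5, 2, 2, 1),
    "P7": (1579, 14, 14, 8, 8, 6, 6, 1),
}


def build_table2_cohort() -> list[AnnotatedVariant]:
    """A cohort realizing the published per-patient tier counts.

    No LFF variant or gene is shared between patients.  The per-patient
    in-run variant totals sum to 10,111 while the published cohort row
    counts 9,457 distinct variants, so 654 non-LFF filler variants are
    shared between two patients each.  Within a patient, duplicated
    genes (more variants than genes) are allocated so that the
    brain-expressed subset reproduces its own variant and gene counts;
    damaging variants are drawn from single-variant genes.
    """
    out: list[AnnotatedVariant] = []
    quotas: dict[str, int] = {}
    for p, (total, lv, lg, bv, bg, dv, dg, best) in TABLE2_ROWS.items():
        chrom = f"chr{p[1:]}"
        pos = iter(range(1_000_000, 90_000_000, 97))
        assert dv == dg
        n_dup = lv - lg                      # genes carrying two variants
        dup_b = bv - bg                      # brain genes carrying two
        genes = [f"{p}_G{i}" for i in range(lg)]
        # gene of each LFF variant: dup genes contribute two variants
        var_genes = genes[:n_dup] * 2 + genes[n_dup:]
        # brain variants: both variants of dup_b duplicated genes, then
        # single-variant genes
        brain_genes = set(genes[:dup_b]) | \
            set(genes[n_dup:n_dup + (bg - dup_b)])
        # damaging variants come from single-variant genes, taken from
        # the end to limit collision with the brain singles
        damaging_genes = set(genes[lg - dv:])
        n_best_left = best
        for g in sorted(var_genes):
            damaging = g in damaging_genes and var_genes.count(g) == 1
            is_best = damaging and n_best_left > 0
            if is_best:
                n_best_left -= 1
            out.append(make_variant(
                sample=p, chrom=chrom, pos=next(pos), gene_id=g,
                consequence="missense",
                af_db=(None, None, None) if is_best else (0.01, 0.01, 0.01),
                nhom_db=(None, None, None) if is_best else (2, 2, 2),
                sift=0.01 if damaging else 0.8,
                pp2_hdiv=0.99 if damaging else 0.1,
                mt=0.9 if damaging else 0.1,
                fpkm_brain=8.0 if g in brain_genes else 0.2,
                roh_length=3_500_000 if is_best else 1_500_000))
        assert n_best_left == 0
        quotas[p] = total - lv               # non-LFF filler still owed

    def filler(sample, chrom, pos, gene):
        return make_variant(
            sample=sample, chrom=chrom, pos=pos, gene_id=gene,
            consequence="synonymous", af_db=(0.3, 0.3, 0.3),
            nhom_db=(50, 50, 50), sift=0.9, pp2_hdiv=0.1, mt=0.1,
            fpkm_brain=0.5, roh_length=1_500_000)

    # 654 filler variants seen in two patients each close the gap
    # between the summed per-patient totals and the distinct-count row
    patients = list(TABLE2_ROWS)
    pairs = list(zip(patients, patients[1:] + patients[:1]))
    for i in range(654):
        a, b = pairs[i % len(pairs)]
        for p in (a, b):
            out.append(filler(p, "chrS", 1_000 + i, f"SHARED_F{i}"))
            quotas[p] -= 1
    for p in patients:
        chrom = f"chr{p[1:]}"
        for i in range(quotas[p]):
            out.append(filler(p, chrom, 50_000_000 + i * 13, f"{p}_F{i}"))
    return out
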