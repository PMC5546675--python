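"""Readers and writers for the standard formats the pipeline touches.

Supported formats
-----------------
* PLINK PED + extended MAP (MAP carries two extra allele columns and an
  optional allele-frequency column, so that genotype panels round-trip
  losslessly; a plain 4-column MAP is also accepted, in which case
  alleles are inferred from the PED calls).
* VCF (sites + GT genotypes) via :mod:`cyvcf2` for reading.
* BED gene/CNV intervals (0-based half-open, as BED is defined).
* GMT gene sets.
* A sidecar annotation TSV joined to a variant VCF by (chrom, pos, ref,
  alt); its schema mirrors a standard exome annotation report (gene,
  consequence, three database allele frequencies and homozygote counts,
  SIFT / PolyPhen-2 HDIV / MutationTaster scores, phyloP, brain FPKM).

Positions are 1-based on disk for VCF/MAP and converted to the package's
internal 0-based half-open convention on read; BED is already 0-based.
"""
from __future__ import annotations

import logging
import os
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .containers import (MISSING, AnnotatedVariant, CnvInterval, GeneInterval,
                         GeneSet, GenotypeMatrix, MarkerMap, sort_intervals)
from .errors import FormatError

log = logging.getLogger(__name__)

ANNOTATION_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "transcript", "consequence",
    "sift", "pp2_hdiv", "mt", "phylop",
    "af_db1", "af_db2", "af_db3", "nhom_db1", "nhom_db2", "nhom_db3",
    "fpkm_brain", "cdna_change", "aa_change",
]

NA = "."


# ---------------------------------------------------------------------------
# PLINK PED / MAP
# ---------------------------------------------------------------------------

def write_plink(gm: GenotypeMatrix, prefix: str) -> tuple[str, str]:
    """Write a genotype panel as ``prefix.ped`` + ``prefix.map``.

    The MAP gains three non-standard trailing columns (A1, A2, A2
    frequency) so the panel round-trips exactly.
    """
    mm = gm.markers
    map_path, ped_path = prefix + ".map", prefix + ".ped"
    with open(map_path, "w") as fh:
        for i in range(mm.n_markers):
            fh.write(f"{mm.chrom[i]}\t{mm.ids[i]}\t0\t{mm.pos[i] + 1}\t"
                     f"{mm.a1[i]}\t{mm.a2[i]}\t{mm.freq[i]:.6g}\n")
    with open(ped_path, "w") as fh:
        for s, row in zip(gm.sample_ids, gm.calls):
            fields = [s, s, "0", "0", "0", "-9"]
            for i, call in enumerate(row):
                if call == MISSING:
                    fields.append("0 0")
                elif call == 0:
                    fields.append(f"{mm.a1[i]} {mm.a1[i]}")
                elif call == 1:
                    fields.append(f"{mm.a1[i]} {mm.a2[i]}")
                else:
                    fields.append(f"{mm.a2[i]} {mm.a2[i]}")
            fh.write("\t".join(fields) + "\n")
    return ped_path, map_path


def _read_map(map_path: str) -> tuple[MarkerMap, np.ndarray]:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            f = line.split()
            if not f:
                continue
            if len(f) not in (4, 6, 7):
                raise FormatError(f"{map_path}:{ln}: expected 4, 6 or 7 "
                                  f"columns, got {len(f)}")
            chrom, mid, _cm, pos = f[:4]
            a1 = f[4] if len(f) >= 6 else None
            a2 = f[5] if len(f) >= 6 else None
            freq = float(f[6]) if len(f) == 7 else np.nan
            rows.append((chrom, mid, int(pos) - 1, a1, a2, freq))
    if not rows:
        raise FormatError(f"{map_path}: empty MAP file")
    seen: dict[tuple[str, int], str] = {}
    for chrom, mid, pos, *_ in rows:
        if (chrom, pos) in seen:
            raise FormatError(
                f"duplicate marker position {chrom}:{pos + 1} "
                f"(markers {seen[(chrom, pos)]} and {mid})")
        seen[(chrom, pos)] = mid
    order = np.array(sorted(range(len(rows)),
                            key=lambda i: (rows[i][0], rows[i][2])))
    if not np.array_equal(order, np.arange(len(rows))):
        log.warning("%s: markers not sorted; sorting by (chrom, pos)",
                    map_path)
    rows = [rows[i] for i in order]
    mm = MarkerMap(
        chrom=[r[0] for r in rows], pos=[r[2] for r in rows],
        ids=[r[1] for r in rows],
        a1=[r[3] if r[3] is not None else "?" for r in rows],
        a2=[r[4] if r[4] is not None else "?" for r in rows],
        freq=[r[5] for r in rows])
    return mm, order


def read_plink(ped_path: str, map_path: Optional[str] = None) -> GenotypeMatrix:
    """Read a PED/MAP pair; MAP defaults to the PED path with ``.map``."""
    if map_path is None:
        map_path = os.path.splitext(ped_path)[0] + ".map"
    mm, order = _read_map(map_path)
    n = mm.n_markers
    # disk column -> sorted-map row
    disk_to_out = np.empty(n, dtype=np.int64)
    disk_to_out[order] = np.arange(n)
    inferred = mm.a1[0] == "?"
    sample_ids: list[str] = []
    call_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            f = line.split()
            if not f:
                continue
            if len(f) != 6 + 2 * n:
                raise FormatError(f"{ped_path}:{ln}: expected {6 + 2 * n} "
                                  f"fields, got {len(f)}")
            sid = f[1]
            alleles = f[6:]
            row = np.empty(n, dtype=np.int8)
            # genotype columns follow the on-disk MAP order
            for disk_i in range(n):
                a, b = alleles[2 * disk_i], alleles[2 * disk_i + 1]
                out_i = int(disk_to_out[disk_i])
                if a == "0" or b == "0":
                    row[out_i] = MISSING
                    continue
                if inferred:
                    if mm.a1[out_i] == "?":
                        mm.a1[out_i] = a
                    for al in (a, b):
                        if al != mm.a1[out_i] and mm.a2[out_i] == "?":
                            mm.a2[out_i] = al
                a1, a2 = mm.a1[out_i], mm.a2[out_i]
                valid = {a1, a2}
                if a not in valid or b not in valid:
                    raise FormatError(
                        f"{ped_path}:{ln}: sample {sid}, marker "
                        f"{mm.ids[out_i]}: allele not in MAP ({a}/{b} vs "
                        f"{a1}/{a2})")
                row[out_i] = (a == a2) + (b == a2)
            sample_ids.append(sid)
            call_rows.append(row)
    for i in range(n):
        if mm.a1[i] == "?":
            mm.a1[i] = "A"
        if mm.a2[i] == "?":
            mm.a2[i] = "B"
    return GenotypeMatrix(sample_ids, np.array(call_rows, dtype=np.int8), mm)


# ---------------------------------------------------------------------------
# VCF genotype panels
# ---------------------------------------------------------------------------

def write_vcf_genotypes(gm: GenotypeMatrix, path: str) -> str:
    """Write a minimal sites+GT VCF for a genotype panel."""
    mm = gm.markers
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,'
                 'Description="Allele frequency">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for chrom in mm.chromosomes():
            sl = mm.chrom_slice(chrom)
            fh.write(f"##contig=<ID={chrom},length={int(mm.pos[sl][-1]) + 2}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for i in range(mm.n_markers):
            af = "" if np.isnan(mm.freq[i]) else f"AF={mm.freq[i]:.6g}"
            gts = "\t".join(gt_str[int(c)] for c in gm.calls[:, i])
            fh.write(f"{mm.chrom[i]}\t{mm.pos[i] + 1}\t{mm.ids[i]}\t"
                     f"{mm.a1[i]}\t{mm.a2[i]}\t.\t.\t{af or '.'}\tGT\t{gts}\n")
    return path


def read_vcf_genotypes(path: str) -> GenotypeMatrix:
    """Read a genotype panel from a VCF (GT field only)."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    chroms, poss, ids, a1s, a2s, freqs, calls = [], [], [], [], [], [], []
    # cyvcf2 gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
    code = np.array([0, 1, MISSING, 2], dtype=np.int8)
    for v in vcf:
        if len(v.ALT) != 1:
            raise FormatError(f"{path}: {v.CHROM}:{v.POS} is not biallelic")
        chroms.append(v.CHROM)
        poss.append(v.POS - 1)
        ids.append(v.ID or f"{v.CHROM}_{v.POS}")
        a1s.append(v.REF)
        a2s.append(v.ALT[0])
        af = v.INFO.get("AF")
        freqs.append(float(af) if af is not None else np.nan)
        calls.append(code[v.gt_types])
    if not poss:
        raise FormatError(f"{path}: no variant records")
    order = sorted(range(len(poss)), key=lambda i: (chroms[i], poss[i]))
    if order != list(range(len(poss))):
        log.warning("%s: markers not sorted; sorting by (chrom, pos)", path)
    dup = {}
    for i in order:
        k = (chroms[i], poss[i])
        if k in dup:
            raise FormatError(f"duplicate marker position "
                              f"{k[0]}:{k[1] + 1} ({ids[dup[k]]} and {ids[i]})")
        dup[k] = i
    mm = MarkerMap(chrom=[chroms[i] for i in order],
                   pos=[poss[i] for i in order],
                   ids=[ids[i] for i in order],
                   a1=[a1s[i] for i in order], a2=[a2s[i] for i in order],
                   freq=[freqs[i] for i in order])
    mat = np.stack([calls[i] for i in order], axis=1)
    return GenotypeMatrix(samples, mat, mm)


def read_genotypes(path: str, format: str = "ped") -> GenotypeMatrix:
    """Dispatch genotype reading by dialect (``ped`` or ``vcf``)."""
    if format == "ped":
        return read_plink(path)
    if format == "vcf":
        return read_vcf_genotypes(path)
    raise FormatError(f"unknown genotype format '{format}'")


# ---------------------------------------------------------------------------
# BED / GMT / CNV TSV
# ---------------------------------------------------------------------------

def read_intervals(path: str) -> list[GeneInterval]:
    """Read gene intervals from BED (0-based half-open)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise FormatError(f"{path}:{ln}: BED needs 4 columns "
                                  "(chrom start end name)")
            out.append(GeneInterval(gene_id=f[3], chrom=f[0],
                                    start=int(f[1]), end=int(f[2])))
    return sort_intervals(out)


def write_intervals(genes: Sequence[GeneInterval], path: str) -> str:
    with open(path, "w") as fh:
        for g in sort_intervals(genes):
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\n")
    return path


def read_gene_sets(path: str) -> list[GeneSet]:
    """Read gene sets from GMT (name, description, members...)."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{ln}: GMT line has {len(f)} "
                                  "fields, expected >= 3")
            out.append(GeneSet(name=f[0], description=f[1],
                               members=frozenset(m for m in f[2:] if m)))
    return out


def write_gene_sets(sets: Sequence[GeneSet], path: str) -> str:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description] + sorted(s.members))
                     + "\n")
    return path


def read_cnvs(path: str) -> list[CnvInterval]:
    """Read per-sample CNV calls from a BED-like TSV.

    Columns: sample, chrom, start, end, copy_number (0-based half-open).
    A header line starting with 'sample' is skipped.
    """
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split()
            if f[0] == "sample":
                continue
            if len(f) < 5:
                raise FormatError(f"{path}:{ln}: CNV TSV needs 5 columns")
            out.append(CnvInterval(sample=f[0], chrom=f[1], start=int(f[2]),
                                   end=int(f[3]), copy_number=int(f[4])))
    return sorted(out, key=lambda c: (c.sample, c.chrom, c.start))


def write_cnvs(cnvs: Sequence[CnvInterval], path: str) -> str:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tcopy_number\n")
        for c in cnvs:
            fh.write(f"{c.sample}\t{c.chrom}\t{c.start}\t{c.end}\t"
                     f"{c.copy_number}\n")
    return path


# ---------------------------------------------------------------------------
# Variant VCF + annotation TSV
# ---------------------------------------------------------------------------

def _fmt(x, fmt: str = "") -> str:
    if x is None:
        return NA
    if fmt:
        return format(x, fmt)
    return str(x)


def write_variant_annotations(variants: Sequence[AnnotatedVariant],
                              vcf_path: str, tsv_path: str) -> tuple[str, str]:
    """Write per-sample variant calls as a cohort VCF plus annotation TSV.

    The VCF carries genotypes per sample; site-level annotations go to
    the TSV keyed by (chrom, pos, ref, alt), positions 1-based in both.
    """
    samples = sorted({v.sample for v in variants})
    sidx = {s: i for i, s in enumerate(samples)}
    sites: dict[tuple, AnnotatedVariant] = {}
    gts: dict[tuple, list[str]] = {}
    zyg_gt = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1",
              "missing": "./."}
    for v in variants:
        k = v.site_key()
        sites.setdefault(k, v)
        gts.setdefault(k, ["./."] * len(samples))[sidx[v.sample]] = \
            zyg_gt[v.zygosity]
    keys = sorted(sites, key=lambda k: (k[0], k[1], k[2], k[3]))
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,'
                 'Description="Genotype">\n')
        for chrom in sorted({k[0] for k in keys}):
            mx = max(k[1] for k in keys if k[0] == chrom)
            fh.write(f"##contig=<ID={chrom},length={mx + 2}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for k in keys:
            chrom, pos, ref, alt = k
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t"
                     + "\t".join(gts[k]) + "\n")
    with open(tsv_path, "w") as fh:
        fh.write("\t".join(ANNOTATION_COLUMNS) + "\n")
        for k in keys:
            v = sites[k]
            row = [v.chrom, str(v.pos + 1), v.ref, v.alt,
                   _fmt(v.gene_id), _fmt(v.transcript), v.consequence,
                   _fmt(v.sift, ".4g"), _fmt(v.pp2_hdiv, ".4g"),
                   _fmt(v.mt, ".4g"), _fmt(v.phylop, ".4g")]
            row += [_fmt(a, ".6g") for a in v.af_db]
            row += [_fmt(n) for n in v.nhom_db]
            row += [_fmt(v.fpkm_brain, ".4g"), _fmt(v.cdna_change),
                    _fmt(v.aa_change)]
            fh.write("\t".join(row) + "\n")
    return vcf_path, tsv_path


def read_variant_annotations(vcf_path: str,
                             tsv_path: str) -> list[AnnotatedVariant]:
    """Read a variant VCF and join its sidecar annotation TSV.

    Returns one :class:`AnnotatedVariant` per (sample, site) pair where
    the sample carries the alternate allele (het or hom-alt).  Every
    annotation row must match a VCF record and vice versa.
    """
    from cyvcf2 import VCF

    ann = pd.read_csv(tsv_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(ANNOTATION_COLUMNS) - set(ann.columns)
    if missing_cols:
        raise FormatError(f"{tsv_path}: missing columns {sorted(missing_cols)}")
    table: dict[tuple, dict] = {}
    for rec in ann.to_dict("records"):
        k = (rec["chrom"], int(rec["pos"]) - 1, rec["ref"], rec["alt"])
        table[k] = rec

    def opt_f(x: str) -> Optional[float]:
        return None if x in (NA, "") else float(x)

    def opt_i(x: str) -> Optional[int]:
        return None if x in (NA, "") else int(x)

    vcf = VCF(vcf_path)
    samples = list(vcf.samples)
    out: list[AnnotatedVariant] = []
    matched: set[tuple] = set()
    n_unannotated = 0
    for v in vcf:
        for alt in v.ALT:
            k = (v.CHROM, v.POS - 1, v.REF, alt)
            rec = table.get(k)
            if rec is None:
                n_unannotated += 1
                continue
            matched.add(k)
            for i, gt in enumerate(v.gt_types):
                if gt == 1:
                    zyg = "het"
                elif gt == 3:
                    zyg = "hom_alt"
                else:
                    continue
                out.append(AnnotatedVariant(
                    sample=samples[i], chrom=v.CHROM, pos=v.POS - 1,
                    ref=v.REF, alt=alt, zygosity=zyg,
                    gene_id=None if rec["gene"] in (NA, "") else rec["gene"],
                    transcript=None if rec["transcript"] in (NA, "")
                    else rec["transcript"],
                    consequence=rec["consequence"],
                    af_db=(opt_f(rec["af_db1"]), opt_f(rec["af_db2"]),
                           opt_f(rec["af_db3"])),
                    nhom_db=(opt_i(rec["nhom_db1"]), opt_i(rec["nhom_db2"]),
                             opt_i(rec["nhom_db3"])),
                    sift=opt_f(rec["sift"]), pp2_hdiv=opt_f(rec["pp2_hdiv"]),
                    mt=opt_f(rec["mt"]), phylop=opt_f(rec["phylop"]),
                    fpkm_brain=opt_f(rec["fpkm_brain"]),
                    cdna_change=None if rec["cdna_change"] in (NA, "")
                    else rec["cdna_change"],
                    aa_change=None if rec["aa_change"] in (NA, "")
                    else rec["aa_change"]))
    unmatched = len(table) - len(matched)
    if unmatched:
        raise FormatError(f"{tsv_path}: {unmatched} annotation rows have no "
                          "matching VCF record")
    if n_unannotated:
        raise FormatError(f"{vcf_path}: {n_unannotated} VCF records have no "
                          "annotation row")
    out.sort(key=lambda v: (v.sample, v.chrom, v.pos, v.ref, v.alt))
    return out
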