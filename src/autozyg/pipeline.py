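"""End-to-end orchestration: simulate/load -> ROH -> tiers -> enrichment.

A single seeded :class:`RunConfig` drives every stage; identical config
and seed reproduce byte-identical artifacts.  Outputs are publication-style
tables (per-sample ROH summary, per-sample tier counts, best-candidate
list), a BED of detected runs, an enrichment TSV and a JSON run
manifest sufficient to re-run the pipeline.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .containers import AnnotatedVariant, GeneInterval, GeneSet
from .enrichment import EnrichmentResult, permutation_overlap_test
from .errors import ConfigurationError, PipelineError
from .io_formats import (read_gene_sets, read_intervals,
                         read_variant_annotations, write_intervals,
                         write_variant_annotations)
from .prioritize import (TierAssignment, TierParams, assign_roh_context,
                         summarize_tiers, tier_variants)
from .roh import (ROHParams, ROHSummary, detect_rohs, select_roh_individuals,
                  summarize_rohs, write_segments_bed)
from .simulate import (SimulationConfig, simulate_cohort,
                       simulate_exome_variants, simulate_gene_intervals,
                       simulate_gene_sets, simulate_marker_map, write_truth)

log = logging.getLogger(__name__)

TABLE1_COLUMNS = ["Patient", "Number of ROHs >1Mb", "Median dimension (bp)",
                  "Max dimension (bp)", "Amount of the genome within ROHs (bp)",
                  "Number of genes within ROHs"]
TABLE2_COLUMNS = ["Patient", "Variants", "LFF variants",
                  "LFF variants in genes expressed in brain",
                  "LFF-D variants", "Best candidate variants"]
TABLE3_COLUMNS = ["Patient", "Variant", "Gene name", "Gene ID",
                  "cDNA change", "AA change", "SIFT", "PP2_HDIV", "MT",
                  "PP100V", "Frequency", "ROH size"]


@dataclass
class RunConfig:
    """One pipeline run: inputs (or a simulation), thresholds, outputs."""

    out_dir: str
    seed: int = 0
    sim: Optional[SimulationConfig] = None
    genotypes: Optional[str] = None          # PED path (with sibling MAP)
    genes_bed: Optional[str] = None
    variants_vcf: Optional[str] = None
    annotations_tsv: Optional[str] = None
    gene_sets_gmt: Optional[str] = None
    roh: ROHParams = field(default_factory=ROHParams)
    tier: TierParams = field(default_factory=TierParams)
    n_perm: int = 9_999
    set_enrichment: float = 0.17             # simulated target-set overlap
    set_size_fraction: float = 0.10          # simulated set size vs universe
    match_to_roh_background: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.sim is None:
            for name in ("genotypes", "genes_bed", "variants_vcf",
                         "annotations_tsv"):
                path = getattr(self, name)
                if path is None:
                    raise ConfigurationError(
                        f"no simulation configured and '{name}' not given")
                if not os.path.exists(path):
                    raise ConfigurationError(f"{name} path does not exist: "
                                             f"{path}")
        else:
            self.sim.validate()
        if self.gene_sets_gmt is not None and \
                not os.path.exists(self.gene_sets_gmt):
            raise ConfigurationError("gene_sets_gmt path does not exist: "
                                     f"{self.gene_sets_gmt}")


def _tier_frame(assignments: Sequence[TierAssignment]) -> pd.DataFrame:
    rows = [{"sample": a.key[0], "chrom": a.key[1], "pos": a.key[2],
             "ref": a.key[3], "alt": a.key[4], "gene": a.gene_id or ".",
             "tier": a.tier, "brain_expressed": a.brain_expressed,
             "exclusion_reason": a.exclusion_reason or "."}
            for a in assignments]
    return pd.DataFrame(rows)


def render_table(data, style: str,
                 variants: Optional[Sequence[AnnotatedVariant]] = None
                 ) -> pd.DataFrame:
    """Render summaries in the layout of the published cohort tables.

    ``table1`` takes per-sample ROH summaries; ``table2`` takes the
    frame from :func:`autozyg.prioritize.summarize_tiers` (its 'All'
    row keeps distinct-count semantics); ``table3`` takes best-candidate
    tier assignments plus the matching variants.
    """
    if style == "table1":
        rows = [(s.sample, s.n_rohs, int(round(s.median_length)),
                 s.max_length, s.total_length, s.n_genes)
                for s in data]
        return pd.DataFrame(rows, columns=TABLE1_COLUMNS)
    if style == "table2":
        df = data.copy()
        out = pd.DataFrame({
            "Patient": df["sample"],
            "Variants": df["variants_in_roh"],
            "LFF variants": [f"{v} ({g})" for v, g in
                             zip(df["lff_variants"], df["lff_genes"])],
            "LFF variants in genes expressed in brain":
                [f"{v} ({g})" for v, g in zip(df["lff_brain_variants"],
                                              df["lff_brain_genes"])],
            "LFF-D variants": [f"{v} ({g})" for v, g in
                               zip(df["lffd_variants"], df["lffd_genes"])],
            "Best candidate variants": df["best_candidate_variants"],
        })
        return out[TABLE2_COLUMNS]
    if style == "table3":
        by_key = {v.key(): v for v in (variants or [])}
        rows = []
        for a in data:
            if a.tier != "best_candidate":
                continue
            v = by_key.get(a.key)
            if v is None:
                continue
            freq = "Novel" if v.is_novel else f"{v.max_af:.3g}"
            rows.append((
                a.key[0], f"{v.chrom}:{v.pos + 1}{v.ref}>{v.alt}",
                v.gene_id or ".", v.transcript or ".",
                v.cdna_change or ".", v.aa_change or ".",
                "." if v.sift is None else f"{v.sift:.2f}",
                "." if v.pp2_hdiv is None else f"{v.pp2_hdiv:.3f}",
                "." if v.mt is None else f"{v.mt:.2f}",
                "." if v.phylop is None else f"{v.phylop:.3f}",
                freq,
                "." if v.roh_length is None
                else f"{v.roh_length / 1e6:.1f} Mb"))
        return pd.DataFrame(rows, columns=TABLE3_COLUMNS)
    raise ConfigurationError(f"unknown table style '{style}'")


def _enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and write artifacts to ``out_dir``.

    Returns the run manifest (also written as ``manifest.json``).  Any
    stage failure removes files created during the run and re-raises as
    :class:`PipelineError` naming the stage.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    created: list[str] = []

    def out(name: str) -> str:
        path = os.path.join(config.out_dir, name)
        created.append(path)
        return path

    stage = "setup"
    try:
        # ------------------------------------------------------ inputs
        stage = "inputs"
        truths = None
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            markers = simulate_marker_map(sim)
            genes = simulate_gene_intervals(sim)
            gm, truths = simulate_cohort(sim, markers)
            variants = simulate_exome_variants(truths, genes, sim)
            write_intervals(genes, out("genes.bed"))
            write_truth(truths, out("truth.tsv"))
            write_variant_annotations(variants, out("variants.vcf"),
                                      out("annotations.tsv"))
        else:
            from .io_formats import read_plink
            gm = read_plink(config.genotypes)
            genes = read_intervals(config.genes_bed)
            variants = read_variant_annotations(config.variants_vcf,
                                                config.annotations_tsv)
        # ------------------------------------------------------ ROH
        stage = "roh"
        segments = detect_rohs(gm, config.roh)
        summaries = summarize_rohs(segments, genes, config.roh,
                                   sample_ids=gm.sample_ids)
        selected = select_roh_individuals(summaries, config.roh)
        write_segments_bed(segments, out("roh_segments.bed"))
        sel_summaries = [s for s in summaries if s.sample in set(selected)]
        render_table(sel_summaries, "table1").to_csv(
            out("table1.tsv"), sep="\t", index=False)
        # ------------------------------------------------------ tiers
        stage = "prioritize"
        sel = set(selected)
        sel_variants = [v for v in variants if v.sample in sel]
        sel_segments = [s for s in segments if s.sample in sel]
        sel_variants = assign_roh_context(sel_variants, sel_segments)
        assignments = tier_variants(sel_variants, config.tier)
        tier_summary = summarize_tiers(assignments, sample_ids=selected)
        _tier_frame(assignments).to_csv(out("tiers.tsv"), sep="\t",
                                        index=False)
        render_table(tier_summary, "table2").to_csv(
            out("table2.tsv"), sep="\t", index=False)
        render_table(assignments, "table3", variants=sel_variants).to_csv(
            out("table3.tsv"), sep="\t", index=False)
        # ------------------------------------------------------ enrichment
        stage = "enrichment"
        results = []
        lff_genes = sorted({a.gene_id for a in assignments
                            if a.tier in ("LFF", "LFF_D", "best_candidate")
                            and a.gene_id})
        lffd_genes = sorted({a.gene_id for a in assignments
                             if a.tier in ("LFF_D", "best_candidate")
                             and a.gene_id})
        if config.match_to_roh_background:
            from .roh import _genes_hit
            from .containers import genes_by_chrom
            background = sorted(_genes_hit(sel_segments,
                                           genes_by_chrom(genes)))
            bg_name = "roh"
        else:
            background = sorted({g.gene_id for g in genes})
            bg_name = "all"
        if config.gene_sets_gmt is not None:
            targets = read_gene_sets(config.gene_sets_gmt)
        elif background:
            targets = [simulate_gene_sets(
                universe=background,
                set_size=max(1, int(config.set_size_fraction
                                    * len(background))),
                enrichment=config.set_enrichment, seed=config.seed,
                query=lff_genes, name="composite")]
        else:
            targets = []
        for query, qname in ((lff_genes, "LFF"), (lffd_genes, "LFF-D")):
            if not query:
                continue
            for t in targets:
                results.append(permutation_overlap_test(
                    query, t, background, n_perm=config.n_perm,
                    seed=config.seed,
                    match_to_roh_background=config.match_to_roh_background,
                    query_name=qname, background_name=bg_name))
        _enrichment_frame(results).to_csv(out("enrichment.tsv"), sep="\t",
                                          index=False)
        # ------------------------------------------------------ manifest
        stage = "manifest"
        manifest = {
            "package": "autozyg",
            "version": __version__,
            "seed": config.seed,
            "selected_samples": selected,
            "inputs": {k: getattr(config, k) for k in
                       ("genotypes", "genes_bed", "variants_vcf",
                        "annotations_tsv", "gene_sets_gmt")},
            "simulation": None if config.sim is None
            else dataclasses.asdict(dataclasses.replace(config.sim,
                                                        seed=config.seed)),
            "roh_params": dataclasses.asdict(config.roh),
            "tier_params": {k: (sorted(v) if isinstance(v, frozenset) else v)
                            for k, v in
                            dataclasses.asdict(config.tier).items()},
            "n_perm": config.n_perm,
            "match_to_roh_background": config.match_to_roh_background,
            "artifacts": [os.path.basename(p) for p in created],
            "versions": {"numpy": np.__version__,
                         "pandas": pd.__version__},
        }
        with open(out("manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except Exception as exc:
        for path in created:
            if os.path.exists(path):
                os.remove(path)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc


def run_from_manifest(manifest_path: str, out_dir: str) -> dict:
    """Re-run a pipeline from its manifest (bit-identical for same seed)."""
    with open(manifest_path) as fh:
        m = json.load(fh)
    sim = None
    if m.get("simulation"):
        s = dict(m["simulation"])
        s["chrom_lengths"] = tuple((c, int(l)) for c, l in s["chrom_lengths"])
        s["allele_freq_dist"] = tuple(s["allele_freq_dist"])
        s["rare_af_range"] = tuple(s["rare_af_range"])
        sim = SimulationConfig(**s)
    tier_kwargs = dict(m["tier_params"])
    tier_kwargs["functional"] = frozenset(tier_kwargs["functional"])
    cfg = RunConfig(
        out_dir=out_dir, seed=m["seed"], sim=sim,
        roh=ROHParams(**m["roh_params"]), tier=TierParams(**tier_kwargs),
        n_perm=m["n_perm"],
        match_to_roh_background=m["match_to_roh_background"],
        **{k: v for k, v in m["inputs"].items()})
    return run_pipeline(cfg)
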