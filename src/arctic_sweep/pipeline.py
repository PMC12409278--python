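"""End-to-end orchestration: simulate -> filter -> scan -> outliers ->
derived -> cnv -> dels, with a combined candidate-gene report.

A single YAML-serializable configuration drives the whole run.  Per-stage
seeds are derived from the master seed by a fixed counter scheme so that
each stage is independently reproducible, and every artifact is written
deterministically: the same configuration always produces byte-identical
outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from arctic_sweep import cnv as cnv_mod
from arctic_sweep import dels as dels_mod
from arctic_sweep import derived as derived_mod
from arctic_sweep import io as aio
from arctic_sweep import outliers as outliers_mod
from arctic_sweep import popstats, sim
from arctic_sweep.filters import FilterConfig, apply_filters

logger = logging.getLogger(__name__)

#: per-stage seed offsets (master seed + offset, kept below 2^31)
STAGE_SEED_OFFSET = {"genotypes": 0, "annotation": 101, "cnv": 211, "depth": 307}


def stage_seed(master: int, stage: str) -> int:
    return (int(master) + STAGE_SEED_OFFSET[stage]) % (2**31 - 1)


_KNOWN_KEYS = {
    "seed",
    "autosomes",
    "simulate",
    "filter",
    "scan",
    "outliers",
    "derived",
    "cnv",
    "dels",
}


@dataclass
class RunConfig:
    seed: int = 0
    autosomes: list[str] | None = None
    simulate: dict = field(default_factory=dict)
    filter: dict = field(default_factory=dict)
    scan: dict = field(default_factory=dict)
    outliers: dict = field(default_factory=dict)
    derived: dict = field(default_factory=dict)
    cnv: dict = field(default_factory=dict)
    dels: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class CombinedReport:
    gene_lists: dict[str, list[str]]
    union: list[str]
    provenance: dict[str, list[str]]
    overlap: pd.DataFrame

    def to_json(self) -> str:
        return json.dumps(
            {
                "gene_lists": self.gene_lists,
                "union": self.union,
                "provenance": self.provenance,
                "overlap_matrix": {
                    a: {b: int(self.overlap.loc[a, b]) for b in self.overlap.columns}
                    for a in self.overlap.index
                },
            },
            indent=2,
            sort_keys=True,
        )


def report_overlap(gene_lists: dict[str, list[str]]) -> pd.DataFrame:
    """Pairwise gene-set intersection counts between approaches."""
    names = list(gene_lists)
    sets = {n: set(gene_lists[n]) for n in names}
    mat = pd.DataFrame(
        [[len(sets[a] & sets[b]) for b in names] for a in names],
        index=names,
        columns=names,
        dtype=int,
    )
    return mat


def _build_cohort_spec(cfg: RunConfig, stage: str) -> sim.CohortSpec:
    s = cfg.simulate
    return sim.CohortSpec(
        n_focal=s.get("n_focal", 28),
        n_sister=s.get("n_sister", 13),
        n_comparison=s.get("n_comparison", 12),
        chrom_lengths=dict(s.get("chrom_lengths", {"chr1": 2_000_000})),
        n_sites=s.get("n_sites", 20_000),
        drift_f=dict(s.get("drift_f", sim.DEFAULT_DRIFT)),
        ancestral_freq_dist=tuple(s.get("ancestral_freq_dist", (0.8, 0.8))),
        gt_depth_mean=s.get("gt_depth_mean", 20.0),
        seed=stage_seed(cfg.seed, stage),
    )


def simulate_artifacts(cfg: RunConfig, outdir: str | Path) -> dict:
    """Run the simulation stage alone and write its artifacts.

    Returns the in-memory objects keyed by name (``spec``, ``genotypes``,
    ``genes``, ``effects``, ``cnv_matrix``, ``tracks``, truth tables and the
    raw injection lists) so the full pipeline can continue without
    re-reading files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scfg = cfg.simulate

    logger.info("stage simulate")
    spec = _build_cohort_spec(cfg, "genotypes")
    sweeps = [sim.SweepSpec(**sw) for sw in scfg.get("sweeps", [])]
    genotypes, sweep_truth = sim.simulate_genotypes(spec, sweeps)

    ann_spec = replace(spec, seed=stage_seed(cfg.seed, "annotation"))
    planted = [sim.PlantedVariant(**pv) for pv in scfg.get("derived_variants", [])]
    genes, effects, variant_truth, genotypes = sim.simulate_annotation(
        ann_spec,
        n_genes=scfg.get("n_genes", 40),
        derived_variants=planted,
        genotypes=genotypes,
        n_background_effects=scfg.get("n_background_effects", 50),
    )

    cnv_cfg = scfg.get("cnv", {})
    cnv_spec = replace(spec, seed=stage_seed(cfg.seed, "cnv"))
    outlier_loci = [
        (o["index"], o["focal_freqs"], o["comparison_freqs"])
        for o in cnv_cfg.get("outliers", [])
    ]
    locus_intervals = {
        int(k): tuple(v) for k, v in cnv_cfg.get("locus_intervals", {}).items()
    }
    cnv_matrix, cnv_truth = sim.simulate_cnv_matrix(
        cnv_spec,
        n_loci=cnv_cfg.get("n_loci", 200),
        outlier_loci=outlier_loci,
        background_freqs=cnv_cfg.get("background_freqs"),
        locus_intervals=locus_intervals or None,
    )

    depth_cfg = scfg.get("depth", {})
    depth_spec = replace(spec, seed=stage_seed(cfg.seed, "depth"))
    deletions = [tuple(d) for d in depth_cfg.get("deletions", [])]
    unmappable = [tuple(u) for u in depth_cfg.get("unmappable", [])]
    tracks, depth_truth = sim.simulate_depth_tracks(
        depth_spec,
        deletions=deletions,
        mean_depth_per_genome=depth_cfg.get("mean_depth", 10.0),
        unmappable=unmappable,
        n_focal=depth_cfg.get("n_focal"),
        n_comparison=depth_cfg.get("n_comparison"),
    )

    aio.write_vcf(genotypes, outdir / "cohort.vcf", spec.chrom_lengths)
    aio.write_manifest(genotypes.populations, outdir / "populations.tsv")
    aio.write_gff3(genes, outdir / "genes.gff3")
    aio.write_effect_table(effects, outdir / "effects.tsv")
    aio.write_cnv_matrix(cnv_matrix, outdir / "cnv_matrix.tsv")
    sweep_truth.write(outdir / "truth_sweeps.tsv")
    variant_truth.write(outdir / "truth_variants.tsv")
    cnv_truth.write(outdir / "truth_cnv.tsv")
    depth_truth.write(outdir / "truth_deletions.tsv")

    return {
        "spec": spec,
        "genotypes": genotypes,
        "genes": genes,
        "effects": effects,
        "cnv_matrix": cnv_matrix,
        "tracks": tracks,
        "sweep_truth": sweep_truth,
        "variant_truth": variant_truth,
        "cnv_truth": cnv_truth,
        "depth_truth": depth_truth,
        "unmappable": unmappable,
    }


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> CombinedReport:
    """Execute every stage in order, writing all intermediates to ``outdir``.

    Returns the combined candidate-gene report; also written as
    ``combined_report.json`` together with per-stage TSV/BED/VCF artifacts.
    """
    outdir = Path(outdir)
    art = simulate_artifacts(cfg, outdir)
    spec = art["spec"]
    genotypes = art["genotypes"]
    genes = art["genes"]
    effects = art["effects"]
    cnv_matrix = art["cnv_matrix"]
    tracks = art["tracks"]
    unmappable = art["unmappable"]

    # ---- filter -----------------------------------------------------------
    logger.info("stage filter")
    fcfg = FilterConfig(**cfg.filter) if cfg.filter else FilterConfig()
    filtered, freport = apply_filters(genotypes, indel_positions=[], cfg=fcfg)
    with open(outdir / "filter_report.json", "w") as fh:
        json.dump(freport.as_dict(), fh, indent=2, sort_keys=True)
    aio.write_vcf(filtered, outdir / "filtered.vcf", spec.chrom_lengths)

    # ---- scan -------------------------------------------------------------
    logger.info("stage scan")
    windows = popstats.windowed_scan(
        filtered,
        window=cfg.scan.get("window", 50_000),
        step=cfg.scan.get("step", 10_000),
        min_sites=cfg.scan.get("min_sites", 10),
        chrom_lengths=spec.chrom_lengths,
    )
    windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)

    # ---- outliers ---------------------------------------------------------
    logger.info("stage outliers")
    cds = aio.IntervalSet(genes.df[genes.df["kind"] == "CDS"].reset_index(drop=True))
    report = outliers_mod.call_outliers(
        windows, percentile=cfg.outliers.get("percentile", 99.9)
    )
    report = outliers_mod.annotate_outliers(report, cds)
    contrast = outliers_mod.d_contrast(report.windows)
    aio.write_bed(report.outlier_windows, outdir / "pbs_outlier_windows.bed")
    aio.write_bed(report.merged_regions, outdir / "pbs_outlier_regions.bed")
    report.genes_hit.to_csv(outdir / "pbs_genes.tsv", sep="\t", index=False)
    contrast.to_csv(outdir / "d_contrast.tsv", sep="\t", index=False)

    # ---- derived-allele filter -------------------------------------------
    logger.info("stage derived")
    variants = derived_mod.build_effect_variants(filtered, effects)
    retained = derived_mod.frequency_filter(
        variants,
        min_focal=cfg.derived.get("min_focal", 0.7),
        max_comparison=cfg.derived.get("max_comparison", 0.25),
        min_call_rate=cfg.derived.get("min_call_rate", 0.5),
    )
    gene_summary = derived_mod.summarize_genes(retained)
    retained.to_csv(outdir / "derived_retained.tsv", sep="\t", index=False)
    gene_summary.to_csv(outdir / "derived_genes.tsv", sep="\t", index=False)

    # ---- CNV DAPC ---------------------------------------------------------
    logger.info("stage cnv")
    dapc_res = cnv_mod.dapc(
        cnv_matrix,
        groups={"focal": ["focal"], "mainland": ["sister", "comparison"]},
        n_pcs=cfg.cnv.get("n_pcs", 5),
        threshold=cfg.cnv.get("threshold", 0.0005),
    )
    cnv_genes = cnv_mod.cnv_gene_overlap(cnv_matrix, dapc_res.outlier_loci, cds)
    dapc_res.loading_table().to_csv(outdir / "cnv_loadings.tsv", sep="\t", index=False)
    dapc_res.coords.to_csv(outdir / "cnv_discriminant_coords.tsv", sep="\t", index=False)
    cnv_genes.to_csv(outdir / "cnv_genes.tsv", sep="\t", index=False)
    outlier_set = cnv_matrix.loci.df[
        cnv_matrix.loci.df["name"].isin(dapc_res.outlier_loci)
    ].reset_index(drop=True)
    if len(outlier_set):
        aio.write_bed(aio.IntervalSet(outlier_set), outdir / "cnv_outliers.bed")

    # ---- deletions --------------------------------------------------------
    logger.info("stage dels")
    unmap_set = (
        aio.IntervalSet.from_records(
            [(c, s, e, "") for c, s, e in unmappable], kind="unmappable"
        )
        if unmappable
        else aio.IntervalSet(pd.DataFrame(columns=aio.INTERVAL_COLUMNS))
    )
    mask = dels_mod.mask_from_intervals(unmap_set, merge_gap=cfg.dels.get("merge_gap", 250))
    sums = dels_mod.sum_depth(tracks, mask)
    autosomes = cfg.autosomes or list(spec.chrom_lengths)
    calls = dels_mod.call_deletions(
        sums,
        expected_focal=tracks.expected_cohort_depth("focal"),
        expected_comparison=tracks.expected_cohort_depth("comparison"),
        window=cfg.dels.get("window", 100),
        min_comparison_frac=cfg.dels.get("min_comparison_frac", 0.5),
        merge_gap=cfg.dels.get("merge_gap", 250),
        low_frac=cfg.dels.get("low_frac", 0.05),
        min_length=cfg.dels.get("min_length", 500),
        autosomes=[c for c in autosomes if c in sums],
    )
    del_genes = dels_mod.deletion_gene_overlap(calls, cds)
    aio.write_bed(mask.intervals, outdir / "mappability_mask.bed")
    aio.write_bed(dels_mod.deletion_calls_to_intervals(calls), outdir / "deletions.bed")
    del_genes.to_csv(outdir / "deletion_genes.tsv", sep="\t", index=False)

    # ---- combined report --------------------------------------------------
    logger.info("stage combine")
    gene_lists = {
        "pbs": sorted(report.genes_hit["gene"].unique().tolist()),
        "derived": sorted(gene_summary["gene"].unique().tolist()),
        "cnv": sorted(cnv_genes["gene"].unique().tolist()),
        "deletion": sorted(del_genes["gene"].unique().tolist()),
    }
    union = sorted(set().union(*gene_lists.values()))
    provenance = {
        g: sorted(a for a, lst in gene_lists.items() if g in lst) for g in union
    }
    combined = CombinedReport(
        gene_lists=gene_lists,
        union=union,
        provenance=provenance,
        overlap=report_overlap(gene_lists),
    )
    (outdir / "combined_report.json").write_text(combined.to_json())
    return combined


def demo_config(seed: int = 0) -> RunConfig:
    """A compact, fully planted demonstration cohort (two 1 Mb chromosomes).

    Signals are deliberately planted in disjoint genes so the
    inter-approach overlap matrix has a known (all-zero off-diagonal)
    truth: sweeps over genes 2 and 8, qualifying coding variants in genes
    22/25/28, fixed deletions over the CDS of genes 14 and 17, and outlier
    CNV loci over the CDS of genes 33 and 36.
    """
    chrom_lengths = {"chr1": 1_000_000, "chr2": 1_000_000}
    # gene layout mirrors sim.simulate_annotation: 20 genes per chromosome,
    # slot width 50 kb, gene length 6 kb centred in the slot, CDS middle 60%
    def gene_cds(idx: int) -> tuple[str, int, int]:
        chrom = "chr1" if idx < 20 else "chr2"
        k = idx % 20
        slot = 50_000
        start = k * slot + (slot - 6_000) // 2
        return chrom, start + 1_200, start + 4_800

    def gene_center(idx: int) -> tuple[str, int]:
        chrom, cs, ce = gene_cds(idx)
        return chrom, (cs + ce) // 2

    sweeps = []
    for gi in (2, 8):
        chrom, center = gene_center(gi)
        sweeps.append(
            {"chrom": chrom, "center": center, "halfwidth": 25_000, "focal_freq": 0.95, "other_freq": 0.05}
        )
    deletions = []
    for gi in (14, 17):
        chrom, cs, ce = gene_cds(gi)
        deletions.append([chrom, cs - 200, cs + 1_300])  # 1.5 kb over the CDS start
    cnv_locus_intervals = {}
    cnv_outliers = []
    for i, gi in enumerate((33, 36)):
        chrom, cs, ce = gene_cds(gi)
        cnv_locus_intervals[i] = [chrom, cs, ce]
        cnv_outliers.append(
            {
                "index": i,
                "focal_freqs": {"A": 0.05, "CN0": 0.95, "CN2": 0.0, "CNH": 0.0},
                "comparison_freqs": {"A": 0.95, "CN0": 0.05, "CN2": 0.0, "CNH": 0.0},
            }
        )
    return RunConfig(
        seed=seed,
        autosomes=["chr1", "chr2"],
        simulate={
            "n_focal": 28,
            "n_sister": 13,
            "n_comparison": 12,
            "chrom_lengths": chrom_lengths,
            "n_sites": 20_000,
            "drift_f": {"internal": 0.05, "focal": 0.08, "sister": 0.05, "comparison": 0.05},
            "sweeps": sweeps,
            "n_genes": 40,
            "derived_variants": [
                {"gene": 22, "effect_class": "MODERATE", "focal_freq": 0.8, "comparison_freq": 0.1},
                {"gene": 25, "effect_class": "HIGH", "focal_freq": 1.0, "comparison_freq": 0.0},
                {"gene": 28, "effect_class": "MODERATE", "focal_freq": 0.9, "comparison_freq": 0.1},
            ],
            "cnv": {
                "n_loci": 120,
                "outliers": cnv_outliers,
                "locus_intervals": cnv_locus_intervals,
            },
            "depth": {
                "mean_depth": {"focal": 23.0, "comparison": 11.2},
                "n_comparison": 11,
                "deletions": deletions,
                "unmappable": [["chr1", 300_000, 300_400], ["chr2", 650_000, 650_300]],
            },
        },
        scan={"window": 50_000, "step": 10_000, "min_sites": 10},
        outliers={"percentile": 99.9},
        # at the demo's 120 CNV loci (~240 variables) the normalized-loading
        # noise floor sits far above the genome-scale default threshold, so
        # the demo uses a threshold proportionate to its variable count
        cnv={"n_pcs": 5, "threshold": 0.01},
    )
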