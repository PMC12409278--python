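"""Site- and genotype-level quality filters applied before any statistic.

The filters mirror standard short-read variant-calling hygiene for a
medium-coverage cohort: a per-genotype depth floor, an allelic-balance check
on heterozygous calls, removal of SNPs adjacent to indels, and exclusion of
the X chromosome (all frequency statistics here assume autosomal diploidy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from arctic_sweep.io import MISSING, GenotypeTable


@dataclass
class FilterConfig:
    min_gt_depth: int = 5
    min_base_qual: int = 30  # provenance only: base quality is applied upstream
    indel_exclusion_radius: int = 5
    allelic_balance_bounds: tuple[float, float] = (0.2, 0.8)
    exclude_chroms: tuple[str, ...] = ("chrX",)

    def __post_init__(self) -> None:
        low, high = self.allelic_balance_bounds
        if not 0 <= low < high <= 1:
            raise ValueError("allelic balance bounds must satisfy 0 <= low < high <= 1")
        if self.min_gt_depth < 0 or self.indel_exclusion_radius < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class FilterReport:
    n_sites_in: int = 0
    n_sites_out: int = 0
    n_sites_removed_chrom: int = 0
    n_sites_removed_indel: int = 0
    n_genotypes_masked_depth: int = 0
    n_genotypes_masked_balance: int = 0
    min_base_qual: int = 30

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def apply_filters(
    gt: GenotypeTable,
    indel_positions: list[tuple[str, int]] | None = None,
    cfg: FilterConfig | None = None,
) -> tuple[GenotypeTable, FilterReport]:
    """Mask low-quality genotypes and drop excluded/indel-adjacent sites.

    Genotype-level: calls with depth below ``min_gt_depth`` become missing;
    heterozygous calls whose reference-allele balance (AD_ref / DP) falls
    outside ``allelic_balance_bounds`` become missing (homozygous calls are
    exempt — a balance of 0 or 1 is what a correct homozygote looks like).
    Site-level: sites on ``exclude_chroms`` are removed, as are SNPs within
    ``indel_exclusion_radius`` bp of an indel anchor position
    (``|snp - indel| <= radius``).
    """
    cfg = cfg or FilterConfig()
    indel_positions = indel_positions or []
    report = FilterReport(n_sites_in=gt.n_sites, min_base_qual=cfg.min_base_qual)

    dosage = gt.dosage.copy()
    called = dosage != MISSING

    low_depth = called & (gt.depth < cfg.min_gt_depth)
    report.n_genotypes_masked_depth = int(low_depth.sum())
    dosage[low_depth] = MISSING
    called &= ~low_depth

    het = called & (dosage == 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        balance = np.where(gt.depth > 0, gt.ad_ref / np.maximum(gt.depth, 1), np.nan)
    low, high = cfg.allelic_balance_bounds
    bad_balance = het & ((balance < low) | (balance > high))
    report.n_genotypes_masked_balance = int(bad_balance.sum())
    dosage[bad_balance] = MISSING

    chroms = gt.sites["chrom"].to_numpy()
    pos = gt.sites["pos0"].to_numpy()
    keep = ~np.isin(chroms, list(cfg.exclude_chroms))
    report.n_sites_removed_chrom = int((~keep).sum())

    near_indel = np.zeros(gt.n_sites, dtype=bool)
    by_chrom: dict[str, list[int]] = {}
    for chrom, p in indel_positions:
        by_chrom.setdefault(chrom, []).append(p)
    for chrom, plist in by_chrom.items():
        anchors = np.sort(np.asarray(plist))
        on_chrom = chroms == chrom
        if not on_chrom.any():
            continue
        idx = np.searchsorted(anchors, pos[on_chrom])
        dist = np.full(int(on_chrom.sum()), np.iinfo(np.int64).max)
        has_right = idx < len(anchors)
        dist[has_right] = np.abs(anchors[idx[has_right]] - pos[on_chrom][has_right])
        has_left = idx > 0
        dist[has_left] = np.minimum(
            dist[has_left], np.abs(pos[on_chrom][has_left] - anchors[idx[has_left] - 1])
        )
        sub = np.zeros_like(near_indel)
        sub[on_chrom] = dist <= cfg.indel_exclusion_radius
        near_indel |= sub
    report.n_sites_removed_indel = int((keep & near_indel).sum())
    keep &= ~near_indel

    out = GenotypeTable(
        sites=gt.sites[keep].reset_index(drop=True),
        dosage=dosage[keep],
        depth=gt.depth[keep],
        ad_ref=gt.ad_ref[keep],
        samples=list(gt.samples),
        populations=dict(gt.populations),
        outgroup=None if gt.outgroup is None else gt.outgroup[keep],
    )
    report.n_sites_out = out.n_sites
    return out, report
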