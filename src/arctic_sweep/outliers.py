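"""Empirical-percentile outlier calling on PBS windows, gene annotation, and
the Tajima's D contrast between outlier and background windows."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arctic_sweep.io import IntervalSet, intersect, merge_intervals
from arctic_sweep.popstats import ROLES


@dataclass
class OutlierReport:
    threshold_value: float
    percentile: float
    windows: pd.DataFrame  # scan table with is_outlier column
    outlier_windows: IntervalSet
    merged_regions: IntervalSet
    genes_hit: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["gene", "chrom", "start", "end", "max_pbs"])
    )
    d_contrast: pd.DataFrame | None = None


def call_outliers(windows: pd.DataFrame, percentile: float = 99.9) -> OutlierReport:
    """Flag windows whose PBS reaches the empirical percentile threshold.

    The threshold is the linearly interpolated empirical percentile of
    ``pbs_focal`` over *defined* windows, pooled genome-wide; windows with
    ``PBS >= threshold`` are outliers (ties at the threshold are included).
    """
    defined = windows[windows["defined"].astype(bool)].copy()
    if defined.empty:
        raise ValueError("no defined windows to compute a percentile over")
    if len(defined) < 1000:
        warnings.warn(
            f"only {len(defined)} defined windows; the {percentile}th percentile "
            "is poorly resolved below ~1000 windows",
            stacklevel=2,
        )
    threshold = float(np.percentile(defined["pbs_focal"].to_numpy(), percentile))
    out = windows.copy()
    out["is_outlier"] = out["defined"].astype(bool) & (out["pbs_focal"] >= threshold)
    flagged = out[out["is_outlier"]]
    outlier_windows = (
        IntervalSet.from_records(
            [
                (r.chrom, r.start, r.end, f"win_{i}")
                for i, r in enumerate(flagged.itertuples(index=False))
            ],
            kind="window",
        )
        if len(flagged)
        else IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "name", "kind"]))
    )
    merged = (
        merge_intervals(outlier_windows, max_gap=0)
        if len(outlier_windows)
        else outlier_windows
    )
    return OutlierReport(
        threshold_value=threshold,
        percentile=percentile,
        windows=out,
        outlier_windows=outlier_windows,
        merged_regions=merged,
    )


def annotate_outliers(report: OutlierReport, genes: IntervalSet) -> OutlierReport:
    """Intersect outlier windows with CDS intervals; one row per gene hit.

    ``max_pbs`` is the largest PBS among the outlier windows overlapping the
    gene.  Overlap is half-open, so a single shared base pair counts.
    """
    flagged = report.windows[report.windows["is_outlier"]].reset_index(drop=True)
    if flagged.empty or len(genes) == 0:
        report.genes_hit = pd.DataFrame(columns=["gene", "chrom", "start", "end", "max_pbs"])
        return report
    win_set = IntervalSet.from_records(
        [(r.chrom, r.start, r.end, str(i)) for i, r in enumerate(flagged.itertuples(index=False))],
        kind="window",
    )
    hits: dict[str, dict] = {}
    for wi, gi in intersect(win_set, genes):
        win_row = flagged.iloc[int(win_set.df["name"].iat[wi])]
        gene = genes.df.iloc[gi]
        entry = hits.setdefault(
            gene["name"],
            {
                "gene": gene["name"],
                "chrom": gene["chrom"],
                "start": int(gene["start"]),
                "end": int(gene["end"]),
                "max_pbs": -np.inf,
            },
        )
        entry["max_pbs"] = max(entry["max_pbs"], float(win_row["pbs_focal"]))
    report.genes_hit = (
        pd.DataFrame(sorted(hits.values(), key=lambda h: h["gene"]))
        if hits
        else pd.DataFrame(columns=["gene", "chrom", "start", "end", "max_pbs"])
    )
    return report


def d_contrast(windows: pd.DataFrame) -> pd.DataFrame:
    """Mean Tajima's D and proportion of positive values, by outlier class.

    Expects the scan table with an ``is_outlier`` column.  Returns one row
    per (population, class) with ``mean_d``, ``prop_positive`` and
    ``n_windows``; a class with no windows carrying a defined D yields NaN
    summaries.
    """
    if "is_outlier" not in windows.columns:
        raise ValueError("call_outliers must run before d_contrast")
    rows = []
    for role in ROLES:
        col = windows[f"d_{role}"]
        for label, mask in (
            ("outlier", windows["is_outlier"]),
            ("non_outlier", windows["defined"].astype(bool) & ~windows["is_outlier"]),
        ):
            vals = col[mask].dropna()
            rows.append(
                {
                    "population": role,
                    "klass": label,
                    "n_windows": len(vals),
                    "mean_d": float(vals.mean()) if len(vals) else np.nan,
                    "prop_positive": float((vals > 0).mean()) if len(vals) else np.nan,
                }
            )
    return pd.DataFrame(rows)
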