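"""Outgroup polarization and the derived-allele frequency-differential filter.

The filter retains effect-annotated coding variants whose derived allele is
at high frequency (default >= 0.7) in the focal population and low
frequency (default <= 0.25) in the pooled mainland comparison group, with a
per-population call-rate floor.  The asymmetric thresholds deliberately
leave room for post-selection drift in the focal population and for the
selected allele to have segregated as standing variation in the source
populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from arctic_sweep.io import MISSING, GenotypeTable

EFFECT_CLASSES = ("HIGH", "MODERATE", "LOW", "MODIFIER")
KEPT_CLASSES = ("HIGH", "MODERATE")


def polarize(gt: GenotypeTable, outgroup_alleles: np.ndarray | None = None) -> pd.DataFrame:
    """Assign the derived allele per site from the outgroup-species allele.

    The ancestral allele is the outgroup allele when it matches REF or ALT;
    the derived allele is then the other one.  Sites where the outgroup
    allele matches neither, or is missing, are marked unpolarized
    (``derived = ""``) and must be excluded downstream.

    Returns a DataFrame aligned with ``gt.sites``: columns ``derived`` and
    ``polarized``.
    """
    if outgroup_alleles is None:
        outgroup_alleles = gt.outgroup
    if outgroup_alleles is None:
        raise ValueError("no outgroup alleles available for polarization")
    ref = gt.sites["ref"].to_numpy()
    alt = gt.sites["alt"].to_numpy()
    og = np.asarray(outgroup_alleles, dtype=object)
    derived = np.where(og == ref, alt, np.where(og == alt, ref, ""))
    return pd.DataFrame(
        {"derived": derived, "polarized": derived != ""}, index=gt.sites.index
    )


def _pop_freqs(gt: GenotypeTable, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt-allele frequency, call rate) per site over the given samples."""
    sub = gt.dosage[:, cols]
    called = sub != MISSING
    n_called = called.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        freq = np.where(n_called > 0, np.where(called, sub, 0).sum(axis=1) / (2 * n_called), np.nan)
    return freq, n_called / len(cols)


def build_effect_variants(
    gt: GenotypeTable,
    effects: pd.DataFrame,
    outgroup_alleles: np.ndarray | None = None,
    comparison_pops: tuple[str, ...] = ("sister", "comparison"),
) -> pd.DataFrame:
    """Join effect annotations to polarized per-population derived frequencies.

    ``effects`` carries ``chrom, pos0, ref, alt, gene, effect_class`` (the
    shape of an effect-predictor output).  Unpolarized sites and annotations
    with no matching genotype record are dropped.

    Returns one row per effect variant with ``derived_freq_focal``,
    ``derived_freq_comparison`` (pooled over ``comparison_pops``),
    and per-population call rates.
    """
    pol = polarize(gt, outgroup_alleles)
    focal_cols = gt.sample_indices("focal")
    comp_cols = gt.sample_indices(list(comparison_pops))
    alt_freq_f, call_f = _pop_freqs(gt, focal_cols)
    alt_freq_c, _ = _pop_freqs(gt, comp_cols)
    # the comparison frequency is pooled, but the call-rate floor applies to
    # each comparison population separately
    per_pop_call = {
        pop: _pop_freqs(gt, gt.sample_indices(pop))[1] for pop in comparison_pops
    }
    call_c_min = np.minimum.reduce(list(per_pop_call.values()))

    site_key = pd.MultiIndex.from_frame(gt.sites[["chrom", "pos0"]])
    lookup = pd.Series(np.arange(gt.n_sites), index=site_key)

    rows = []
    for rec in effects.itertuples(index=False):
        key = (rec.chrom, rec.pos0)
        if key not in lookup.index:
            continue
        i = int(lookup[key])
        if not pol["polarized"].iat[i]:
            continue
        derived = pol["derived"].iat[i]
        derived_is_alt = derived == gt.sites["alt"].iat[i]
        f_f = alt_freq_f[i] if derived_is_alt else 1.0 - alt_freq_f[i]
        f_c = alt_freq_c[i] if derived_is_alt else 1.0 - alt_freq_c[i]
        rows.append(
            {
                "chrom": rec.chrom,
                "pos0": rec.pos0,
                "ref": rec.ref,
                "alt": rec.alt,
                "gene": rec.gene,
                "effect_class": rec.effect_class,
                "derived": derived,
                "derived_freq_focal": f_f,
                "derived_freq_comparison": f_c,
                "call_rate_focal": call_f[i],
                "call_rate_comparison": call_c_min[i],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos0",
            "ref",
            "alt",
            "gene",
            "effect_class",
            "derived",
            "derived_freq_focal",
            "derived_freq_comparison",
            "call_rate_focal",
            "call_rate_comparison",
        ],
    )


def frequency_filter(
    variants: pd.DataFrame,
    min_focal: float = 0.7,
    max_comparison: float = 0.25,
    min_call_rate: float = 0.5,
) -> pd.DataFrame:
    """Retain HIGH/MODERATE variants with a focal-vs-comparison frequency differential.

    Keep iff derived frequency >= ``min_focal`` in the focal population AND
    <= ``max_comparison`` in the comparison pool AND call rate >=
    ``min_call_rate`` in every population.  Bounds are inclusive.  LOW and
    MODIFIER classes are dropped before the frequency test.
    """
    classed = variants[variants["effect_class"].isin(KEPT_CLASSES)]
    keep = (
        (classed["derived_freq_focal"] >= min_focal)
        & (classed["derived_freq_comparison"] <= max_comparison)
        & (classed["call_rate_focal"] >= min_call_rate)
        & (classed["call_rate_comparison"] >= min_call_rate)
    )
    return classed[keep].reset_index(drop=True)


def summarize_genes(retained: pd.DataFrame) -> pd.DataFrame:
    """Per-gene variant counts by effect class (genes deduplicated)."""
    if retained.empty:
        return pd.DataFrame(columns=["gene", "n_variants", "n_high", "n_moderate"])
    grouped = retained.groupby("gene")
    out = pd.DataFrame(
        {
            "gene": list(grouped.groups),
            "n_variants": grouped.size().to_numpy(),
            "n_high": grouped["effect_class"].apply(lambda s: int((s == "HIGH").sum())).to_numpy(),
            "n_moderate": grouped["effect_class"]
            .apply(lambda s: int((s == "MODERATE").sum()))
            .to_numpy(),
        }
    )
    return out.sort_values("gene").reset_index(drop=True)
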