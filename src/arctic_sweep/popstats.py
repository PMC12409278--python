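"""Core population-genetic statistics: Hudson F_ST, PBS, and Tajima's D.

Site statistics are aggregated into sliding windows (default 50 kb windows
with a 10 kb step).  Window F_ST is the Hudson estimator combined by ratio
of sums — per-site numerators and denominators are summed separately across
the window before dividing — which is the standard small-sample-robust
aggregation.  PBS is the focal-branch length after the ``-log(1 - F_ST)``
transform of the three pairwise values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from arctic_sweep.io import GenotypeTable

FST_CLAMP = 1.0 - 1e-9
ROLES = ("focal", "sister", "comparison")


def hudson_fst_site(p1: float, n1: int, p2: float, n2: int) -> tuple[float, float]:
    """Per-site Hudson F_ST numerator and denominator.

    ``numerator = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)`` and
    ``denominator = p1(1-p2) + p2(1-p1)``, where ``n`` counts called
    chromosomes.  Both are returned so callers can aggregate windows as a
    ratio of sums.  Requires ``n1, n2 >= 2``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("hudson_fst_site needs >= 2 called chromosomes per population")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def _hudson_site_arrays(
    k1: np.ndarray, n1: np.ndarray, k2: np.ndarray, n2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-site Hudson terms; sites with n < 2 flagged invalid."""
    valid = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = np.where(valid, k1 / np.maximum(n1, 1), 0.0)
        p2 = np.where(valid, k2 / np.maximum(n2, 1), 0.0)
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / np.maximum(n1 - 1, 1) - p2 * (1 - p2) / np.maximum(
            n2 - 1, 1
        )
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num[~valid] = 0.0
    den[~valid] = 0.0
    return num, den, valid


def window_fst(num: np.ndarray, den: np.ndarray) -> float:
    """Ratio-of-sums window F_ST, clamped to ``[0, 1 - 1e-9]``."""
    total_den = float(np.sum(den))
    if total_den <= 0:
        return 0.0
    return float(np.clip(np.sum(num) / total_den, 0.0, FST_CLAMP))


def pbs(fst_fs: float, fst_fc: float, fst_sc: float) -> float:
    """Population branch statistic for the focal lineage.

    ``T_xy = -log(1 - F_ST,xy)``; ``PBS = (T_fs + T_fc - T_sc) / 2``.
    Inputs are clamped to ``[0, 1 - 1e-9]``; the result may be negative
    (reported as computed — negative values simply never reach the upper
    outlier tail).
    """
    t = [-math.log(1.0 - min(max(f, 0.0), FST_CLAMP)) for f in (fst_fs, fst_fc, fst_sc)]
    return (t[0] + t[1] - t[2]) / 2.0


@dataclass(frozen=True)
class TajimaConstants:
    """Normalizing constants for Tajima's D at haploid sample size ``n``."""

    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float

    @classmethod
    def for_n(cls, n: int) -> "TajimaConstants":
        if n < 3:
            raise ValueError("Tajima's D needs at least 3 sequences")
        i = np.arange(1, n)
        a1 = float(np.sum(1.0 / i))
        a2 = float(np.sum(1.0 / i**2))
        b1 = (n + 1) / (3.0 * (n - 1))
        b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
        c1 = b1 - 1.0 / a1
        c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
        e1 = c1 / a1
        e2 = c2 / (a1**2 + a2)
        return cls(n=n, a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(alt_count: np.ndarray, n_chrom: np.ndarray) -> float | None:
    """Tajima's D for one population over the sites of one window.

    ``alt_count[i]`` and ``n_chrom[i]`` are the alternate-allele count and
    the number of called chromosomes at site ``i``.  π is computed from
    allele counts as ``sum k(n-k) / C(n,2)`` with per-site ``n``; the
    normalizing constants use the window median of ``n`` over segregating
    sites.  Returns ``None`` when the window has no segregating site or
    fewer than 3 called chromosomes (undefined rather than NaN).
    """
    alt_count = np.asarray(alt_count, dtype=float)
    n_chrom = np.asarray(n_chrom, dtype=float)
    seg = (alt_count > 0) & (alt_count < n_chrom) & (n_chrom >= 2)
    s = int(seg.sum())
    if s == 0:
        return None
    k = alt_count[seg]
    n = n_chrom[seg]
    pi = float(np.sum(k * (n - k) / (n * (n - 1) / 2.0)))
    n_const = int(np.median(n))
    if n_const < 3:
        return None
    c = TajimaConstants.for_n(n_const)
    var = c.e1 * s + c.e2 * s * (s - 1)
    if var <= 0:
        return None
    return (pi - s / c.a1) / math.sqrt(var)


def windowed_scan(
    gt: GenotypeTable,
    window: int = 50_000,
    step: int = 10_000,
    min_sites: int = 10,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Sliding-window F_ST / PBS / Tajima's D scan over a genotype table.

    Windows are laid on fixed coordinates starting at 0 on each chromosome;
    the last partial window is retained.  Windows with fewer than
    ``min_sites`` sites are marked undefined (``defined=False``) and carry
    NaN statistics; they are excluded from downstream percentile thresholds.

    Population labels must be exactly ``focal``, ``sister``, ``comparison``.

    Returns a DataFrame with one row per window: ``chrom, start, end,
    n_sites, fst_fs, fst_fc, fst_sc, pbs_focal, d_focal, d_sister,
    d_comparison, defined``.
    """
    seen_roles = set(gt.populations.values())
    unknown = seen_roles - set(ROLES)
    if unknown:
        raise ValueError(f"unknown population roles: {sorted(unknown)}")
    if not set(ROLES) <= seen_roles:
        raise ValueError(f"scan needs all three roles {ROLES}, got {sorted(seen_roles)}")

    cols = {role: gt.sample_indices(role) for role in ROLES}
    counts = {role: gt.allele_counts(cols[role]) for role in ROLES}

    pair_terms = {}
    for a, b, key in (
        ("focal", "sister", "fs"),
        ("focal", "comparison", "fc"),
        ("sister", "comparison", "sc"),
    ):
        ka, na = counts[a]
        kb, nb = counts[b]
        pair_terms[key] = _hudson_site_arrays(ka, na, kb, nb)

    chrom_arr = gt.sites["chrom"].to_numpy()
    pos_arr = gt.sites["pos0"].to_numpy()
    rows = []
    chrom_order = list(dict.fromkeys(chrom_arr)) if chrom_lengths is None else list(chrom_lengths)
    for chrom in chrom_order:
        on = chrom_arr == chrom
        cpos = pos_arr[on]
        cidx = np.nonzero(on)[0]
        if chrom_lengths is not None:
            chrom_len = chrom_lengths[chrom]
        elif len(cpos):
            chrom_len = int(cpos.max()) + 1
        else:
            continue
        for start in range(0, max(chrom_len - 1, 1), step):
            end = min(start + window, chrom_len)
            lo, hi = np.searchsorted(cpos, [start, end])
            idx = cidx[lo:hi]
            n_sites = len(idx)
            row = {
                "chrom": chrom,
                "start": start,
                "end": end,
                "n_sites": n_sites,
                "defined": n_sites >= min_sites,
            }
            if n_sites >= min_sites:
                fsts = {}
                for key, (num, den, _valid) in pair_terms.items():
                    fsts[key] = window_fst(num[idx], den[idx])
                row["fst_fs"], row["fst_fc"], row["fst_sc"] = (
                    fsts["fs"],
                    fsts["fc"],
                    fsts["sc"],
                )
                row["pbs_focal"] = pbs(fsts["fs"], fsts["fc"], fsts["sc"])
                for role in ROLES:
                    k, nn = counts[role]
                    d = tajimas_d(k[idx], nn[idx])
                    row[f"d_{role}"] = np.nan if d is None else d
            else:
                for col in ("fst_fs", "fst_fc", "fst_sc", "pbs_focal", "d_focal", "d_sister", "d_comparison"):
                    row[col] = np.nan
            rows.append(row)
            if end >= chrom_len:
                break
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "n_sites",
            "fst_fs",
            "fst_fc",
            "fst_sc",
            "pbs_focal",
            "d_focal",
            "d_sister",
            "d_comparison",
            "defined",
        ],
    )
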