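"""CNV allele-class frequencies and DAPC outlier detection.

Copy-number genotypes are decomposed into unordered allele pairs over the
classes ``A`` (single copy), ``CN0`` (deletion), ``CN2`` (duplication) and
``CNH`` (more than two copies).  Differentiation between two predefined
groups is measured by DAPC: PCA dimension reduction of the per-allele-class
dosage matrix followed by a two-class linear discriminant in PC space; the
discriminant axis is rotated back to variable space and its squared
loadings, normalized to sum 1, are thresholded to call outlier loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arctic_sweep.io import CnvMatrix, IntervalSet, intersect
from arctic_sweep.sim import CNV_CLASSES, PAIR_FOR_COPY


def allele_pair(copy_number: int) -> tuple[str, str]:
    """Canonical unordered allele pair for a diploid copy number.

    0 -> (CN0, CN0), 1 -> (CN0, A), 2 -> (A, A), 3 -> (A, CN2),
    4 -> (CN2, CN2), >= 5 -> (CN2, CNH).  The decomposition of copy numbers
    above 2 is not unique in copy-number genotyping output; this mapping is
    the package's declared convention.
    """
    if copy_number < 0:
        raise ValueError("negative copy number")
    return PAIR_FOR_COPY[min(copy_number, 5)]


def cnv_allele_frequencies(m: CnvMatrix, groups: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Per-population allele-class frequencies for every CNV locus.

    Each individual contributes two alleles via :func:`allele_pair`.
    ``groups`` maps a group name to the population labels it pools; by
    default each population label is its own group.

    Returns one row per (locus, group) with columns ``A, CN0, CN2, CNH``
    summing to 1.
    """
    if groups is None:
        groups = {p: [p] for p in sorted(set(m.populations.values()))}
    rows = []
    loci_names = m.loci.df["name"].to_numpy()
    for gname, pops in groups.items():
        cols = m.individual_indices(pops)
        if len(cols) == 0:
            continue
        sub = m.copy_number[:, cols]
        for li in range(len(loci_names)):
            tally = dict.fromkeys(CNV_CLASSES, 0)
            for k in sub[li]:
                for cls in allele_pair(int(k)):
                    tally[cls] += 1
            total = 2 * len(cols)
            rows.append(
                {"locus": loci_names[li], "group": gname}
                | {cls: tally[cls] / total for cls in CNV_CLASSES}
            )
    return pd.DataFrame(rows, columns=["locus", "group", *CNV_CLASSES])


def dosage_matrix(m: CnvMatrix) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Individuals × (locus, allele-class) dosage matrix.

    The dosage of class ``c`` for an individual at a locus is the number of
    ``c`` alleles in its canonical pair (0, 1 or 2).  Classes absent from a
    locus across all individuals produce all-zero columns; they are kept
    here and dropped inside :func:`dapc`.
    """
    n_loci, n_ind = m.copy_number.shape
    names = m.loci.df["name"].to_numpy()
    cols: list[tuple[str, str]] = []
    mat = np.zeros((n_ind, n_loci * len(CNV_CLASSES)), dtype=float)
    class_idx = {c: i for i, c in enumerate(CNV_CLASSES)}
    for li in range(n_loci):
        for ci, cls in enumerate(CNV_CLASSES):
            cols.append((names[li], cls))
        for j in range(n_ind):
            for cls in allele_pair(int(m.copy_number[li, j])):
                mat[j, li * len(CNV_CLASSES) + class_idx[cls]] += 1
    return mat, cols


@dataclass
class DapcResult:
    n_pcs: int
    threshold: float
    variables: list[tuple[str, str]]  # (locus, allele class) per retained column
    loadings: np.ndarray  # normalized squared loadings, sum to 1
    discriminant_direction: np.ndarray  # unit vector in retained-variable space
    coords: pd.DataFrame  # per-individual discriminant coordinate + group
    outlier_loci: list[str]
    n_dropped_constant: int = 0

    def loading_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "locus": [v[0] for v in self.variables],
                "allele": [v[1] for v in self.variables],
                "loading": self.loadings,
            }
        )


def dapc(
    m: CnvMatrix,
    groups: dict[str, list[str]],
    n_pcs: int = 5,
    threshold: float = 0.0005,
) -> DapcResult:
    """Two-group DAPC on CNV allele-class dosages with a loading threshold.

    Columns are centered (not scaled), reduced by SVD-based PCA to
    ``n_pcs`` components, and a single linear discriminant between the two
    groups is computed in PC space using the pooled within-group
    covariance.  The discriminant axis is back-rotated to variable space;
    squared variable loadings are normalized to sum 1, and every locus with
    any allele-class loading strictly above ``threshold`` is an outlier.
    """
    if len(groups) != 2:
        raise ValueError("dapc compares exactly two groups")
    labels = {}
    for gname, pops in groups.items():
        for i in m.individual_indices(pops):
            labels[int(i)] = gname
    if len(labels) != len(m.individuals):
        raise ValueError("groups must cover every individual exactly once")
    y = np.array([labels[i] for i in range(len(m.individuals))])
    gnames = sorted(groups)
    for g in gnames:
        if (y == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 individuals")
    if n_pcs >= len(m.individuals):
        raise ValueError("n_pcs must be smaller than the number of individuals")

    x, cols = dosage_matrix(m)
    variances = x.var(axis=0)
    keep = variances > 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("all variables have zero variance")
    x = x[:, keep]
    cols = [c for c, k in zip(cols, keep) if k]

    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    k = min(n_pcs, rank)
    scores = u[:, :k] * s[:k]
    v = vt[:k].T  # variables × k rotation

    mask1 = y == gnames[0]
    mask2 = ~mask1
    mu1 = scores[mask1].mean(axis=0)
    mu2 = scores[mask2].mean(axis=0)
    w = np.zeros((k, k))
    for mask in (mask1, mask2):
        dev = scores[mask] - scores[mask].mean(axis=0)
        w += dev.T @ dev
    w /= len(y) - 2
    # pooled-covariance LDA direction in PC space; ridge for degenerate pools
    try:
        a = np.linalg.solve(w, mu2 - mu1)
    except np.linalg.LinAlgError:
        a = np.linalg.solve(w + 1e-8 * np.eye(k), mu2 - mu1)

    direction = v @ a
    direction /= np.linalg.norm(direction)
    sq = direction**2
    loadings = sq / sq.sum()

    coord = xc @ direction
    coords = pd.DataFrame(
        {"individual": m.individuals, "group": y, "ld1": coord}
    )
    locus_max: dict[str, float] = {}
    for (locus, _cls), ld in zip(cols, loadings):
        locus_max[locus] = max(locus_max.get(locus, 0.0), float(ld))
    outliers = sorted(l for l, ld in locus_max.items() if ld > threshold)
    return DapcResult(
        n_pcs=k,
        threshold=threshold,
        variables=cols,
        loadings=loadings,
        discriminant_direction=direction,
        coords=coords,
        outlier_loci=outliers,
        n_dropped_constant=n_dropped,
    )


def cnv_gene_overlap(
    m: CnvMatrix, outlier_loci: list[str], genes: IntervalSet
) -> pd.DataFrame:
    """Half-open intersection of outlier CNV intervals with CDS intervals."""
    sub = m.loci.df[m.loci.df["name"].isin(outlier_loci)].reset_index(drop=True)
    if sub.empty or len(genes) == 0:
        return pd.DataFrame(columns=["locus", "gene", "chrom", "start", "end"])
    loci_set = IntervalSet(sub)
    rows = []
    for li, gi in intersect(loci_set, genes):
        rows.append(
            {
                "locus": loci_set.df["name"].iat[li],
                "gene": genes.df["name"].iat[gi],
                "chrom": genes.df["chrom"].iat[gi],
                "start": int(genes.df["start"].iat[gi]),
                "end": int(genes.df["end"].iat[gi]),
            }
        )
    return (
        pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)
        if rows
        else pd.DataFrame(columns=["locus", "gene", "chrom", "start", "end"])
    )
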