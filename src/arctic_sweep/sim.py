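"""Synthetic three-population cohorts with machine-readable truth tables.

The generator emulates the statistical structure the selection analyses
assume: a focal island population and its sister population diverging from a
shared ancestor, with a more distant comparison population — topology
``((focal, sister), comparison)`` — under a hierarchical Balding–Nichols
drift model.  On top of the neutral background it injects, each with a truth
record:

* selective-sweep loci (focal derived-allele frequency forced high),
* effect-annotated coding variants at controlled population frequencies,
* large fixed deletions in per-genome read-depth tracks, and
* differentiated copy-number loci.

The Balding–Nichols kernel draws a child population's allele frequency from
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` given parent frequency ``p`` and a branch
drift parameter ``F``; it satisfies ``E[F_ST] ≈ F`` between parent and
child, which makes the generator analytically checkable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from arctic_sweep.io import (
    MISSING,
    CnvMatrix,
    DepthTrackSet,
    GenotypeTable,
    IntervalSet,
)

BASES = np.array(["A", "C", "G", "T"])

DEFAULT_DRIFT = {"internal": 0.05, "focal": 0.08, "sister": 0.05, "comparison": 0.05}

#: per-allele haploid copy contribution of each CNV allele class
ALLELE_COPIES = {"CN0": 0, "A": 1, "CN2": 2, "CNH": 3}
CNV_CLASSES = ["A", "CN0", "CN2", "CNH"]
#: canonical unordered allele pair for each diploid copy number
PAIR_FOR_COPY = {
    0: ("CN0", "CN0"),
    1: ("CN0", "A"),
    2: ("A", "A"),
    3: ("A", "CN2"),
    4: ("CN2", "CN2"),
    5: ("CN2", "CNH"),
}


@dataclass
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the cohort structure the analyses are designed around:
    28 focal, 13 sister and 12 comparison diploid individuals.
    """

    n_focal: int = 28
    n_sister: int = 13
    n_comparison: int = 12
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"chr1": 2_000_000})
    n_sites: int = 20_000
    drift_f: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_DRIFT))
    ancestral_freq_dist: tuple[float, float] = (0.8, 0.8)  # Beta(a, b) on derived freq
    gt_depth_mean: float = 20.0  # per-genotype sequencing depth for DP/AD fields
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_focal, self.n_sister, self.n_comparison) < 2:
            raise ValueError("each population needs at least 2 individuals")
        for branch, f in self.drift_f.items():
            if not 0.0 < f < 1.0:
                raise ValueError(f"drift_f[{branch!r}]={f} must lie strictly in (0, 1)")
        if any(length <= 0 for length in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")

    @property
    def populations(self) -> dict[str, str]:
        pops = {}
        for i in range(self.n_focal):
            pops[f"focal_{i:02d}"] = "focal"
        for i in range(self.n_sister):
            pops[f"sister_{i:02d}"] = "sister"
        for i in range(self.n_comparison):
            pops[f"comparison_{i:02d}"] = "comparison"
        return pops


@dataclass
class SweepSpec:
    """A locus where the focal population's derived allele is forced high."""

    chrom: str
    center: int
    halfwidth: int
    focal_freq: float = 0.95
    other_freq: float = 0.05

    def __post_init__(self) -> None:
        if not (0 <= self.other_freq <= 1 and 0 <= self.focal_freq <= 1):
            raise ValueError("sweep frequencies must lie in [0, 1]")
        if self.focal_freq <= self.other_freq:
            raise ValueError("focal_freq must exceed other_freq")

    @property
    def start(self) -> int:
        return max(self.center - self.halfwidth, 0)

    @property
    def end(self) -> int:
        return self.center + self.halfwidth


@dataclass
class TruthTable:
    """Ground-truth records for injected signals (0-based half-open intervals)."""

    df: pd.DataFrame  # columns: kind, chrom, start, end, params (dict)
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_records(cls, records: list[tuple[str, str, int, int, dict]], **extras) -> "TruthTable":
        df = pd.DataFrame(records, columns=["kind", "chrom", "start", "end", "params"])
        return cls(df=df, extras=extras)

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.df[self.df["kind"] == kind].reset_index(drop=True)

    def intervals(self, kind: str) -> IntervalSet:
        sub = self.of_kind(kind)
        return IntervalSet.from_records(
            [
                (r.chrom, r.start, r.end, f"{kind}_{i}")
                for i, r in enumerate(sub.itertuples(index=False))
            ],
            kind=kind,
        )

    def write(self, path: str | Path) -> None:
        out = self.df.copy()
        out["params"] = out["params"].map(json.dumps)
        out.to_csv(path, sep="\t", index=False)


def balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    """Draw daughter-population frequencies from the Balding–Nichols kernel.

    Frequencies fixed at 0 or 1 in the parent stay fixed (the Beta parameters
    would degenerate there, and a fixed allele cannot drift).
    """
    scale = (1.0 - f) / f
    out = np.array(p, dtype=float, copy=True)
    seg = (p > 0) & (p < 1)
    out[seg] = rng.beta(p[seg] * scale, (1.0 - p[seg]) * scale)
    return out


def _site_positions(rng: np.random.Generator, spec: CohortSpec) -> tuple[np.ndarray, np.ndarray]:
    """Distinct site positions allocated to chromosomes proportionally to length."""
    chroms = list(spec.chrom_lengths)
    lengths = np.array([spec.chrom_lengths[c] for c in chroms], dtype=float)
    n_per = rng.multinomial(spec.n_sites, lengths / lengths.sum())
    chrom_col, pos_col = [], []
    for chrom, n in zip(chroms, n_per):
        length = spec.chrom_lengths[chrom]
        pos = np.sort(rng.choice(length, size=min(n, length), replace=False))
        chrom_col.append(np.full(len(pos), chrom, dtype=object))
        pos_col.append(pos)
    return np.concatenate(chrom_col), np.concatenate(pos_col)


def simulate_genotypes(
    spec: CohortSpec, sweeps: list[SweepSpec] | None = None
) -> tuple[GenotypeTable, TruthTable]:
    """Simulate diploid genotypes under hierarchical drift with optional sweeps.

    Per site: the ancestral derived-allele frequency is drawn from
    ``Beta(*spec.ancestral_freq_dist)``; the (focal, sister) ancestor drifts
    from it along the ``internal`` branch, then focal and sister drift from
    that ancestor and the comparison population drifts directly from the
    root, each via the Balding–Nichols kernel.  Inside a sweep interval the
    focal frequency is forced to ``focal_freq`` and both other populations
    to ``other_freq``.  Genotypes are binomial draws; sites monomorphic in
    the total sample are dropped (variant callers emit variant sites only).

    An outgroup-species allele column carrying the true ancestral base is
    attached for polarization, and the simulator's derived allele is kept in
    ``sites["derived"]`` for truth checks.
    """
    sweeps = sweeps or []
    for s in sweeps:
        if s.chrom not in spec.chrom_lengths:
            raise ValueError(f"sweep chromosome {s.chrom!r} not in genome")
        if s.end > spec.chrom_lengths[s.chrom]:
            raise ValueError("sweep interval extends beyond chromosome end")
    by_chrom: dict[str, list[SweepSpec]] = {}
    for s in sweeps:
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, group in by_chrom.items():
        group.sort(key=lambda s: s.start)
        for prev, nxt in zip(group, group[1:]):
            if nxt.start < prev.end:
                raise ValueError(f"overlapping sweep intervals on {chrom}")

    rng = np.random.default_rng(spec.seed)
    chrom_arr, pos_arr = _site_positions(rng, spec)
    n = len(pos_arr)

    a, b = spec.ancestral_freq_dist
    p_anc = rng.beta(a, b, size=n)
    p_internal = balding_nichols(rng, p_anc, spec.drift_f["internal"])
    p_focal = balding_nichols(rng, p_internal, spec.drift_f["focal"])
    p_sister = balding_nichols(rng, p_internal, spec.drift_f["sister"])
    p_comp = balding_nichols(rng, p_anc, spec.drift_f["comparison"])

    in_sweep = np.zeros(n, dtype=bool)
    for s in sweeps:
        mask = (chrom_arr == s.chrom) & (pos_arr >= s.start) & (pos_arr < s.end)
        p_focal[mask] = s.focal_freq
        p_sister[mask] = s.other_freq
        p_comp[mask] = s.other_freq
        in_sweep |= mask

    pops = spec.populations
    samples = list(pops)
    freq_of = {"focal": p_focal, "sister": p_sister, "comparison": p_comp}
    dosage_derived = np.empty((n, len(samples)), dtype=np.int8)
    for j, s in enumerate(samples):
        dosage_derived[:, j] = rng.binomial(2, freq_of[pops[s]])

    # allele letters: ancestral base random; derived base distinct; the derived
    # allele lands on REF or ALT with equal probability, as in real polarization
    anc_base_idx = rng.integers(0, 4, size=n)
    derived_offset = rng.integers(1, 4, size=n)
    derived_base_idx = (anc_base_idx + derived_offset) % 4
    derived_is_alt = rng.random(n) < 0.5
    ref = np.where(derived_is_alt, BASES[anc_base_idx], BASES[derived_base_idx])
    alt = np.where(derived_is_alt, BASES[derived_base_idx], BASES[anc_base_idx])
    dosage_alt = np.where(derived_is_alt[:, None], dosage_derived, 2 - dosage_derived).astype(np.int8)

    depth = rng.poisson(spec.gt_depth_mean, size=dosage_alt.shape).astype(np.int32)
    ad_ref = np.where(
        dosage_alt == 0, depth, np.where(dosage_alt == 2, 0, rng.binomial(depth, 0.5))
    ).astype(np.int32)

    keep = ~np.all(dosage_alt == dosage_alt[:, :1], axis=1)
    keep |= in_sweep  # sweep sites stay even if the sample happens to be monomorphic
    sites = pd.DataFrame(
        {
            "chrom": chrom_arr[keep],
            "pos0": pos_arr[keep],
            "ref": ref[keep],
            "alt": alt[keep],
            "derived": np.where(derived_is_alt, alt, ref)[keep],
        }
    )
    table = GenotypeTable(
        sites=sites.reset_index(drop=True),
        dosage=dosage_alt[keep],
        depth=depth[keep],
        ad_ref=ad_ref[keep],
        samples=samples,
        populations=pops,
        outgroup=BASES[anc_base_idx][keep].astype(object),
    )
    truth = TruthTable.from_records(
        [
            (
                "sweep",
                s.chrom,
                s.start,
                s.end,
                {"focal_freq": s.focal_freq, "other_freq": s.other_freq},
            )
            for s in sweeps
        ]
    )
    return table, truth


def simulate_depth_tracks(
    spec: CohortSpec,
    deletions: list[tuple[str, int, int]] | None = None,
    mean_depth_per_genome: float | dict[str, float] = 10.0,
    unmappable: list[tuple[str, int, int]] | None = None,
    n_focal: int | None = None,
    n_comparison: int | None = None,
) -> tuple[DepthTrackSet, TruthTable]:
    """Per-site Poisson depth tracks with engineered fixed deletions.

    ``mean_depth_per_genome`` is either one coverage for every genome or a
    ``{"focal": x, "comparison": y}`` map.  Deletions are carried by every
    focal genome (depth forced to 0); comparison genomes are unaffected.
    ``unmappable`` intervals are recorded in the truth table for mask
    construction but do not alter the simulated depths.
    """
    deletions = deletions or []
    unmappable = unmappable or []
    if isinstance(mean_depth_per_genome, dict):
        cov = dict(mean_depth_per_genome)
    else:
        cov = {"focal": float(mean_depth_per_genome), "comparison": float(mean_depth_per_genome)}
    if min(cov.values()) < 0:
        raise ValueError("coverage must be non-negative")
    for chrom, start, end in list(deletions) + list(unmappable):
        if chrom not in spec.chrom_lengths or start < 0 or end > spec.chrom_lengths[chrom]:
            raise ValueError(f"interval {chrom}:{start}-{end} outside genome")

    n_f = spec.n_focal if n_focal is None else n_focal
    n_c = spec.n_comparison if n_comparison is None else n_comparison
    genomes = [f"focal_{i:02d}" for i in range(n_f)] + [
        f"comparison_{i:02d}" for i in range(n_c)
    ]
    cohorts = {g: ("focal" if g.startswith("focal") else "comparison") for g in genomes}
    mean_depths = {g: cov[cohorts[g]] for g in genomes}

    rng = np.random.default_rng(spec.seed)
    depths: dict[str, np.ndarray] = {}
    for chrom, length in spec.chrom_lengths.items():
        arr = np.empty((len(genomes), length), dtype=np.int16)
        for i, g in enumerate(genomes):
            arr[i] = rng.poisson(mean_depths[g], size=length)
        depths[chrom] = arr
    focal_rows = [i for i, g in enumerate(genomes) if cohorts[g] == "focal"]
    for chrom, start, end in deletions:
        depths[chrom][np.ix_(focal_rows, range(start, end))] = 0

    tracks = DepthTrackSet(depths=depths, genomes=genomes, cohorts=cohorts, mean_depths=mean_depths)
    records = [
        ("deletion", chrom, start, end, {"fixed_in": "focal"})
        for chrom, start, end in deletions
    ] + [("unmappable", chrom, start, end, {}) for chrom, start, end in unmappable]
    return tracks, TruthTable.from_records(records)


def simulate_cnv_matrix(
    spec: CohortSpec,
    n_loci: int,
    outlier_loci: list[tuple[int, dict[str, float], dict[str, float]]] | None = None,
    background_freqs: dict[str, float] | None = None,
    locus_length: tuple[int, int] = (2_000, 20_000),
    locus_intervals: dict[int, tuple[str, int, int]] | None = None,
) -> tuple[CnvMatrix, TruthTable]:
    """Copy-number genotype matrix with population-differentiated outlier loci.

    Each individual draws two allele classes from its population's class
    frequencies over ``{A, CN0, CN2, CNH}``; the diploid copy number is the
    summed per-allele copy contribution (A=1, CN0=0, CN2=2, CNH=3, capped at
    5).  Non-outlier loci share one frequency vector across populations:
    either ``background_freqs`` at every locus, or (default) a rare-skewed
    per-locus spectrum in which the CNV-allele frequency is drawn from
    ``0.5 * Beta(0.3, 8)`` and assigned to CN0 with probability 0.7, else
    CN2 — most segregating copy-number alleles are rare.
    ``outlier_loci`` entries are ``(locus_index, focal_freqs, other_freqs)``
    where ``other_freqs`` applies to both the sister and comparison
    populations (the pooled mainland group).  ``locus_intervals`` pins the
    genomic interval of selected locus indices (e.g. to place an outlier
    CNV over a known gene); all other loci get non-overlapping random
    intervals.  The realized canonical allele-class counts per locus and
    population are recorded in ``truth.extras["allele_draws"]``.
    """
    locus_intervals = locus_intervals or {}
    outlier_loci = outlier_loci or []

    def _check(freqs: dict[str, float], label: str) -> np.ndarray:
        vec = np.array([freqs.get(c, 0.0) for c in CNV_CLASSES], dtype=float)
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError(f"{label} class frequencies must sum to 1 (got {vec.sum()})")
        return vec

    bg_fixed = _check(background_freqs, "background") if background_freqs else None
    outlier_by_idx = {}
    for idx, f_freqs, c_freqs in outlier_loci:
        if not 0 <= idx < n_loci:
            raise ValueError(f"outlier locus index {idx} out of range")
        outlier_by_idx[idx] = (_check(f_freqs, "focal"), _check(c_freqs, "comparison"))

    rng = np.random.default_rng(spec.seed)
    pops = spec.populations
    individuals = list(pops)
    group = np.array([0 if pops[s] == "focal" else 1 for s in individuals])

    # non-overlapping locus intervals spread over the genome
    chroms = list(spec.chrom_lengths)
    loci_rows = []
    per_chrom = int(np.ceil(n_loci / len(chroms)))
    made = 0
    for chrom in chroms:
        length = spec.chrom_lengths[chrom]
        slot = length // per_chrom
        for k in range(per_chrom):
            if made >= n_loci:
                break
            lo = k * slot
            size = int(rng.integers(*locus_length))
            size = min(size, max(slot - 1, 1))
            start = int(lo + rng.integers(0, max(slot - size, 1)))
            if made in locus_intervals:
                pchrom, pstart, pend = locus_intervals[made]
                loci_rows.append((pchrom, int(pstart), int(pend), f"cnv_{made:05d}", "cnv"))
            else:
                loci_rows.append((chrom, start, start + size, f"cnv_{made:05d}", "cnv"))
            made += 1
    loci = IntervalSet(pd.DataFrame(loci_rows, columns=["chrom", "start", "end", "name", "kind"]))
    # loci.df is sorted by coordinates; map locus ids to matrix rows
    id_to_row = {name: i for i, name in enumerate(loci.df["name"])}

    copies = np.array([ALLELE_COPIES[c] for c in CNV_CLASSES])
    cn = np.empty((n_loci, len(individuals)), dtype=np.int64)
    draws_rows = []
    class_order = {c: i for i, c in enumerate(CNV_CLASSES)}
    for locus_id in range(n_loci):
        if locus_id in outlier_by_idx:
            fvec, cvec = outlier_by_idx[locus_id]
        elif bg_fixed is not None:
            fvec = cvec = bg_fixed
        else:
            # rare-skewed background spectrum: most segregating CNV alleles
            # are rare, mirroring a neutral structural-variant SFS; the
            # frequency is shared between populations (no differentiation)
            q = float(rng.beta(0.3, 8.0)) * 0.5
            cnv_cls = "CN0" if rng.random() < 0.7 else "CN2"
            fvec = cvec = np.zeros(len(CNV_CLASSES))
            fvec[class_order["A"]] = 1.0 - q
            fvec[class_order[cnv_cls]] = q
        row = id_to_row[f"cnv_{locus_id:05d}"]
        for g, vec in ((0, fvec), (1, cvec)):
            cols = np.nonzero(group == g)[0]
            alleles = rng.choice(4, size=(len(cols), 2), p=vec)
            k = np.minimum(copies[alleles].sum(axis=1), 5)
            cn[row, cols] = k
        # canonical pair tallies per population (what the matrix can encode)
        for pop_name, g in (("focal", 0), ("comparison", 1)):
            cols = np.nonzero(group == g)[0]
            tally = {c: 0 for c in CNV_CLASSES}
            for k in cn[row, cols]:
                for cls in PAIR_FOR_COPY[int(k)]:
                    tally[cls] += 1
            draws_rows.append({"locus": f"cnv_{locus_id:05d}", "population": pop_name, **tally})

    matrix = CnvMatrix(
        loci=loci,
        copy_number=cn,
        individuals=individuals,
        populations=pops,
    )
    loci_df = loci.df
    records = []
    for idx in sorted(outlier_by_idx):
        row = id_to_row[f"cnv_{idx:05d}"]
        records.append(
            (
                "cnv_outlier",
                loci_df["chrom"].iat[row],
                int(loci_df["start"].iat[row]),
                int(loci_df["end"].iat[row]),
                {"locus": f"cnv_{idx:05d}"},
            )
        )
    truth = TruthTable.from_records(records, allele_draws=pd.DataFrame(draws_rows))
    return matrix, truth


@dataclass
class PlantedVariant:
    """An effect-annotated variant planted at controlled population frequencies."""

    gene: int
    effect_class: str
    focal_freq: float
    comparison_freq: float
    focal_call_rate: float = 1.0
    comparison_call_rate: float = 1.0

    def __post_init__(self) -> None:
        if not (0 <= self.focal_freq <= 1 and 0 <= self.comparison_freq <= 1):
            raise ValueError("planted frequencies must lie in [0, 1]")


def _planted_dosages(
    rng: np.random.Generator, n_ind: int, freq: float, call_rate: float
) -> np.ndarray:
    """Dosage column with an exact derived-allele count at the target frequency.

    ``round(call_rate * n_ind)`` individuals are called; among their
    ``2 * n_called`` chromosomes exactly ``round(freq * 2 * n_called)`` carry
    the derived allele, assigned at random.  Exact counts (rather than
    binomial draws) keep planted loci on the intended side of downstream
    frequency thresholds regardless of sample size.
    """
    n_called = int(round(call_rate * n_ind))
    dos = np.full(n_ind, MISSING, dtype=np.int8)
    called = rng.permutation(n_ind)[:n_called]
    chroms = np.zeros(2 * n_called, dtype=np.int8)
    k = int(round(freq * 2 * n_called))
    chroms[:k] = 1
    rng.shuffle(chroms)
    dos[called] = chroms.reshape(n_called, 2).sum(axis=1)
    return dos


def simulate_annotation(
    spec: CohortSpec,
    n_genes: int,
    derived_variants: list[PlantedVariant] | None = None,
    genotypes: GenotypeTable | None = None,
    n_background_effects: int = 50,
) -> tuple[IntervalSet, pd.DataFrame, TruthTable, GenotypeTable]:
    """Gene/CDS models plus an effect table, with planted coding variants.

    Lays ``n_genes`` non-overlapping genes (each with a single CDS covering
    its middle 60%) across the genome, plants each requested variant at an
    exact derived-allele count inside its gene's CDS, and annotates up to
    ``n_background_effects`` existing background sites with LOW/MODIFIER
    classes so that downstream class filtering has something to discard.
    Planted sites are merged into ``genotypes`` (or a fresh empty table) and
    the merged table is returned.
    """
    derived_variants = derived_variants or []
    rng = np.random.default_rng(spec.seed + 1)

    total_len = sum(spec.chrom_lengths.values())
    gene_len = 6_000
    if n_genes * gene_len * 2 > total_len:
        raise ValueError("more genes than fit in the genome")

    chroms = list(spec.chrom_lengths)
    rows = []
    per_chrom = int(np.ceil(n_genes / len(chroms)))
    made = 0
    for chrom in chroms:
        slot = spec.chrom_lengths[chrom] // per_chrom
        for k in range(per_chrom):
            if made >= n_genes:
                break
            start = k * slot + (slot - gene_len) // 2
            name = f"gene_{made:04d}"
            rows.append((chrom, start, start + gene_len, name, "gene"))
            cds_start = start + int(gene_len * 0.2)
            cds_end = start + int(gene_len * 0.8)
            rows.append((chrom, cds_start, cds_end, name, "CDS"))
            made += 1
    genes = IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "kind"]))
    cds = genes.df[genes.df["kind"] == "CDS"].set_index("name")

    pops = spec.populations
    samples = list(pops)
    if genotypes is None:
        genotypes = GenotypeTable(
            sites=pd.DataFrame(columns=["chrom", "pos0", "ref", "alt", "derived"]),
            dosage=np.empty((0, len(samples)), dtype=np.int8),
            depth=np.empty((0, len(samples)), dtype=np.int32),
            ad_ref=np.empty((0, len(samples)), dtype=np.int32),
            samples=samples,
            populations=pops,
            outgroup=np.empty(0, dtype=object),
        )
    if genotypes.samples != samples:
        raise ValueError("genotype table samples do not match the cohort spec")

    used = set(zip(genotypes.sites["chrom"], genotypes.sites["pos0"]))
    focal_cols = genotypes.sample_indices("focal")
    other_cols = genotypes.sample_indices(["sister", "comparison"])

    effect_rows = []
    new_sites, new_dos, new_depth, new_adref, new_out = [], [], [], [], []
    truth_records = []
    for vi, pv in enumerate(derived_variants):
        gene_name = f"gene_{pv.gene:04d}"
        if gene_name not in cds.index:
            raise ValueError(f"gene index {pv.gene} out of range")
        c = cds.loc[gene_name]
        while True:
            pos0 = int(rng.integers(c["start"], c["end"]))
            if (c["chrom"], pos0) not in used:
                used.add((c["chrom"], pos0))
                break
        dos = np.full(len(samples), MISSING, dtype=np.int8)
        dos[focal_cols] = _planted_dosages(rng, len(focal_cols), pv.focal_freq, pv.focal_call_rate)
        dos[other_cols] = _planted_dosages(
            rng, len(other_cols), pv.comparison_freq, pv.comparison_call_rate
        )
        anc, der = "A", "G"  # planted variants: ancestral=REF, derived=ALT
        new_sites.append((c["chrom"], pos0, anc, der, der))
        new_dos.append(dos)
        dp = rng.poisson(spec.gt_depth_mean, size=len(samples)).astype(np.int32)
        dp[dos == MISSING] = 0
        new_depth.append(dp)
        new_adref.append(
            np.where(dos <= 0, dp, np.where(dos == 2, 0, rng.binomial(dp, 0.5))).astype(np.int32)
        )
        new_out.append(anc)
        effect_rows.append(
            {
                "chrom": c["chrom"],
                "pos0": pos0,
                "ref": anc,
                "alt": der,
                "gene": gene_name,
                "effect_class": pv.effect_class,
            }
        )
        truth_records.append(
            (
                "derived_variant",
                c["chrom"],
                pos0,
                pos0 + 1,
                {
                    "gene": gene_name,
                    "effect_class": pv.effect_class,
                    "focal_freq": pv.focal_freq,
                    "comparison_freq": pv.comparison_freq,
                    "focal_call_rate": pv.focal_call_rate,
                    "comparison_call_rate": pv.comparison_call_rate,
                },
            )
        )

    # LOW/MODIFIER decoration of background sites (dropped by class filtering)
    n_bg = min(n_background_effects, genotypes.n_sites)
    if n_bg:
        bg_idx = rng.choice(genotypes.n_sites, size=n_bg, replace=False)
        gene_names = list(cds.index)
        for i in bg_idx:
            effect_rows.append(
                {
                    "chrom": genotypes.sites["chrom"].iat[i],
                    "pos0": int(genotypes.sites["pos0"].iat[i]),
                    "ref": genotypes.sites["ref"].iat[i],
                    "alt": genotypes.sites["alt"].iat[i],
                    "gene": gene_names[int(rng.integers(len(gene_names)))],
                    "effect_class": ["LOW", "MODIFIER"][int(rng.integers(2))],
                }
            )

    if new_sites:
        add_sites = pd.DataFrame(
            new_sites, columns=["chrom", "pos0", "ref", "alt", "derived"]
        )
        sites = pd.concat([genotypes.sites, add_sites], ignore_index=True)
        dosage = np.vstack([genotypes.dosage, np.array(new_dos, dtype=np.int8)])
        depth = np.vstack([genotypes.depth, np.array(new_depth, dtype=np.int32)])
        ad_ref = np.vstack([genotypes.ad_ref, np.array(new_adref, dtype=np.int32)])
        outgroup = (
            np.concatenate([genotypes.outgroup, np.array(new_out, dtype=object)])
            if genotypes.outgroup is not None
            else None
        )
        order = np.lexsort((sites["pos0"].to_numpy(), sites["chrom"].to_numpy()))
        merged = GenotypeTable(
            sites=sites.iloc[order].reset_index(drop=True),
            dosage=dosage[order],
            depth=depth[order],
            ad_ref=ad_ref[order],
            samples=samples,
            populations=pops,
            outgroup=None if outgroup is None else outgroup[order],
        )
    else:
        merged = genotypes

    effects = pd.DataFrame(
        effect_rows, columns=["chrom", "pos0", "ref", "alt", "gene", "effect_class"]
    )
    truth = TruthTable.from_records(truth_records)
    return genes, effects, truth, merged
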