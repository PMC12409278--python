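"""Readers, writers and in-memory containers for the pipeline's data formats.

All internal coordinates are 0-based half-open.  Conversion to the 1-based
conventions of VCF and GFF3 happens only at the file boundary, so interval
arithmetic inside the package never mixes conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # dosage / copy-number sentinel for uncalled genotypes

INTERVAL_COLUMNS = ["chrom", "start", "end", "name", "kind"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTable:
    """Per-site diploid genotypes for a cohort, with population labels.

    Attributes
    ----------
    sites:
        DataFrame with columns ``chrom, pos0, ref, alt`` sorted by
        ``(chrom, pos0)``; ``pos0`` is 0-based.
    dosage:
        ``(n_sites, n_samples)`` int8 array of alt-allele dosages in
        ``{0, 1, 2}`` with :data:`MISSING` for uncalled genotypes.
    depth:
        per-genotype read depth (DP), same shape; 0 where missing.
    ad_ref:
        per-genotype reference-allele read count (first AD field).
    samples:
        ordered sample identifiers (column order of the matrices).
    populations:
        map sample id -> population name; every sample must be present.
    outgroup:
        optional per-site allele carried by the outgroup-species consensus
        (``""`` where unavailable), used for polarization.
    """

    sites: pd.DataFrame
    dosage: np.ndarray
    depth: np.ndarray
    ad_ref: np.ndarray
    samples: list[str]
    populations: dict[str, str]
    outgroup: np.ndarray | None = None

    def __post_init__(self) -> None:
        missing_pop = [s for s in self.samples if s not in self.populations]
        if missing_pop:
            raise ValueError(f"samples without a population label: {missing_pop}")
        if self.dosage.shape != (len(self.sites), len(self.samples)):
            raise ValueError("dosage matrix shape does not match sites × samples")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, population: str | list[str]) -> np.ndarray:
        """Column indices of all samples belonging to ``population`` (or any of a list)."""
        pops = {population} if isinstance(population, str) else set(population)
        return np.array(
            [i for i, s in enumerate(self.samples) if self.populations[s] in pops],
            dtype=np.intp,
        )

    def take_sites(self, index: np.ndarray) -> "GenotypeTable":
        """New table restricted to the given site rows (order preserved)."""
        return GenotypeTable(
            sites=self.sites.iloc[index].reset_index(drop=True),
            dosage=self.dosage[index],
            depth=self.depth[index],
            ad_ref=self.ad_ref[index],
            samples=list(self.samples),
            populations=dict(self.populations),
            outgroup=None if self.outgroup is None else self.outgroup[index],
        )

    def allele_counts(self, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Alt-allele count and called chromosome count per site over ``cols``.

        Returns ``(alt_count, n_called_chromosomes)``, both length ``n_sites``.
        """
        sub = self.dosage[:, cols]
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=1)
        n = 2 * called.sum(axis=1)
        return alt.astype(np.int64), n.astype(np.int64)


@dataclass
class IntervalSet:
    """A sorted collection of genomic intervals (0-based half-open)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.df.columns) != INTERVAL_COLUMNS:
            self.df = self.df.reindex(columns=INTERVAL_COLUMNS)
        if (self.df["end"] <= self.df["start"]).any():
            raise ValueError("intervals must satisfy start < end")
        self.df = (
            self.df.sort_values(["chrom", "start", "end"], kind="mergesort")
            .reset_index(drop=True)
        )

    @classmethod
    def from_records(cls, records, kind: str = "") -> "IntervalSet":
        """Build from an iterable of (chrom, start, end[, name[, kind]]) tuples."""
        rows = []
        for rec in records:
            rec = tuple(rec)
            chrom, start, end = rec[:3]
            name = rec[3] if len(rec) > 3 else ""
            k = rec[4] if len(rec) > 4 else kind
            rows.append((chrom, int(start), int(end), name, k))
        df = pd.DataFrame(rows, columns=INTERVAL_COLUMNS)
        return cls(df)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        return iter(self.df.itertuples(index=False))


@dataclass
class DepthTrackSet:
    """Per-genome per-site sequencing depth over a contiguous coordinate grid.

    ``depths[chrom]`` is a ``(n_genomes, chrom_length)`` integer array; rows
    follow ``genomes``.  ``cohorts`` maps each genome to ``focal`` or
    ``comparison``; ``mean_depths`` records the nominal per-genome coverage.
    """

    depths: dict[str, np.ndarray]
    genomes: list[str]
    cohorts: dict[str, str]
    mean_depths: dict[str, float]

    def __post_init__(self) -> None:
        for chrom, arr in self.depths.items():
            if arr.shape[0] != len(self.genomes):
                raise ValueError(f"depth grid for {chrom} does not match genome list")
            if (arr < 0).any():
                raise ValueError("negative depth")

    def cohort_rows(self, cohort: str) -> np.ndarray:
        return np.array(
            [i for i, g in enumerate(self.genomes) if self.cohorts[g] == cohort],
            dtype=np.intp,
        )

    def expected_cohort_depth(self, cohort: str) -> float:
        """Nominal summed coverage for a cohort (sum of per-genome means)."""
        return float(
            sum(self.mean_depths[g] for g in self.genomes if self.cohorts[g] == cohort)
        )


@dataclass
class CnvMatrix:
    """Copy-number genotypes: loci × individuals integer matrix."""

    loci: IntervalSet
    copy_number: np.ndarray
    individuals: list[str]
    populations: dict[str, str]

    def __post_init__(self) -> None:
        if self.copy_number.shape != (len(self.loci), len(self.individuals)):
            raise ValueError("copy_number shape does not match loci × individuals")
        if (self.copy_number < 0).any():
            raise ValueError("negative copy number")

    def individual_indices(self, population: str | list[str]) -> np.ndarray:
        pops = {population} if isinstance(population, str) else set(population)
        return np.array(
            [i for i, s in enumerate(self.individuals) if self.populations[s] in pops],
            dtype=np.intp,
        )


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------


def read_manifest(path: str | Path) -> dict[str, str]:
    """Read a two-column sample→population TSV (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
    return dict(zip(df["sample"], df["population"]))


def write_manifest(populations: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sample, pop in populations.items():
            fh.write(f"{sample}\t{pop}\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=arctic-sweep
##INFO=<ID=AA,Number=1,Type=String,Description="Outgroup-species (ancestral) allele">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">
"""


def read_vcf(path: str | Path, manifest: dict[str, str] | str | Path) -> GenotypeTable:
    """Load bi-allelic SNP records from a sorted VCF into a :class:`GenotypeTable`.

    Multi-allelic, indel and symbolic records are skipped with a logged count.
    1-based POS becomes 0-based ``pos0``.  The ``AA`` INFO tag, when present,
    populates the outgroup allele column.

    Raises ``ValueError`` for samples missing from the manifest or for an
    unsorted VCF.
    """
    from cyvcf2 import VCF

    if not isinstance(manifest, dict):
        manifest = read_manifest(manifest)

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in manifest]
    if absent:
        raise ValueError(f"VCF samples absent from manifest: {absent}")

    rows, dosages, depths, ad_refs, outgroup = [], [], [], [], []
    n_skipped = 0
    last: tuple[str, int] | None = None
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        key = (var.CHROM, var.POS)
        if last is not None and key[0] == last[0] and key[1] < last[1]:
            raise ValueError(f"VCF not sorted at {var.CHROM}:{var.POS}")
        last = key
        rows.append((var.CHROM, var.POS - 1, var.REF, var.ALT[0]))
        gts = var.genotype.array()[:, :2]
        dos = np.where((gts < 0).any(axis=1), MISSING, gts.clip(min=0).sum(axis=1))
        dosages.append(dos.astype(np.int8))
        try:
            dp = var.format("DP")
        except KeyError:
            dp = None
        depths.append(
            np.zeros(len(samples), dtype=np.int32)
            if dp is None
            else dp[:, 0].clip(min=0).astype(np.int32)
        )
        try:
            ad = var.format("AD")
        except KeyError:
            ad = None
        ad_refs.append(
            np.zeros(len(samples), dtype=np.int32)
            if ad is None
            else ad[:, 0].clip(min=0).astype(np.int32)
        )
        aa = var.INFO.get("AA")
        outgroup.append(aa if aa else "")
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)

    sites = pd.DataFrame(rows, columns=["chrom", "pos0", "ref", "alt"])
    n = len(sites)
    table = GenotypeTable(
        sites=sites,
        dosage=np.vstack(dosages) if n else np.empty((0, len(samples)), dtype=np.int8),
        depth=np.vstack(depths) if n else np.empty((0, len(samples)), dtype=np.int32),
        ad_ref=np.vstack(ad_refs) if n else np.empty((0, len(samples)), dtype=np.int32),
        samples=samples,
        populations={s: manifest[s] for s in samples},
        outgroup=np.array(outgroup, dtype=object) if any(outgroup) else None,
    )
    table.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return table


def write_vcf(table: GenotypeTable, path: str | Path, chrom_lengths: dict[str, int] | None = None) -> None:
    """Write a :class:`GenotypeTable` as VCF 4.2 with GT:DP:AD genotypes."""
    gt_strings = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        if chrom_lengths:
            for chrom, length in chrom_lengths.items():
                fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(table.samples) + "\n")
        sites = table.sites
        for i in range(table.n_sites):
            chrom, pos0, ref, alt = (
                sites["chrom"].iat[i],
                sites["pos0"].iat[i],
                sites["ref"].iat[i],
                sites["alt"].iat[i],
            )
            info = "."
            if table.outgroup is not None and table.outgroup[i]:
                info = f"AA={table.outgroup[i]}"
            fields = []
            for j in range(table.n_samples):
                dos = int(table.dosage[i, j])
                dp = int(table.depth[i, j])
                ad_ref = int(table.ad_ref[i, j])
                fields.append(f"{gt_strings[dos]}:{dp}:{ad_ref},{max(dp - ad_ref, 0)}")
            fh.write(
                f"{chrom}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\tGT:DP:AD\t"
                + "\t".join(fields)
                + "\n"
            )


# ---------------------------------------------------------------------------
# BED / GFF3
# ---------------------------------------------------------------------------


def read_bed(path: str | Path, kind: str = "") -> IntervalSet:
    """Read BED3/BED6 (0-based half-open; name column optional)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3] if len(parts) > 3 else ""
            rows.append((parts[0], int(parts[1]), int(parts[2]), name, kind))
    return IntervalSet(pd.DataFrame(rows, columns=INTERVAL_COLUMNS))


def write_bed(intervals: IntervalSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def read_gff3(path: str | Path, feature_types: tuple[str, ...] = ("gene", "CDS")) -> IntervalSet:
    """Read gene/CDS features from GFF3 (1-based closed -> 0-based half-open).

    The feature name is taken from the ``ID`` or ``Parent`` attribute; the
    interval ``kind`` is the lower-cased feature type (``gene`` or ``CDS``
    kept as is).
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] not in feature_types:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            name = attrs.get("ID") or attrs.get("Parent") or ""
            rows.append((parts[0], int(parts[3]) - 1, int(parts[4]), name, parts[2]))
    return IntervalSet(pd.DataFrame(rows, columns=INTERVAL_COLUMNS))


def write_gff3(intervals: IntervalSet, path: str | Path) -> None:
    """Write gene/CDS intervals as GFF3 (converting to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            attr = f"ID={iv.name}" if iv.kind == "gene" else f"Parent={iv.name}"
            fh.write(
                f"{iv.chrom}\tarctic-sweep\t{iv.kind}\t{iv.start + 1}\t{iv.end}\t.\t+\t.\t{attr}\n"
            )


# ---------------------------------------------------------------------------
# depth tracks / CNV matrix / effect tables
# ---------------------------------------------------------------------------


def write_depth_tracks(tracks: DepthTrackSet, outdir: str | Path) -> None:
    """One samtools-depth-style TSV per genome: chrom, 1-based pos, depth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, genome in enumerate(tracks.genomes):
        frames = [
            pd.DataFrame(
                {"chrom": chrom, "pos": np.arange(1, arr.shape[1] + 1), "depth": arr[i]}
            )
            for chrom, arr in tracks.depths.items()
        ]
        pd.concat(frames).to_csv(
            outdir / f"{genome}.depth.tsv", sep="\t", header=False, index=False
        )


def read_depth_tracks(
    indir: str | Path,
    cohorts: dict[str, str],
    chrom_lengths: dict[str, int],
    mean_depths: dict[str, float] | None = None,
) -> DepthTrackSet:
    """Read per-genome depth TSVs (``<genome>.depth.tsv``) from a directory."""
    indir = Path(indir)
    genomes = list(cohorts)  # manifest order
    depths = {
        chrom: np.zeros((len(genomes), length), dtype=np.int32)
        for chrom, length in chrom_lengths.items()
    }
    for i, genome in enumerate(genomes):
        df = pd.read_csv(
            indir / f"{genome}.depth.tsv",
            sep="\t",
            header=None,
            names=["chrom", "pos", "depth"],
        )
        for chrom, sub in df.groupby("chrom", sort=False):
            depths[chrom][i, sub["pos"].to_numpy() - 1] = sub["depth"].to_numpy()
    if mean_depths is None:
        mean_depths = {
            g: float(np.mean([depths[c][i].mean() for c in depths]))
            for i, g in enumerate(genomes)
        }
    return DepthTrackSet(depths=depths, genomes=genomes, cohorts=cohorts, mean_depths=mean_depths)


def write_cnv_matrix(matrix: CnvMatrix, path: str | Path) -> None:
    df = matrix.loci.df[["name", "chrom", "start", "end"]].copy()
    df.columns = ["locus", "chrom", "start", "end"]
    for j, ind in enumerate(matrix.individuals):
        df[ind] = matrix.copy_number[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_cnv_matrix(path: str | Path, manifest: dict[str, str]) -> CnvMatrix:
    df = pd.read_csv(path, sep="\t")
    individuals = [c for c in df.columns if c not in ("locus", "chrom", "start", "end")]
    loci = IntervalSet.from_records(
        zip(df["chrom"], df["start"], df["end"], df["locus"]), kind="cnv"
    )
    # loci are re-sorted by IntervalSet; realign the matrix rows
    order = (
        df.assign(_row=np.arange(len(df)))
        .sort_values(["chrom", "start", "end"], kind="mergesort")["_row"]
        .to_numpy()
    )
    cn = df[individuals].to_numpy(dtype=np.int64)[order]
    return CnvMatrix(
        loci=loci,
        copy_number=cn,
        individuals=individuals,
        populations={s: manifest[s] for s in individuals},
    )


def read_effect_table(path: str | Path) -> pd.DataFrame:
    """Effect-annotation TSV: chrom, pos (1-based), ref, alt, gene, effect_class."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["pos0"] = df["pos"].astype(int) - 1
    return df[["chrom", "pos0", "ref", "alt", "gene", "effect_class"]]


def write_effect_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["pos"] = out["pos0"] + 1
    out[["chrom", "pos", "ref", "alt", "gene", "effect_class"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# interval operations
# ---------------------------------------------------------------------------


def intersect(a: IntervalSet, b: IntervalSet) -> list[tuple[int, int]]:
    """All pairs of overlapping intervals between two sets.

    Overlap is half-open: ``[s1, e1)`` overlaps ``[s2, e2)`` iff
    ``s1 < e2 and s2 < e1``.  Returns (row index in a, row index in b) pairs,
    sorted.
    """
    pairs: list[tuple[int, int]] = []
    bdf = b.df
    for chrom, agrp in a.df.groupby("chrom", sort=False):
        bgrp = bdf[bdf["chrom"] == chrom]
        if bgrp.empty:
            continue
        b_start = bgrp["start"].to_numpy()
        b_end = bgrp["end"].to_numpy()
        b_idx = bgrp.index.to_numpy()
        # b is sorted by start; prune candidates by start < a.end, then test ends
        for ai, a_start, a_end in zip(
            agrp.index.to_numpy(), agrp["start"].to_numpy(), agrp["end"].to_numpy()
        ):
            hi = np.searchsorted(b_start, a_end, side="left")
            cand = np.nonzero(b_end[:hi] > a_start)[0]
            pairs.extend((int(ai), int(b_idx[c])) for c in cand)
    return sorted(pairs)


def merge_intervals(s: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Union intervals whose gap on the same chromosome is <= ``max_gap``.

    Follows BEDTools ``merge -d`` semantics: touching or overlapping
    intervals always merge; disjoint intervals merge when the gap between
    them is at most ``max_gap`` base pairs.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be non-negative")
    rows = []
    for chrom, grp in s.df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        names = grp["name"].to_numpy()
        cur_start, cur_end = int(starts[0]), int(ends[0])
        cur_names = [names[0]] if names[0] else []
        for st, en, nm in zip(starts[1:], ends[1:], names[1:]):
            if st - cur_end <= max_gap:
                cur_end = max(cur_end, int(en))
                if nm:
                    cur_names.append(nm)
            else:
                rows.append((chrom, cur_start, cur_end, ",".join(cur_names), "merged"))
                cur_start, cur_end = int(st), int(en)
                cur_names = [nm] if nm else []
        rows.append((chrom, cur_start, cur_end, ",".join(cur_names), "merged"))
    return IntervalSet(pd.DataFrame(rows, columns=INTERVAL_COLUMNS))
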