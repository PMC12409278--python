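"""Depth-based discovery of large deletions fixed in the focal cohort.

A deletion fixed in the focal population shows zero summed read depth
across every focal genome while the comparison cohort retains normal
coverage.  Summing per-genome depths sharpens the contrast between deleted
and flanking sequence roughly by the cohort size.  Regions where short
reads cannot map uniquely would mimic deletions in both cohorts, so a
k-mer uniqueness mask is built first and masked sites never contribute
evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arctic_sweep.io import DepthTrackSet, IntervalSet, intersect, merge_intervals

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MappabilityMask:
    """Unmappable intervals per chromosome (0-based half-open, merged)."""

    intervals: IntervalSet
    kmer_length: int = 50
    depth_threshold: int = 25
    merge_gap: int = 250

    def site_mask(self, chrom: str, length: int) -> np.ndarray:
        """Boolean array: True at unmappable sites."""
        mask = np.zeros(length, dtype=bool)
        sub = self.intervals.df[self.intervals.df["chrom"] == chrom]
        for start, end in zip(sub["start"], sub["end"]):
            mask[start:end] = True
        return mask


def build_mappability(
    reference: dict[str, str],
    kmer_length: int = 50,
    depth_threshold: int = 25,
    merge_gap: int = 250,
) -> MappabilityMask:
    """Mappability mask from k-mer uniqueness of the reference.

    Every overlapping ``kmer_length``-mer (step 1) of the reference is
    counted over both strands; a k-mer "maps uniquely" when it occurs
    exactly once.  The per-site mappability depth is the number of unique
    k-mers among the (up to ``kmer_length``) windows covering the site;
    sites with depth below ``depth_threshold`` are unmappable, and
    unmappable runs within ``merge_gap`` bp of each other are merged.

    Contigs shorter than ``kmer_length`` are wholly unmappable.
    """
    k = kmer_length
    counts: dict[str, int] = {}
    for seq in reference.values():
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            counts[kmer] = counts.get(kmer, 0) + 1
            rc = _revcomp(kmer)
            if rc != kmer:
                counts[rc] = counts.get(rc, 0) + 1

    rows = []
    for chrom, seq in reference.items():
        seq = seq.upper()
        length = len(seq)
        if length < k:
            rows.append((chrom, 0, length, "", "unmappable"))
            continue
        n_windows = length - k + 1
        unique = np.zeros(n_windows, dtype=np.int32)
        for i in range(n_windows):
            if counts[seq[i : i + k]] == 1:
                unique[i] = 1
        # depth[site] = sum of unique[j] over windows j covering the site
        csum = np.concatenate([[0], np.cumsum(unique)])
        pos = np.arange(length)
        lo = np.maximum(pos - k + 1, 0)
        hi = np.minimum(pos + 1, n_windows)
        depth = csum[hi] - csum[lo]
        unmappable = depth < depth_threshold
        # runs of unmappable sites -> intervals
        boundaries = np.flatnonzero(np.diff(unmappable.astype(np.int8)))
        starts = [0] if unmappable[0] else []
        starts += [int(b) + 1 for b in boundaries if not unmappable[b]]
        ends = [int(b) + 1 for b in boundaries if unmappable[b]]
        if unmappable[-1]:
            ends.append(length)
        for s, e in zip(starts, ends):
            rows.append((chrom, s, e, "", "unmappable"))
    raw = IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "kind"]))
    merged = merge_intervals(raw, max_gap=merge_gap) if len(raw) else raw
    merged.df["kind"] = "unmappable"
    return MappabilityMask(
        intervals=merged,
        kmer_length=k,
        depth_threshold=depth_threshold,
        merge_gap=merge_gap,
    )


def mask_from_intervals(unmappable: IntervalSet, merge_gap: int = 250) -> MappabilityMask:
    """Mask from a precomputed uniqueness/unmappability track."""
    merged = merge_intervals(unmappable, max_gap=merge_gap) if len(unmappable) else unmappable
    merged.df["kind"] = "unmappable"
    return MappabilityMask(intervals=merged, merge_gap=merge_gap)


def sum_depth(
    tracks: DepthTrackSet, mask: MappabilityMask | None = None
) -> dict[str, dict[str, np.ndarray]]:
    """Per-site summed depth for the focal and comparison cohorts.

    Returns ``{chrom: {"focal": sums, "comparison": sums, "masked": bool}}``.
    Masked sites keep their sums but are flagged; downstream statistics
    exclude them.
    """
    focal_rows = tracks.cohort_rows("focal")
    comp_rows = tracks.cohort_rows("comparison")
    out: dict[str, dict[str, np.ndarray]] = {}
    for chrom, arr in tracks.depths.items():
        length = arr.shape[1]
        out[chrom] = {
            "focal": arr[focal_rows].sum(axis=0, dtype=np.int64),
            "comparison": arr[comp_rows].sum(axis=0, dtype=np.int64),
            "masked": mask.site_mask(chrom, length)
            if mask is not None
            else np.zeros(length, dtype=bool),
        }
    return out


@dataclass
class DeletionCall:
    chrom: str
    start: int
    end: int
    focal_mean: float
    comparison_mean: float
    merged_from: list[tuple[int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def call_deletions(
    sums: dict[str, dict[str, np.ndarray]],
    expected_focal: float,
    expected_comparison: float,
    window: int = 100,
    min_comparison_frac: float = 0.5,
    merge_gap: int = 250,
    low_frac: float = 0.05,
    min_length: int = 500,
    min_unmasked_frac: float = 0.5,
    autosomes: list[str] | None = None,
) -> list[DeletionCall]:
    """Call deletions fixed in the focal cohort from cohort depth sums.

    Non-overlapping candidate windows (default 100 bp) qualify when the
    focal summed depth is exactly zero at every unmasked site and the
    comparison mean over unmasked sites is at least ``min_comparison_frac``
    times the expected comparison sum.  Windows with fewer than
    ``min_unmasked_frac`` of their sites unmasked are skipped and do not
    break a candidate run, so deletions interrupted by masked sequence
    merge across it.  Adjacent candidates merge; separate sub-deletions
    within ``merge_gap`` bp merge when the intervening region's focal mean
    is below ``low_frac * expected_focal`` (tolerating stray misaligned
    reads inside a true deletion).  Calls shorter than ``min_length`` are
    discarded.  ``autosomes`` restricts the scan to the listed chromosomes.
    """
    if expected_focal <= 0:
        raise ValueError("expected_focal must be positive")
    calls: list[DeletionCall] = []
    chroms = autosomes if autosomes is not None else list(sums)
    for chrom in chroms:
        tr = sums[chrom]
        focal, comp, masked = tr["focal"], tr["comparison"], tr["masked"]
        length = len(focal)
        # classify candidate windows: 1=candidate, 0=non-candidate, -1=skipped (masked)
        n_win = (length + window - 1) // window
        state = np.zeros(n_win, dtype=np.int8)
        for wi in range(n_win):
            lo, hi = wi * window, min((wi + 1) * window, length)
            um = ~masked[lo:hi]
            if um.mean() < min_unmasked_frac:
                state[wi] = -1
                continue
            if focal[lo:hi][um].max(initial=0) == 0 and comp[lo:hi][um].mean() >= (
                min_comparison_frac * expected_comparison
            ):
                state[wi] = 1

        # runs of candidate windows; skipped (masked) windows do not break a run
        runs: list[tuple[int, int]] = []  # bp intervals
        run_start = None
        last_candidate_end = None
        for wi in range(n_win):
            if state[wi] == 1:
                if run_start is None:
                    run_start = wi * window
                last_candidate_end = min((wi + 1) * window, length)
            elif state[wi] == 0 and run_start is not None:
                runs.append((run_start, last_candidate_end))
                run_start = None
        if run_start is not None:
            runs.append((run_start, last_candidate_end))

        # merge runs over short, low-coverage gaps
        merged: list[DeletionCall] = []
        for start, end in runs:
            if merged:
                prev = merged[-1]
                gap_lo, gap_hi = prev.end, start
                gap_focal = focal[gap_lo:gap_hi]
                gap_um = ~masked[gap_lo:gap_hi]
                gap_mean = float(gap_focal[gap_um].mean()) if gap_um.any() else 0.0
                if gap_hi - gap_lo <= merge_gap and gap_mean < low_frac * expected_focal:
                    prev.merged_from.append((start, end))
                    prev.end = end
                    continue
            merged.append(DeletionCall(chrom, start, end, 0.0, 0.0, merged_from=[(start, end)]))

        for call in merged:
            if call.length < min_length:
                continue
            um = ~masked[call.start : call.end]
            call.focal_mean = float(focal[call.start : call.end][um].mean()) if um.any() else 0.0
            call.comparison_mean = (
                float(comp[call.start : call.end][um].mean()) if um.any() else 0.0
            )
            calls.append(call)
    return calls


def deletion_calls_to_intervals(calls: list[DeletionCall]) -> IntervalSet:
    if not calls:
        return IntervalSet(pd.DataFrame(columns=["chrom", "start", "end", "name", "kind"]))
    return IntervalSet.from_records(
        [(c.chrom, c.start, c.end, f"del_{i}") for i, c in enumerate(calls)],
        kind="deletion",
    )


def deletion_gene_overlap(calls: list[DeletionCall], genes: IntervalSet) -> pd.DataFrame:
    """Half-open intersection of deletion calls with CDS intervals."""
    dels = deletion_calls_to_intervals(calls)
    if len(dels) == 0 or len(genes) == 0:
        return pd.DataFrame(columns=["deletion", "gene", "chrom", "start", "end"])
    rows = []
    for di, gi in intersect(dels, genes):
        rows.append(
            {
                "deletion": dels.df["name"].iat[di],
                "gene": genes.df["name"].iat[gi],
                "chrom": genes.df["chrom"].iat[gi],
                "start": int(genes.df["start"].iat[gi]),
                "end": int(genes.df["end"].iat[gi]),
            }
        )
    return (
        pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)
        if rows
        else pd.DataFrame(columns=["deletion", "gene", "chrom", "start", "end"])
    )
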