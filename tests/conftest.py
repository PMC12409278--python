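import numpy as np
import pandas as pd
import pytest

from arctic_sweep import sim
from arctic_sweep.io import GenotypeTable, IntervalSet


@pytest.fixture(scope="session")
def small_spec():
    return sim.CohortSpec(
        n_focal=8,
        n_sister=6,
        n_comparison=6,
        chrom_lengths={"chr1": 400_000, "chr2": 300_000},
        n_sites=4_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def sweep_cohort():
    """A cohort with one strong sweep, shared across read-only tests."""
    spec = sim.CohortSpec(
        chrom_lengths={"chr1": 2_000_000},
        n_sites=20_000,
        seed=5,
    )
    sweeps = [sim.SweepSpec("chr1", 1_000_000, 25_000)]
    table, truth = sim.simulate_genotypes(spec, sweeps)
    return spec, sweeps, table, truth


def make_table(dosage, chrom="chr1", populations=None, depth=None, ad_ref=None, outgroup=None):
    """Small GenotypeTable from a dense dosage matrix (sites x samples)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = dosage.shape
    samples = [f"s{i}" for i in range(n_samples)]
    populations = populations or {s: "focal" for s in samples}
    sites = pd.DataFrame(
        {
            "chrom": [chrom] * n_sites,
            "pos0": np.arange(n_sites) * 100,
            "ref": ["A"] * n_sites,
            "alt": ["G"] * n_sites,
        }
    )
    return GenotypeTable(
        sites=sites,
        dosage=dosage,
        depth=np.full(dosage.shape, 20, dtype=np.int32) if depth is None else np.asarray(depth, dtype=np.int32),
        ad_ref=np.zeros(dosage.shape, dtype=np.int32) if ad_ref is None else np.asarray(ad_ref, dtype=np.int32),
        samples=samples,
        populations={s: populations[s] for s in samples},
        outgroup=outgroup,
    )


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=500):
    rows = []
    for i in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, max_pos))
        end = start + 1 + int(rng.integers(max_len))
        rows.append((chrom, start, end, f"iv{i}"))
    return IntervalSet.from_records(rows, kind="test")
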