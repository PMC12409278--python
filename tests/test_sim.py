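"""Calibration and determinism checks for the synthetic cohort generator."""

import numpy as np
import pytest
from scipy import stats

from arctic_sweep import sim
from arctic_sweep.io import MISSING, write_vcf


def hudson_ratio_of_sums(k1, n1, k2, n2):
    """Independent genome-wide Hudson F_ST from allele counts (oracle helper)."""
    p1, p2 = k1 / n1, k2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    keep = den > 0
    return num[keep].sum() / den[keep].sum()


class TestSimulateGenotypes:
    def test_same_seed_gives_byte_identical_vcf(self, tmp_path, small_spec):
        paths = []
        for name in ("a.vcf", "b.vcf"):
            table, _ = sim.simulate_genotypes(small_spec)
            write_vcf(table, tmp_path / name, small_spec.chrom_lengths)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_no_drift_limit_keeps_populations_identical(self):
        spec = sim.CohortSpec(
            n_focal=30,
            n_sister=30,
            n_comparison=30,
            chrom_lengths={"chr1": 1_000_000},
            n_sites=5_000,
            drift_f={"internal": 1e-6, "focal": 1e-6, "sister": 1e-6, "comparison": 1e-6},
            seed=2,
        )
        table, _ = sim.simulate_genotypes(spec)
        freqs = {}
        for pop in ("focal", "sister", "comparison"):
            k, n = table.allele_counts(table.sample_indices(pop))
            freqs[pop] = k / n
        # without drift the three populations sample the same ancestral
        # frequency; differences are pure binomial noise around zero
        for a, b in (("focal", "sister"), ("focal", "comparison")):
            assert abs(np.mean(freqs[a] - freqs[b])) < 0.01
        fst = hudson_ratio_of_sums(
            *table.allele_counts(table.sample_indices("focal")),
            *table.allele_counts(table.sample_indices("comparison")),
        )
        assert abs(fst) < 0.01

    def test_degenerate_drift_rejected(self):
        with pytest.raises(ValueError, match="drift_f"):
            sim.CohortSpec(drift_f={"internal": 0.0, "focal": 0.1, "sister": 0.1, "comparison": 0.1})

    def test_overlapping_sweeps_rejected(self, small_spec):
        sweeps = [
            sim.SweepSpec("chr1", 100_000, 30_000),
            sim.SweepSpec("chr1", 140_000, 30_000),
        ]
        with pytest.raises(ValueError, match="overlapping sweep"):
            sim.simulate_genotypes(small_spec, sweeps)

    def test_genomewide_fst_matches_monte_carlo_oracle(self):
        """Realized F_ST agrees with a direct simulation of the drift kernel.

        The oracle re-simulates the same Balding–Nichols hierarchy at one
        million replicate sites with independent code and applies the same
        ascertainment (polymorphic in the pooled sample).
        """
        drift = {"internal": 0.02, "focal": 0.1, "sister": 0.02, "comparison": 0.02}
        spec = sim.CohortSpec(
            chrom_lengths={"chr1": 10_000_000},
            n_sites=20_000,
            drift_f=drift,
            seed=7,
        )
        table, _ = sim.simulate_genotypes(spec)
        k_f, n_f = table.allele_counts(table.sample_indices("focal"))
        k_c, n_c = table.allele_counts(table.sample_indices("comparison"))
        observed = hudson_ratio_of_sums(k_f, n_f, k_c, n_c)

        rng = np.random.default_rng(123456)
        m = 1_000_000
        a, b = spec.ancestral_freq_dist

        def bn(p, f):
            scale = (1 - f) / f
            out = p.copy()
            seg = (p > 0) & (p < 1)
            out[seg] = rng.beta(p[seg] * scale, (1 - p[seg]) * scale)
            return out

        p0 = rng.beta(a, b, size=m)
        p_int = bn(p0, drift["internal"])
        pf = bn(p_int, drift["focal"])
        pc = bn(p0, drift["comparison"])
        ps = bn(p_int, drift["sister"])
        kf = rng.binomial(2 * spec.n_focal, pf)
        kc = rng.binomial(2 * spec.n_comparison, pc)
        ks = rng.binomial(2 * spec.n_sister, ps)
        total = kf + kc + ks
        poly = (total > 0) & (total < 2 * (spec.n_focal + spec.n_comparison + spec.n_sister))
        expected = hudson_ratio_of_sums(
            kf[poly].astype(float),
            np.full(poly.sum(), 2 * spec.n_focal, dtype=float),
            kc[poly].astype(float),
            np.full(poly.sum(), 2 * spec.n_comparison, dtype=float),
        )
        assert observed == pytest.approx(expected, abs=0.03)

    def test_drift_monotonicity_in_focal_branch(self):
        """Stronger focal drift yields larger mean focal–sister F_ST."""
        means = []
        for f_focal in (0.02, 0.1, 0.3):
            vals = []
            for seed in range(5):
                spec = sim.CohortSpec(
                    chrom_lengths={"chr1": 2_000_000},
                    n_sites=5_000,
                    drift_f={"internal": 0.05, "focal": f_focal, "sister": 0.05, "comparison": 0.05},
                    seed=seed,
                )
                table, _ = sim.simulate_genotypes(spec)
                vals.append(
                    hudson_ratio_of_sums(
                        *table.allele_counts(table.sample_indices("focal")),
                        *table.allele_counts(table.sample_indices("sister")),
                    )
                )
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_sweep_forces_focal_frequency(self, sweep_cohort):
        spec, sweeps, table, truth = sweep_cohort
        sw = sweeps[0]
        sites = table.sites
        in_sweep = (
            (sites["chrom"] == sw.chrom)
            & (sites["pos0"] >= sw.start)
            & (sites["pos0"] < sw.end)
        ).to_numpy()
        k, n = table.allele_counts(table.sample_indices("focal"))
        # derived frequency: flip where the derived allele is REF
        derived_is_alt = (sites["derived"] == sites["alt"]).to_numpy()
        derived_freq = np.where(derived_is_alt, k / n, 1 - k / n)
        assert derived_freq[in_sweep].mean() == pytest.approx(sw.focal_freq, abs=0.03)
        assert truth.of_kind("sweep").iloc[0]["start"] == sw.start

    def test_outgroup_column_carries_ancestral_allele(self, sweep_cohort):
        _, _, table, _ = sweep_cohort
        derived = table.sites["derived"].to_numpy()
        ref = table.sites["ref"].to_numpy()
        alt = table.sites["alt"].to_numpy()
        anc = np.where(derived == alt, ref, alt)
        np.testing.assert_array_equal(np.asarray(table.outgroup, dtype=object), anc)


class TestDepthTracks:
    def test_poisson_mean_within_one_percent(self):
        spec = sim.CohortSpec(
            n_focal=2, n_sister=2, n_comparison=2, chrom_lengths={"chr1": 150_000}, seed=3
        )
        tracks, _ = sim.simulate_depth_tracks(spec, mean_depth_per_genome=10.0)
        for i in range(len(tracks.genomes)):
            assert tracks.depths["chr1"][i].mean() == pytest.approx(10.0, rel=0.01)

    def test_fixed_deletion_zeroes_all_focal_genomes(self):
        spec = sim.CohortSpec(
            n_focal=4, n_sister=2, n_comparison=2, chrom_lengths={"chr1": 10_000}, seed=3
        )
        tracks, truth = sim.simulate_depth_tracks(
            spec, deletions=[("chr1", 2_000, 2_600)], mean_depth_per_genome=10.0
        )
        focal = tracks.cohort_rows("focal")
        comp = tracks.cohort_rows("comparison")
        assert tracks.depths["chr1"][focal, 2_000:2_600].sum() == 0
        assert tracks.depths["chr1"][comp, 2_000:2_600].sum() > 0
        assert truth.of_kind("deletion").iloc[0]["end"] == 2_600

    def test_cohort_total_coverage_matches_study_scale(self):
        """28 focal genomes at 23x sum to ~644 per site; 11 at ~11.2x to ~123."""
        spec = sim.CohortSpec(chrom_lengths={"chr1": 100_000}, seed=4)
        tracks, _ = sim.simulate_depth_tracks(
            spec,
            mean_depth_per_genome={"focal": 23.0, "comparison": 123.0 / 11},
            n_comparison=11,
        )
        focal_sum = tracks.depths["chr1"][tracks.cohort_rows("focal")].sum(axis=0)
        comp_sum = tracks.depths["chr1"][tracks.cohort_rows("comparison")].sum(axis=0)
        assert focal_sum.mean() == pytest.approx(644.0, rel=0.01)
        assert comp_sum.mean() == pytest.approx(123.0, rel=0.02)
        assert tracks.expected_cohort_depth("focal") == pytest.approx(644.0)

    def test_negative_coverage_rejected(self, small_spec):
        with pytest.raises(ValueError, match="coverage"):
            sim.simulate_depth_tracks(small_spec, mean_depth_per_genome=-1.0)


class TestCnvMatrix:
    def test_all_ancestral_gives_copy_number_two(self, small_spec):
        m, _ = sim.simulate_cnv_matrix(
            small_spec, n_loci=10, background_freqs={"A": 1.0, "CN0": 0.0, "CN2": 0.0, "CNH": 0.0}
        )
        assert (m.copy_number == 2).all()

    def test_fixed_outlier_locus_separates_groups(self, small_spec):
        m, truth = sim.simulate_cnv_matrix(
            small_spec,
            n_loci=10,
            outlier_loci=[(0, {"A": 0.0, "CN0": 1.0, "CN2": 0.0, "CNH": 0.0},
                           {"A": 1.0, "CN0": 0.0, "CN2": 0.0, "CNH": 0.0})],
            background_freqs={"A": 1.0, "CN0": 0.0, "CN2": 0.0, "CNH": 0.0},
        )
        row = list(m.loci.df["name"]).index("cnv_00000")
        focal = m.individual_indices("focal")
        others = m.individual_indices(["sister", "comparison"])
        assert (m.copy_number[row, focal] == 0).all()
        assert (m.copy_number[row, others] == 2).all()
        assert truth.of_kind("cnv_outlier").iloc[0]["params"]["locus"] == "cnv_00000"

    def test_bad_frequency_vector_rejected(self, small_spec):
        with pytest.raises(ValueError, match="sum to 1"):
            sim.simulate_cnv_matrix(
                small_spec, n_loci=5, background_freqs={"A": 0.9, "CN0": 0.2, "CN2": 0.0, "CNH": 0.0}
            )

    def test_background_frequencies_agree_between_populations(self, small_spec):
        """Shared background frequencies: the focal sample frequency lies in
        the exact binomial interval implied by the comparison sample."""
        bg = {"A": 0.8, "CN0": 0.15, "CN2": 0.05, "CNH": 0.0}
        m, truth = sim.simulate_cnv_matrix(small_spec, n_loci=60, background_freqs=bg)
        draws = truth.extras["allele_draws"]
        n_focal_alleles = 2 * len(m.individual_indices("focal"))
        outside = 0
        for locus, grp in draws.groupby("locus"):
            focal_cn0 = int(grp.loc[grp["population"] == "focal", "CN0"].iloc[0])
            lo, hi = stats.binom.interval(0.999, n_focal_alleles, bg["CN0"])
            if not lo <= focal_cn0 <= hi:
                outside += 1
        assert outside <= 2  # 99.9% interval, 60 loci

    def test_allele_draw_record_is_consistent_with_matrix(self, small_spec):
        from arctic_sweep.cnv import allele_pair

        m, truth = sim.simulate_cnv_matrix(small_spec, n_loci=20)
        draws = truth.extras["allele_draws"]
        names = list(m.loci.df["name"])
        focal = m.individual_indices("focal")
        for locus, grp in draws.groupby("locus"):
            row = names.index(locus)
            tally = {"A": 0, "CN0": 0, "CN2": 0, "CNH": 0}
            for k in m.copy_number[row, focal]:
                for cls in allele_pair(int(k)):
                    tally[cls] += 1
            rec = grp[grp["population"] == "focal"].iloc[0]
            assert {c: int(rec[c]) for c in tally} == tally


class TestAnnotation:
    def test_planted_variant_realizes_exact_frequencies(self, small_spec):
        pv = sim.PlantedVariant(gene=0, effect_class="MODERATE", focal_freq=0.75, comparison_freq=0.125)
        genes, effects, truth, table = sim.simulate_annotation(
            small_spec, n_genes=4, derived_variants=[pv], n_background_effects=0
        )
        assert len(truth.df) == 1
        k, n = table.allele_counts(table.sample_indices("focal"))
        i = int(np.flatnonzero(table.sites["derived"].notna())[0])
        assert k[i] / n[i] == pytest.approx(0.75)
        kc, nc = table.allele_counts(table.sample_indices(["sister", "comparison"]))
        assert kc[i] / nc[i] == pytest.approx(0.125)

    def test_no_planted_variants_gives_empty_truth(self, small_spec):
        _, effects, truth, _ = sim.simulate_annotation(
            small_spec, n_genes=4, derived_variants=[], n_background_effects=0
        )
        assert truth.df.empty
        assert effects.empty

    def test_too_many_genes_rejected(self):
        spec = sim.CohortSpec(chrom_lengths={"chr1": 50_000}, n_sites=100, seed=1)
        with pytest.raises(ValueError, match="genes"):
            sim.simulate_annotation(spec, n_genes=50)

    def test_genes_do_not_overlap(self, small_spec):
        genes, _, _, _ = sim.simulate_annotation(small_spec, n_genes=10)
        g = genes.df[genes.df["kind"] == "gene"]
        for chrom, grp in g.groupby("chrom"):
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            assert (starts[1:] >= ends[:-1]).all()

    def test_call_rate_controls_missingness(self, small_spec):
        pv = sim.PlantedVariant(
            gene=0, effect_class="HIGH", focal_freq=0.8, comparison_freq=0.1,
            comparison_call_rate=0.5,
        )
        _, _, _, table = sim.simulate_annotation(
            small_spec, n_genes=4, derived_variants=[pv], n_background_effects=0
        )
        comp = table.sample_indices(["sister", "comparison"])
        called = (table.dosage[0, comp] != MISSING).sum()
        assert called == round(0.5 * len(comp))
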