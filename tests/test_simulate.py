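"""Simulator contracts: parent structure, recombination accounting, emission."""
import subprocess

import numpy as np
import pytest

from rtgpoly.simulate import (
    ForcedCrossover,
    GenomeSpec,
    NoiseModel,
    emit_depth_track,
    emit_observations,
    parent_cell,
    simulate_parent,
    simulate_rtg,
)


class TestGenomeSpec:
    def test_validation_errors(self):
        with pytest.raises(ValueError):
            GenomeSpec(chrom_lengths=(1000,), ploidy=(1,))
        with pytest.raises(ValueError):
            GenomeSpec(chrom_lengths=(1000,), ploidy=(3,), marker_density=0)
        with pytest.raises(ValueError):
            GenomeSpec(chrom_lengths=(1000,), ploidy=(3,), loh_blocks=((0, 500, 2000),))

    def test_yaml_round_trip(self, tmp_path, small_spec):
        path = tmp_path / "spec.yaml"
        small_spec.to_yaml(path)
        assert GenomeSpec.from_yaml(path) == small_spec


class TestSimulateParent:
    def test_marker_count_and_heterozygosity(self):
        spec = GenomeSpec(chrom_lengths=(100_000,), ploidy=(3,), marker_density=3.0, seed=1)
        parent = simulate_parent(spec)
        assert 250 <= parent.n_markers <= 350
        k = parent.dosage(0)
        assert np.all((k > 0) & (k < 3))
        assert np.all(np.diff(parent.positions[0]) > 0)

    def test_no_markers_inside_preexisting_loh_block(self):
        spec = GenomeSpec(
            chrom_lengths=(200_000,), ploidy=(3,), marker_density=3.0,
            loh_blocks=((0, 50_000, 100_000),), seed=2,
        )
        parent = simulate_parent(spec)
        pos = parent.positions[0]
        assert not np.any((pos > 50_000) & (pos <= 100_000))

    def test_genome_wide_marker_count_matches_hybrid_scale(self):
        # a ~12 Mb 16-chromosome genome at 3.4 markers/kbp carries ~40.8 K
        # markers, the scale observed in real triploid hybrid strains
        spec = GenomeSpec(
            chrom_lengths=(750_000,) * 16, ploidy=(3,) * 16, marker_density=3.4, seed=3
        )
        parent = simulate_parent(spec)
        assert abs(parent.n_markers - 40_800) / 40_800 < 0.05

    def test_dosage_weights(self):
        spec = GenomeSpec(chrom_lengths=(500_000,), ploidy=(4,), marker_density=3.0, seed=4)
        parent = simulate_parent(spec, dosage_weights={4: [1.0, 0.0, 0.0]})
        assert np.all(parent.dosage(0) == 1)

    def test_deterministic_given_seed(self, small_spec):
        a, b = simulate_parent(small_spec), simulate_parent(small_spec)
        for c in range(2):
            assert np.array_equal(a.positions[c], b.positions[c])
            assert np.array_equal(a.haplotypes[c], b.haplotypes[c])


class TestSimulateRtg:
    def test_no_dsb_means_no_change(self, small_parent):
        mother, daughter, truth = simulate_rtg(small_parent, n_dsb_per_Mb=0.0, seed=1)
        for c in range(2):
            assert np.array_equal(mother.dosage(c), small_parent.dosage(c))
            assert np.array_equal(daughter.dosage(c), small_parent.dosage(c))
        assert truth.events == []

    @pytest.mark.parametrize("seed", range(8))
    def test_chromatid_conservation_outside_conversion_tracts(self, small_parent, seed):
        # segregation is a partition of the chromatid pool, so allele counts
        # are conserved everywhere except where gene conversion overwrote a
        # recipient (the non-Mendelian 3:1 part of recombination)
        mother, daughter, truth = simulate_rtg(small_parent, n_dsb_per_Mb=8.0, seed=seed)
        for c in range(2):
            total = mother.dosage(c) + daughter.dosage(c)
            expected = 2 * small_parent.dosage(c)
            conv = truth.conversion_mask(c)
            assert np.array_equal(total[~conv], expected[~conv])
            violations = total != expected
            assert not np.any(violations & ~conv)

    def test_missegregation_violates_only_affected_chromosome(self, small_parent):
        mother, daughter, truth = simulate_rtg(
            small_parent, n_dsb_per_Mb=2.0, p_missegregation=1.0, seed=9
        )
        assert truth.missegregation is not None
        mc = truth.missegregation[0]
        for c in range(2):
            conv = truth.conversion_mask(c)
            # raw counts: both sisters still exist, so the sum is conserved
            # even on the missegregated chromosome
            assert np.array_equal(
                (mother.dosage(c) + daughter.dosage(c))[~conv],
                2 * small_parent.dosage(c)[~conv],
            )
            # in AF space (dosage at nominal ploidy) the missegregated
            # chromosome, and only it, breaks the equality
            scaled = truth.scaled_dosage("mother", c) + truth.scaled_dosage("daughter", c)
            equal = np.allclose(scaled[~conv], 2 * small_parent.dosage(c)[~conv])
            assert equal == (c != mc)
        # complementary whole-chromosome gain and loss
        assert {mother.copy_number(mc), daughter.copy_number(mc)} == {2, 4}

    def test_forced_co_produces_reciprocal_downstream_shift(self, forced_co_pair, small_parent):
        mother, daughter, truth, fc = forced_co_pair
        diff_m = mother.dosage(0) - small_parent.dosage(0)
        diff_d = daughter.dosage(0) - small_parent.dosage(0)
        # marker-by-marker accounting oracle over the explicit chromatid sets:
        # downstream of the breakpoint the two cells exchange exactly the
        # alleles at which the two recombining homologs differ
        h1, h2 = small_parent.haplotypes[0][0], small_parent.haplotypes[0][1]
        downstream = small_parent.positions[0] >= fc.pos
        expected = np.where(downstream, h2.astype(int) - h1.astype(int), 0)
        assert np.array_equal(diff_m, expected)
        assert np.array_equal(diff_d, -expected)

    def test_nco_touches_exactly_one_cell(self, small_parent):
        found = 0
        for seed in range(60):
            mother, daughter, truth = simulate_rtg(
                small_parent, n_dsb_per_Mb=0.6, p_crossover=0.0, seed=seed
            )
            if len(truth.events) != 1:
                continue
            found += 1
            (ev,) = truth.events
            changed = [
                c for c in ("mother", "daughter")
                if truth.shifted_mask(c, ev.chrom).any()
            ]
            assert len(changed) <= 1
        assert found >= 5

    def test_aneuploid_chromosome_pairs_extra_homolog(self):
        spec = GenomeSpec(chrom_lengths=(400_000,), ploidy=(4,), marker_density=3.0, seed=6)
        parent = simulate_parent(spec)
        mother, daughter, truth = simulate_rtg(parent, n_dsb_per_Mb=10.0, seed=6)
        used = {h for ev in truth.events for h in ev.homologs}
        assert used <= {0, 1, 2, 3}
        assert len(used) > 2  # the extra homolog does take part


class TestEmitObservations:
    def test_high_depth_recovers_true_af(self, small_parent):
        mother, _, _ = simulate_rtg(small_parent, n_dsb_per_Mb=3.0, seed=3)
        noise = NoiseModel(mean_depth=1e6, error_rate=0.0)
        table = emit_observations(mother, noise, seed=4)
        truth_af = np.concatenate([mother.dosage(c) / 3 for c in range(2)])
        obs = table["alt_depth"].to_numpy() / table["total_depth"].to_numpy()
        assert np.max(np.abs(obs - truth_af)) < 1e-2

    def test_full_dropout_empties_vcf(self, small_parent, tmp_path):
        path = tmp_path / "empty.vcf"
        emit_observations(
            parent_cell(small_parent), NoiseModel(dropout=1.0), seed=1, vcf_path=path
        )
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert body == []

    def test_vcf_byte_identical_across_runs(self, small_parent, tmp_path):
        noise = NoiseModel(mean_depth=50, error_rate=0.002)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        for p in (p1, p2):
            emit_observations(parent_cell(small_parent), noise, seed=7, vcf_path=p)
        assert p1.read_bytes() == p2.read_bytes()

    def test_negative_binomial_depth_model(self, small_parent):
        noise = NoiseModel(mean_depth=50, depth_model="nb", nb_dispersion=5.0)
        table = emit_observations(parent_cell(small_parent), noise, seed=2)
        depths = table["total_depth"].to_numpy()
        assert depths.var() > 1.5 * depths.mean()  # overdispersed vs Poisson

    def test_noise_model_validation(self):
        with pytest.raises(ValueError):
            NoiseModel(error_rate=0.6)
        with pytest.raises(ValueError):
            NoiseModel(mean_depth=-1)


class TestEmitDepthTrack:
    def test_uniform_copy_number_is_flat(self, small_parent):
        noise = NoiseModel(mean_depth=80)
        track = emit_depth_track(parent_cell(small_parent), noise, window=1000, seed=1)
        d = track["mean_depth"].to_numpy()
        sd = np.sqrt(80 / 1000)  # Poisson per-base, averaged over the window
        assert np.all(np.abs(d - 80) < 5 * sd)

    def test_planted_deletion_and_gain_scale_depth(self, small_parent):
        noise = NoiseModel(mean_depth=80)
        cell = parent_cell(small_parent)
        track = emit_depth_track(
            cell, noise, window=1000, seed=2, cnvs=((0, 100_000, 200_000, -1),)
        )
        g = track[track["chrom"] == "chrI"]
        inside = g[(g["start"] >= 100_000) & (g["end"] <= 200_000)]["mean_depth"].mean()
        outside = g[g["end"] <= 100_000]["mean_depth"].mean()
        assert abs(inside / outside - 2 / 3) < 0.02   # 2 of 3 haplotypes left
        track = emit_depth_track(
            cell, noise, window=1000, seed=3, cnvs=((0, 0, 300_000, 1),)
        )
        chr1 = track[track["chrom"] == "chrI"]["mean_depth"].mean()
        chr2 = track[track["chrom"] == "chrII"]["mean_depth"].mean()
        assert abs(chr1 / chr2 - 4 / 3) < 0.02

    def test_invalid_window(self, small_parent):
        with pytest.raises(ValueError):
            emit_depth_track(parent_cell(small_parent), NoiseModel(), window=0)


def test_simulate_cli_end_to_end(tmp_path):
    spec = GenomeSpec(chrom_lengths=(120_000, 100_000), ploidy=(3, 3), seed=1)
    cfg = tmp_path / "spec.yaml"
    spec.to_yaml(cfg)
    out = tmp_path / "sim"
    res = subprocess.run(
        ["rtgpoly", "simulate", "--config", str(cfg), "--seed", "4", "--out", str(out)],
        capture_output=True, text=True,
    )
    assert res.returncode == 0, res.stderr
    for name in ("catalog.tsv", "ploidy.tsv", "parent.vcf", "mother.vcf",
                 "daughter.vcf", "mother.depth.tsv", "mother.truth.bed"):
        assert (out / name).exists()
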