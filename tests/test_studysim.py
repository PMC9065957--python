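"""The generator must reproduce the study design arithmetic and the
statistical structure (coverage, baseline mixture, planted effects) that
the downstream inference assumes."""

import numpy as np
import pytest
from scipy.special import expit

from methfam import make_design, mask_snps, plant_ct_snps, simulate_methylome
from methfam.studysim import SimParams, delta_to_logit_shift


class TestMakeDesign:
    def test_replica_counts(self, design54):
        assert len(design54.family_ids) == 14
        assert len(design54.samples) == 54

    def test_groups_balanced(self, design54):
        warm = [s for s in design54.samples if s.parental_temp == "warm"]
        assert len(warm) == 27

    def test_families_split_across_offspring_temps(self, design54):
        for fam in design54.family_ids:
            temps = {
                s.offspring_temp
                for s in design54.samples
                if s.family_id == fam
            }
            assert temps == {"warm", "cold"}

    def test_minimal_design(self):
        d = make_design(
            n_full_crosses_per_group=1,
            n_partial_crosses_per_group=0,
            offspring_per_cell=1,
            singleton_cells=0,
        )
        assert len(d.family_ids) == 8
        assert len(d.samples) == 16

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            make_design(n_full_crosses_per_group=0)
        with pytest.raises(ValueError):
            make_design(offspring_per_cell=1, singleton_cells=1)
        with pytest.raises(ValueError):
            make_design(singleton_cells=1000)


class TestSimulateMethylome:
    def test_deterministic(self, design54):
        params = SimParams(n_cpg=300, chrom_len=20_000, seed=3)
        m1, _ = simulate_methylome(design54, params)
        m2, _ = simulate_methylome(design54, params)
        assert m1 == m2

    def test_counts_bounded(self, null_sim):
        matrix, _, _ = null_sim
        assert np.all(matrix.methylated >= 0)
        assert np.all(matrix.methylated <= matrix.coverage)

    def test_mean_coverage_near_target(self, null_sim):
        matrix, _, params = null_sim
        mean = matrix.coverage.mean()  # >= 10^5 site-sample draws
        assert abs(mean - params.target_coverage) / params.target_coverage < 0.05

    def test_null_truth_empty_and_group_difference_small(
        self, design54, null_sim
    ):
        from conftest import pooled_group_difference

        matrix, truth, _ = null_sim
        assert all(not v for v in truth.regions.values())
        warm = [s.sample_id for s in design54.samples if s.parental_temp == "warm"]
        cold = [s.sample_id for s in design54.samples if s.parental_temp == "cold"]
        assert abs(pooled_group_difference(matrix, warm, cold)) < 0.005

    def test_null_group_z_scores_symmetric(self, design54, null_sim):
        matrix, _, _ = null_sim
        warm = np.array([s.parental_temp == "warm" for s in design54.samples])
        p = matrix.methylated.sum(axis=1) / matrix.coverage.sum(axis=1)
        pa = matrix.methylated[:, warm].sum(axis=1) / matrix.coverage[:, warm].sum(axis=1)
        pb = matrix.methylated[:, ~warm].sum(axis=1) / matrix.coverage[:, ~warm].sum(axis=1)
        keep = (p > 0.05) & (p < 0.95)
        diff = (pa - pb)[keep]
        z = diff / diff.std()
        se = 1.0 / np.sqrt(len(z))
        assert abs(z.mean()) < 3 * se

    def test_baseline_mixture_mean_recovered(self, design54):
        params = SimParams(seed=5, family_sd=0.0, n_cpg=5_000, chrom_len=200_000)
        matrix, _ = simulate_methylome(design54, params)
        observed = matrix.methylated.sum() / matrix.coverage.sum()
        expected = sum(w * a / (a + b) for w, a, b in params.baseline_mixture)
        assert abs(observed - expected) < 0.02

    def test_planted_parental_delta_recovered(self, design54):
        from conftest import pooled_group_difference

        params = SimParams(seed=9, n_parental_dmrs=5, family_sd=0.0)
        matrix, truth = simulate_methylome(design54, params)
        warm = [s.sample_id for s in design54.samples if s.parental_temp == "warm"]
        cold = [s.sample_id for s in design54.samples if s.parental_temp == "cold"]
        for region in truth.regions["adult"]:
            diff = pooled_group_difference(matrix, warm, cold, region.interval)
            assert diff == pytest.approx(params.dmr_delta, abs=0.05)

    def test_planted_regions_disjoint_within_term(self, design54):
        params = SimParams(seed=13, n_parental_dmrs=20, n_offspring_dmrs=5)
        _, truth = simulate_methylome(design54, params)
        for term, regions in truth.regions.items():
            ivs = sorted((r.interval.chrom, r.interval.start, r.interval.end)
                         for r in regions)
            for (c1, s1, e1), (c2, s2, _e2) in zip(ivs, ivs[1:]):
                assert c1 != c2 or e1 <= s2

    def test_zero_cpgs_rejected(self, design54):
        with pytest.raises(ValueError):
            simulate_methylome(design54, SimParams(n_cpg=0))

    def test_delta_to_logit_shift_round_trip(self):
        shift = delta_to_logit_shift(0.3)
        assert expit(shift / 2) - expit(-shift / 2) == pytest.approx(0.3)


class TestPlantCtSnps:
    def test_zero_sites_is_noop(self, design54, small_sim):
        out, bed = plant_ct_snps(small_sim, design54, 0, seed=1)
        assert out == small_sim and bed == []

    def test_bed_has_requested_records_at_cpg_positions(self, design54, small_sim):
        _, bed = plant_ct_snps(small_sim, design54, 100, seed=2)
        assert len(bed) == 100
        sites = set(zip(small_sim.chrom, small_sim.pos))
        assert all((iv.chrom, iv.start) in sites and iv.length == 1 for iv in bed)

    def test_masking_removes_exactly_planted_sites(self, design54, small_sim):
        planted, bed = plant_ct_snps(small_sim, design54, 100, seed=2)
        masked = mask_snps(planted, bed)
        # set-difference oracle
        removed = {(iv.chrom, iv.start) for iv in bed}
        expected = [
            (c, p) for c, p in zip(small_sim.chrom, small_sim.pos)
            if (c, p) not in removed
        ]
        assert masked.n_sites == small_sim.n_sites - 100
        assert expected == list(zip(masked.chrom, masked.pos))

    def test_too_many_sites_rejected(self, design54, small_sim):
        with pytest.raises(ValueError):
            plant_ct_snps(small_sim, design54, small_sim.n_sites + 1)
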