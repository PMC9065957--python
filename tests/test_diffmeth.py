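"""Smoothing, dispersion estimation, site-level Wald tests and BH-FDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methfam import (
    FilterSpec,
    MethylMatrix,
    SmoothSpec,
    bh_fdr,
    build_design_matrix,
    coverage_filter,
    estimate_dispersion,
    make_design,
    simulate_methylome,
    smooth_proportions,
    test_dml,
)
from methfam.studysim import SimParams


def matrix_of(chrom, pos, cov, meth, samples=None):
    cov = np.atleast_2d(np.asarray(cov, dtype=np.int64))
    meth = np.atleast_2d(np.asarray(meth, dtype=np.int64))
    if cov.shape[0] != len(pos):
        cov, meth = cov.T, meth.T
    return MethylMatrix(
        chrom=np.array(chrom, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        coverage=cov,
        methylated=meth,
        samples=samples or [f"s{j}" for j in range(cov.shape[1])],
    )


class TestSmoothing:
    def test_isolated_site_is_raw_ratio(self):
        m = matrix_of(["chr1", "chr1"], [0, 10_000], [[4], [8]], [[2], [6]])
        sm = smooth_proportions(m, SmoothSpec(window=500))
        assert sm.proportions[0, 0] == pytest.approx(2 / 4)
        assert sm.proportions[1, 0] == pytest.approx(6 / 8)

    def test_two_close_sites_pool_counts(self):
        m = matrix_of(["chr1", "chr1"], [0, 100], [[4], [8]], [[2], [6]])
        sm = smooth_proportions(m, SmoothSpec(window=500))
        assert np.allclose(sm.proportions[:, 0], 8 / 12)

    def test_window_does_not_cross_chromosomes(self):
        m = matrix_of(["chr1", "chr2"], [0, 10], [[4], [8]], [[0], [8]])
        sm = smooth_proportions(m, SmoothSpec(window=500))
        assert sm.proportions[0, 0] == 0.0
        assert sm.proportions[1, 0] == 1.0

    def test_zero_coverage_window_flagged_missing(self):
        m = matrix_of(["chr1"], [0], [[0]], [[0]])
        sm = smooth_proportions(m)
        assert sm.missing[0, 0]
        assert np.isnan(sm.proportions[0, 0])

    def test_matches_brute_force_double_loop(self, small_sim):
        spec = SmoothSpec(window=500)
        sm = smooth_proportions(small_sim, spec)
        half = spec.window / 2
        # O(n^2) oracle over site pairs
        for j in (0, 11):
            for i in range(0, small_sim.n_sites, 37):
                in_win = (small_sim.chrom == small_sim.chrom[i]) & (
                    np.abs(small_sim.pos - small_sim.pos[i]) <= half
                )
                n = small_sim.coverage[in_win, j].sum()
                m = small_sim.methylated[in_win, j].sum()
                assert sm.pooled_coverage[i, j] == n
                assert sm.proportions[i, j] == pytest.approx(m / n)


class TestDispersion:
    def test_identical_high_coverage_proportions_near_lower_clamp(self):
        cov = np.full((200, 20), 1000)
        meth = cov // 2
        m = matrix_of(
            ["chr1"] * 200, np.arange(200) * 1000, cov, meth
        )
        phi = estimate_dispersion(m, smooth_proportions(m), prior_weight=0.0)
        assert np.all(phi <= 0.002)

    def test_recovers_simulated_phi(self, design54, null_filtered):
        phi = estimate_dispersion(null_filtered)
        assert abs(phi.mean() - 0.1) < 0.02

    def test_clamped_to_valid_range(self, null_filtered):
        phi = estimate_dispersion(null_filtered)
        assert np.all((phi >= 1e-4) & (phi <= 0.99))


class TestTestDml:
    def test_identical_samples_give_null_result(self, design54):
        n_sites = 20
        cov = np.full((n_sites, 54), 30)
        meth = np.full((n_sites, 54), 15)
        m = matrix_of(
            ["chr1"] * n_sites, np.arange(n_sites) * 1000, cov, meth,
            samples=design54.sample_ids,
        )
        sm = smooth_proportions(m)
        dml = test_dml(m, sm, np.full(n_sites, 0.1), build_design_matrix(design54))
        assert np.allclose(dml["beta"], 0.0, atol=1e-12)
        assert np.allclose(dml["p"], 1.0)

    def test_null_p_values_approximately_uniform(
        self, design54, null_filtered, design_matrix54
    ):
        sm = smooth_proportions(null_filtered)
        phi = estimate_dispersion(null_filtered, sm)
        dml = test_dml(null_filtered, sm, phi, design_matrix54)
        for term in ("adult", "offspring", "interaction"):
            frac = (dml.loc[dml["term"] == term, "p"] < 0.05).mean()
            assert 0.035 <= frac <= 0.065

    def test_planted_region_p_far_below_background(self, design54, design_matrix54):
        params = SimParams(seed=9, n_parental_dmrs=5, family_sd=0.0)
        matrix, truth = simulate_methylome(design54, params)
        f = coverage_filter(matrix, FilterSpec())
        sm = smooth_proportions(f)
        dml = test_dml(f, sm, estimate_dispersion(f, sm), design_matrix54)
        adult = dml[dml["term"] == "adult"]
        in_region = np.zeros(len(adult), dtype=bool)
        for r in truth.regions["adult"]:
            iv = r.interval
            in_region |= (
                (adult["chrom"] == iv.chrom)
                & (adult["pos"] >= iv.start)
                & (adult["pos"] < iv.end)
            ).to_numpy()
        p_in = np.median(adult["p"].to_numpy()[in_region])
        p_out = np.median(adult["p"].to_numpy()[~in_region])
        assert p_in < p_out * 1e-2

    def test_flipping_adult_coding_flips_beta_keeps_p(
        self, design54, small_sim
    ):
        f = coverage_filter(small_sim, FilterSpec())
        sm = smooth_proportions(f)
        phi = estimate_dispersion(f, sm)
        X = build_design_matrix(design54)
        flipped = X.copy()
        flipped["adult"] = 1.0 - flipped["adult"]
        flipped["interaction"] = flipped["adult"] * flipped["offspring"]
        a = test_dml(f, sm, phi, X)
        b = test_dml(f, sm, phi, flipped)
        a, b = a[a.term == "adult"], b[b.term == "adult"]
        assert np.allclose(a["beta"].to_numpy(), -b["beta"].to_numpy(), atol=1e-9)
        assert np.allclose(a["p"].to_numpy(), b["p"].to_numpy(), atol=1e-9)

    def test_sample_order_invariant(self, design54, small_sim):
        f = coverage_filter(small_sim, FilterSpec())

        def run(order):
            sub = f.take_samples(order)
            sm = smooth_proportions(sub)
            phi = estimate_dispersion(sub, sm)
            return test_dml(sub, sm, phi, build_design_matrix(design54, order))

        a = run(f.samples)
        b = run(f.samples[::-1])
        assert np.allclose(
            a[a.term == "adult"]["p"].to_numpy(),
            b[b.term == "adult"]["p"].to_numpy(),
            atol=1e-9,
        )

    def test_power_monotone_in_delta(self, design54, design_matrix54):
        sens = []
        for delta in (0.1, 0.2, 0.3):
            params = SimParams(
                seed=17, n_parental_dmrs=10, dmr_delta=delta, family_sd=0.0,
                n_cpg=4000, chrom_len=100_000,
            )
            matrix, truth = simulate_methylome(design54, params)
            f = coverage_filter(matrix, FilterSpec())
            sm = smooth_proportions(f)
            dml = test_dml(f, sm, estimate_dispersion(f, sm), design_matrix54)
            adult = dml[dml["term"] == "adult"]
            hit = 0
            for r in truth.regions["adult"]:
                iv = r.interval
                sub = adult[
                    (adult["chrom"] == iv.chrom)
                    & (adult["pos"] >= iv.start)
                    & (adult["pos"] < iv.end)
                ]
                hit += int((sub["fdr"] < 0.001).any())
            sens.append(hit / len(truth.regions["adult"]))
        assert sens[0] <= sens[1] <= sens[2]
        assert sens[2] >= 0.9


class TestBhFdr:
    def test_closed_form_example(self):
        assert np.allclose(bh_fdr(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr(np.array([0.42]))[0] == pytest.approx(0.42)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([0.5, 1.5]))

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=1000))
    def test_matches_step_up_definition(self, ps):
        p = np.array(ps)
        adj = bh_fdr(p)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            expected[i] = running
        assert np.allclose(adj, expected, atol=1e-12)
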