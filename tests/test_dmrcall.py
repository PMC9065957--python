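"""DMR calling rules and the pooled mean-difference summary."""

import numpy as np
import pandas as pd
import pytest

from methfam import DMRSpec, FilterSpec, call_dmrs, coverage_filter, dmr_mean_diff
from methfam.dmrcall import DMR
from methfam.methio import GenomicInterval
from methfam.studysim import SimParams
from methfam import make_design, simulate_methylome


def dml_frame(pos, fdr, chrom="chr1", term="adult", wald=None):
    pos = np.asarray(pos)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "term": term,
            "beta": 0.1,
            "se": 0.05,
            "wald": wald if wald is not None else np.full(len(pos), 2.0),
            "p": fdr,
            "fdr": fdr,
        }
    )


def brute_force_dmrs(pos, sig, spec):
    """Independent re-statement of the calling rules as explicit scans."""
    pos = np.asarray(pos)
    sig = np.asarray(sig, dtype=bool)
    sig_pos = pos[sig]
    # cluster significant sites by gap
    clusters, current = [], []
    for p in sig_pos:
        if current and p - current[-1] > spec.merge_dist:
            clusters.append(current)
            current = []
        current.append(p)
    if current:
        clusters.append(current)
    regions = []
    for cl in clusters:
        lo, hi = cl[0], cl[-1]
        members = (pos >= lo) & (pos <= hi)
        if sig[members].sum() / members.sum() >= spec.pct_sig:
            regions.append((lo, hi))
    # merge close regions when combined density still qualifies
    merged = []
    for lo, hi in regions:
        if merged and lo - merged[-1][1] < spec.merge_dist:
            plo = merged[-1][0]
            members = (pos >= plo) & (pos <= hi)
            if sig[members].sum() / members.sum() >= spec.pct_sig:
                merged[-1] = (plo, hi)
                continue
        merged.append((lo, hi))
    out = []
    for lo, hi in merged:
        members = (pos >= lo) & (pos <= hi)
        if hi - lo + 1 >= spec.min_len and members.sum() >= spec.min_cpg:
            out.append((int(lo), int(hi) + 1, int(members.sum()), int(sig[members].sum())))
    return out


class TestCallDmrs:
    def test_no_significant_sites_empty(self):
        dml = dml_frame([10, 20, 30], [0.5, 0.9, 0.2])
        assert call_dmrs(dml, DMRSpec(sig_threshold=0.001), "adult") == []

    def test_single_run_of_five(self):
        dml = dml_frame([100, 120, 140, 160, 200], [1e-5] * 5)
        (dmr,) = call_dmrs(dml, DMRSpec(sig_threshold=0.001), "adult")
        assert dmr.interval == GenomicInterval("chr1", 100, 201)
        assert dmr.n_cpg == 5 and dmr.n_sig == 5
        assert dmr.area_stat == pytest.approx(10.0)

    def test_short_span_dropped(self):
        dml = dml_frame([100, 110, 130], [1e-5] * 3)  # span 31 < 50
        assert call_dmrs(dml, DMRSpec(sig_threshold=0.001), "adult") == []

    def test_too_few_cpgs_dropped(self):
        dml = dml_frame([100, 190], [1e-5] * 2)
        assert call_dmrs(dml, DMRSpec(sig_threshold=0.001), "adult") == []

    def test_density_rule(self):
        # 3 significant + 4 interleaved non-significant members: 3/7 < 0.5
        pos = [100, 110, 120, 130, 140, 150, 160]
        fdr = [1e-5, 0.9, 0.9, 1e-5, 0.9, 0.9, 1e-5]
        assert call_dmrs(dml_frame(pos, fdr), DMRSpec(sig_threshold=0.001), "adult") == []

    def test_unsorted_input_rejected(self):
        dml = dml_frame([100, 90, 120], [1e-5] * 3)
        with pytest.raises(ValueError, match="sorted"):
            call_dmrs(dml, DMRSpec(sig_threshold=0.001), "adult")

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 800
        pos = np.sort(rng.choice(40_000, size=n, replace=False))
        # spatially clustered significance plus background noise
        sig_p = np.where(rng.random(n) < 0.08, 1e-6, rng.random(n))
        centers = rng.choice(n, size=6)
        for c in centers:
            near = np.abs(pos - pos[c]) < 400
            sig_p[near] = np.where(rng.random(near.sum()) < 0.9, 1e-6, sig_p[near])
        spec = DMRSpec(sig_threshold=0.001)
        got = call_dmrs(dml_frame(pos, sig_p), spec, "adult")
        expected = brute_force_dmrs(pos, sig_p < spec.sig_threshold, spec)
        assert [
            (d.interval.start, d.interval.end, d.n_cpg, d.n_sig) for d in got
        ] == expected
        for d in got:
            assert d.n_sig / d.n_cpg >= spec.pct_sig
            assert d.length >= spec.min_len and d.n_cpg >= spec.min_cpg

    def test_per_chromosome_independence(self):
        a = dml_frame([100, 120, 140, 160, 200], [1e-5] * 5, chrom="chr1")
        b = dml_frame([300, 320, 340, 360, 400], [1e-5] * 5, chrom="chr2")
        both = pd.concat([a, b], ignore_index=True)
        spec = DMRSpec(sig_threshold=0.001)
        combined = call_dmrs(both, spec, "adult")
        separate = call_dmrs(a, spec, "adult") + call_dmrs(b, spec, "adult")
        assert [d.interval for d in combined] == [d.interval for d in separate]


class TestDmrMeanDiff:
    def make_region(self, start=0, end=100):
        return DMR(GenomicInterval("chr1", start, end), "adult", 3, 3, 6.0)

    def test_identical_groups_zero(self, design54, small_sim):
        half = small_sim.samples[:27]
        d = dmr_mean_diff(
            small_sim, self.make_region(0, 40_000), half, half
        )
        assert d == pytest.approx(0.0)

    def test_planted_delta_recovered(self, design54):
        params = SimParams(seed=9, n_parental_dmrs=3, family_sd=0.0)
        matrix, truth = simulate_methylome(design54, params)
        warm = [s.sample_id for s in design54.samples if s.parental_temp == "warm"]
        cold = [s.sample_id for s in design54.samples if s.parental_temp == "cold"]
        for r in truth.regions["adult"]:
            dmr = DMR(r.interval, "adult", 1, 1, 0.0)
            assert dmr_mean_diff(matrix, dmr, warm, cold) == pytest.approx(
                0.3, abs=0.05
            )

    def test_single_cpg_region_equals_site_difference(self, small_sim):
        pos = int(small_sim.pos[5])
        dmr = DMR(GenomicInterval("chr1", pos, pos + 1), "adult", 1, 1, 0.0)
        a, b = small_sim.samples[:10], small_sim.samples[10:20]
        got = dmr_mean_diff(small_sim, dmr, a, b)
        ja = [small_sim.samples.index(s) for s in a]
        jb = [small_sim.samples.index(s) for s in b]
        expected = (
            small_sim.methylated[5, ja].sum() / small_sim.coverage[5, ja].sum()
            - small_sim.methylated[5, jb].sum() / small_sim.coverage[5, jb].sum()
        )
        assert got == pytest.approx(expected)
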