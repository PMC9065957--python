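"""Synthetic family-structured WGBS study generator.

Emulates a two-generation thermal-plasticity design: broodstock held under
warm or cold regimes are crossed in 2x2 blocks (two sires x two dams = four
full-sib families) plus one partial 2x2 (three families) per parental group,
and each family's eggs are split between warm and cold offspring rearing
temperatures.  The default design reproduces the study bookkeeping of 14
full-sib families and 54 offspring (two offspring per family-by-temperature
cell, two cells reduced to a singleton).

Counts are generated with the statistical structure the downstream
inference assumes:

* per-site baseline methylation drawn from a bimodal Beta mixture
  (hypomethylated / intermediate / hypermethylated states),
* treatment effects planted in non-overlapping regions, additive on the
  logit scale, with the effect size ``dmr_delta`` expressed as a
  proportion-scale difference at a 0.5 baseline,
* diffuse family random effects (iid logit offsets per family and site),
* family-confounded regions where a single family carries a large logit
  shift — built so jackknife verification should reject them,
* negative-binomial coverage around the target depth and beta-binomial
  methylated counts with overdispersion ``dispersion_phi``.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

from .methio import GenomicInterval, MethylMatrix

__all__ = [
    "SampleMeta",
    "Family",
    "StudyDesign",
    "SimParams",
    "PlantedRegion",
    "SimTruth",
    "make_design",
    "simulate_methylome",
    "plant_ct_snps",
    "delta_to_logit_shift",
]

WARM = "warm"
COLD = "cold"
TERMS = ("adult", "offspring", "interaction")


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    sire_id: str
    dam_id: str
    family_id: str
    parental_temp: str
    offspring_temp: str


@dataclass(frozen=True)
class Family:
    family_id: str
    sire_id: str
    dam_id: str
    parental_temp: str


@dataclass
class StudyDesign:
    """Samples plus family records for a two-temperature 2x2-cross design."""

    samples: list[SampleMeta]
    families: list[Family]
    parental_groups: tuple[str, str] = (WARM, COLD)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        fam = {f.family_id: f for f in self.families}
        for s in self.samples:
            f = fam.get(s.family_id)
            if f is None:
                raise ValueError(f"sample {s.sample_id}: unknown family {s.family_id}")
            if (s.sire_id, s.dam_id) != (f.sire_id, f.dam_id):
                raise ValueError(
                    f"sample {s.sample_id}: parents disagree with family record"
                )
            if s.parental_temp != f.parental_temp:
                raise ValueError(
                    f"sample {s.sample_id}: parental_temp differs within family"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def family_ids(self) -> list[str]:
        return [f.family_id for f in self.families]

    def samples_of_family(self, family_id: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.family_id == family_id]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(s) for s in self.samples])

    @classmethod
    def from_frame(cls, df) -> "StudyDesign":
        samples = [
            SampleMeta(
                sample_id=str(r.sample_id),
                sire_id=str(r.sire_id),
                dam_id=str(r.dam_id),
                family_id=str(r.family_id),
                parental_temp=str(r.parental_temp),
                offspring_temp=str(r.offspring_temp),
            )
            for r in df.itertuples()
        ]
        fam: dict[str, Family] = {}
        for s in samples:
            fam.setdefault(
                s.family_id, Family(s.family_id, s.sire_id, s.dam_id, s.parental_temp)
            )
        return cls(samples=samples, families=list(fam.values()))


def make_design(
    n_full_crosses_per_group: int = 1,
    n_partial_crosses_per_group: int = 1,
    offspring_per_cell: int = 2,
    singleton_cells: int = 2,
    seed: int = 0,
) -> StudyDesign:
    """Build the breeding design.

    Each parental group (warm, cold) gets ``n_full_crosses_per_group`` full
    2x2 crosses (4 full-sib families each) and ``n_partial_crosses_per_group``
    partial crosses missing one family (3 families each).  Every family is
    split across both offspring rearing temperatures with
    ``offspring_per_cell`` offspring per family-by-temperature cell;
    ``singleton_cells`` randomly chosen cells (alternating between parental
    groups so the reduction is balanced) are reduced to a single offspring.

    Defaults reproduce 14 families and 54 samples.
    """
    if min(n_full_crosses_per_group, offspring_per_cell) < 1 or (
        n_partial_crosses_per_group < 0 or singleton_cells < 0
    ):
        raise ValueError("counts must be positive (partial/singleton counts >= 0)")

    rng = np.random.default_rng(seed)
    families: list[Family] = []
    for group in (WARM, COLD):
        g = group[0].upper()
        cross_sizes = [4] * n_full_crosses_per_group + [3] * n_partial_crosses_per_group
        for c, size in enumerate(cross_sizes):
            sires = [f"sire_{g}{c}a", f"sire_{g}{c}b"]
            dams = [f"dam_{g}{c}a", f"dam_{g}{c}b"]
            pairs = [(s, d) for s in sires for d in dams][:size]
            for s, d in pairs:
                fid = f"fam_{g}{c}_{s[-1]}{d[-1]}"
                families.append(Family(fid, s, d, group))

    cells = [
        (f, temp) for f in families for temp in (WARM, COLD)
    ]
    if singleton_cells > len(cells):
        raise ValueError("singleton_cells exceeds number of family-by-temperature cells")
    if offspring_per_cell == 1 and singleton_cells:
        raise ValueError("cannot reduce cells that already hold one offspring")

    # choose singleton cells alternating between parental groups so e.g. the
    # default two reductions leave 27 samples in each group
    reduced: set[tuple[str, str]] = set()
    group_cells = {
        WARM: [c for c in cells if c[0].parental_temp == WARM],
        COLD: [c for c in cells if c[0].parental_temp == COLD],
    }
    for i in range(singleton_cells):
        group = (WARM, COLD)[i % 2]
        pool = [c for c in group_cells[group] if (c[0].family_id, c[1]) not in reduced]
        if not pool:
            pool = [c for c in cells if (c[0].family_id, c[1]) not in reduced]
        pick = pool[rng.integers(len(pool))]
        reduced.add((pick[0].family_id, pick[1]))

    samples: list[SampleMeta] = []
    for fam, temp in cells:
        n = 1 if (fam.family_id, temp) in reduced else offspring_per_cell
        for k in range(n):
            samples.append(
                SampleMeta(
                    sample_id=f"{fam.family_id}_{temp}_{k + 1}",
                    sire_id=fam.sire_id,
                    dam_id=fam.dam_id,
                    family_id=fam.family_id,
                    parental_temp=fam.parental_temp,
                    offspring_temp=temp,
                )
            )
    return StudyDesign(samples=samples, families=families)


# ---------------------------------------------------------------------------
# simulation parameters and truth


@dataclass
class SimParams:
    """Knobs for the synthetic methylome.

    Defaults place 10,000 CpGs on two 250 kb chromosomes (~50 bp mean
    spacing, matching the dinucleotide density of a weakly CpG-depleted
    salmonid genome) at the study's anticipated 15x depth.
    """

    n_chrom: int = 2
    chrom_len: int = 250_000
    n_cpg: int = 10_000
    target_coverage: float = 15.0
    coverage_dispersion: float = 8.0  # negative-binomial shape (size)
    # baseline Beta mixture: (weight, alpha, beta) per state
    baseline_mixture: tuple[tuple[float, float, float], ...] = (
        (0.30, 2.0, 18.0),   # hypomethylated
        (0.10, 8.0, 8.0),    # intermediate
        (0.60, 18.0, 2.0),   # hypermethylated
    )
    dispersion_phi: float = 0.1
    family_sd: float = 0.3
    n_parental_dmrs: int = 0
    n_offspring_dmrs: int = 0
    n_interaction_dmrs: int = 0
    n_family_confounded_regions: int = 0
    confound_logit_offset: float = 2.0
    dmr_len_range: tuple[int, int] = (1_000, 2_000)
    dmr_delta: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_chrom, self.n_cpg,
            self.n_parental_dmrs, self.n_offspring_dmrs,
            self.n_interaction_dmrs, self.n_family_confounded_regions,
        )
        if any(c < 0 for c in counts) or self.n_chrom == 0:
            raise ValueError("counts must be non-negative (n_chrom positive)")
        if self.n_cpg == 0:
            raise ValueError("n_cpg must be positive")
        if not 0.0 < self.dmr_delta < 1.0:
            raise ValueError("dmr_delta must lie in (0, 1)")
        if not 0.0 < self.dispersion_phi < 1.0:
            raise ValueError("dispersion_phi must lie in (0, 1)")
        w = sum(m[0] for m in self.baseline_mixture)
        if abs(w - 1.0) > 1e-8:
            raise ValueError("baseline mixture weights must sum to 1")


@dataclass(frozen=True)
class PlantedRegion:
    interval: GenomicInterval
    term: str
    delta: float


@dataclass
class SimTruth:
    """Ground truth emitted alongside the simulated matrix."""

    regions: dict[str, list[PlantedRegion]] = field(default_factory=dict)
    confounded: list[tuple[GenomicInterval, str, float]] = field(default_factory=list)
    family_effects: dict[str, float] = field(default_factory=dict)
    snp_sites: list[GenomicInterval] = field(default_factory=list)

    def regions_for(self, term: str) -> list[PlantedRegion]:
        return self.regions.get(term, [])


def delta_to_logit_shift(delta: float) -> float:
    """Logit-scale shift giving a proportion difference ``delta`` at a 0.5 baseline."""
    return float(logit(0.5 + delta / 2.0) - logit(0.5 - delta / 2.0))


def _place_regions(
    rng: np.random.Generator,
    params: SimParams,
    n_regions: int,
    occupied: list[tuple[int, int, int]],
) -> list[GenomicInterval]:
    """Sample non-overlapping intervals, avoiding previously placed ones."""
    out: list[GenomicInterval] = []
    tries = 0
    while len(out) < n_regions:
        tries += 1
        if tries > 1000 * max(n_regions, 1):
            raise ValueError("could not place requested regions without overlap")
        c = int(rng.integers(params.n_chrom))
        length = int(rng.integers(params.dmr_len_range[0], params.dmr_len_range[1] + 1))
        if length >= params.chrom_len:
            raise ValueError("dmr length exceeds chromosome length")
        start = int(rng.integers(params.chrom_len - length))
        end = start + length
        if any(c == oc and start < oe and os_ < end for oc, os_, oe in occupied):
            continue
        occupied.append((c, start, end))
        out.append(GenomicInterval(f"chr{c + 1}", start, end))
    return out


def _region_mask(chrom: np.ndarray, pos: np.ndarray, iv: GenomicInterval) -> np.ndarray:
    return (chrom == iv.chrom) & (pos >= iv.start) & (pos < iv.end)


def simulate_methylome(
    design: StudyDesign, params: SimParams
) -> tuple[MethylMatrix, SimTruth]:
    """Simulate per-CpG beta-binomial counts for every sample in ``design``.

    Returns the count matrix and the ground truth (planted regions per term,
    family-confounded regions with their driver family, diffuse family
    effect scale).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)

    # CpG positions: uniform random with a minimum 2 bp gap, per chromosome
    per_chrom = np.full(params.n_chrom, params.n_cpg // params.n_chrom, dtype=int)
    per_chrom[: params.n_cpg % params.n_chrom] += 1
    chroms: list[np.ndarray] = []
    positions: list[np.ndarray] = []
    for c in range(params.n_chrom):
        k = per_chrom[c]
        if 2 * k > params.chrom_len:
            raise ValueError("chromosome too short for requested CpG count")
        # draw gaps >= 2 summing below chrom_len
        slack = rng.multinomial(params.chrom_len - 2 * k, np.full(k, 1.0 / k))
        pos = np.cumsum(slack + 2) - 1
        chroms.append(np.full(k, f"chr{c + 1}", dtype=object))
        positions.append(pos.astype(np.int64))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)

    n_sites = len(pos)
    n_samples = len(design.samples)

    # baseline per-site methylation from the Beta mixture
    weights = np.array([m[0] for m in params.baseline_mixture])
    comp = rng.choice(len(weights), size=n_sites, p=weights)
    alphas = np.array([m[1] for m in params.baseline_mixture])[comp]
    betas = np.array([m[2] for m in params.baseline_mixture])[comp]
    baseline = rng.beta(alphas, betas)

    truth = SimTruth()
    occupied: list[tuple[int, int, int]] = []
    shift = delta_to_logit_shift(params.dmr_delta)
    half = float(logit(0.5 + params.dmr_delta / 2.0))

    # sample-level indicator vectors
    is_warm_parent = np.array(
        [s.parental_temp == WARM for s in design.samples], dtype=float
    )
    is_warm_off = np.array(
        [s.offspring_temp == WARM for s in design.samples], dtype=float
    )
    term_indicator = {
        "adult": is_warm_parent,
        "offspring": is_warm_off,
        "interaction": is_warm_parent * is_warm_off,
    }

    # logit-scale mean per (site, sample)
    eta = np.tile(logit(np.clip(baseline, 1e-6, 1 - 1e-6))[:, None], (1, n_samples))

    n_regions = {
        "adult": params.n_parental_dmrs,
        "offspring": params.n_offspring_dmrs,
        "interaction": params.n_interaction_dmrs,
    }
    for term in TERMS:
        intervals = _place_regions(rng, params, n_regions[term], occupied)
        truth.regions[term] = [
            PlantedRegion(iv, term, params.dmr_delta) for iv in intervals
        ]
        for iv in intervals:
            sites = _region_mask(chrom, pos, iv)
            # re-anchor the region baseline at 0.5 so the planted shift is
            # a clean proportion difference of dmr_delta
            eta[sites, :] = -half
            eta[np.ix_(sites, term_indicator[term] > 0)] += shift

    # family-confounded regions: one family carries a large logit shift
    fam_ids = design.family_ids
    fam_col = {f: np.array([s.family_id == f for s in design.samples]) for f in fam_ids}
    confound = _place_regions(
        rng, params, params.n_family_confounded_regions, occupied
    )
    for iv in confound:
        driver = fam_ids[int(rng.integers(len(fam_ids)))]
        sites = _region_mask(chrom, pos, iv)
        eta[sites, :] = 0.0  # 0.5 baseline, matching planted regions
        eta[np.ix_(sites, fam_col[driver])] += params.confound_logit_offset
        truth.confounded.append((iv, driver, params.confound_logit_offset))

    # diffuse family random effects: iid logit offsets per (site, family)
    if params.family_sd > 0:
        fam_index = np.array(
            [fam_ids.index(s.family_id) for s in design.samples]
        )
        fam_fx = rng.normal(0.0, params.family_sd, size=(n_sites, len(fam_ids)))
        eta += fam_fx[:, fam_index]
    truth.family_effects = {f: params.family_sd for f in fam_ids}

    p = expit(eta)
    np.clip(p, 1e-6, 1 - 1e-6, out=p)

    # negative-binomial coverage (gamma-poisson mixture)
    shape = params.coverage_dispersion
    lam = rng.gamma(shape, params.target_coverage / shape, size=(n_sites, n_samples))
    coverage = rng.poisson(lam)

    # beta-binomial methylated counts
    phi = params.dispersion_phi
    conc = (1.0 - phi) / phi
    q = rng.beta(p * conc, (1.0 - p) * conc)
    methylated = rng.binomial(coverage, q)

    matrix = MethylMatrix(
        chrom=chrom,
        pos=pos,
        coverage=coverage,
        methylated=methylated,
        samples=design.sample_ids,
    )
    return matrix, truth


def plant_ct_snps(
    matrix: MethylMatrix,
    design: StudyDesign,
    n_sites: int,
    seed: int = 0,
) -> tuple[MethylMatrix, list[GenomicInterval]]:
    """Overwrite ``n_sites`` CpGs with genotype-driven apparent methylation.

    Emulates segregating C/T polymorphism: within each full-sib family, a
    genotype (CC / CT / TT with the C allele read as "methylated") is drawn
    per sample from the family's parental allele pair, so the planted signal
    is family-correlated rather than treatment-driven.  Returns the modified
    matrix and the 1 bp BED records of planted sites for masking tests.
    """
    if n_sites < 0 or n_sites > matrix.n_sites:
        raise ValueError("n_sites must lie in [0, n_sites of matrix]")
    if n_sites == 0:
        return matrix, []
    rng = np.random.default_rng(seed)
    picks = np.sort(rng.choice(matrix.n_sites, size=n_sites, replace=False))

    cov = matrix.coverage.copy()
    meth = matrix.methylated.copy()
    fam_of = np.array([s.family_id for s in design.samples])
    fams = list(dict.fromkeys(fam_of))
    for i in picks:
        # per-family C-allele frequency; offspring genotype dosage ~ Binomial(2, f)
        fam_freq = {f: rng.beta(0.8, 0.8) for f in fams}
        dosage = np.array(
            [rng.binomial(2, fam_freq[f]) for f in fam_of], dtype=float
        )
        apparent = dosage / 2.0  # TT -> 0, CT -> 0.5, CC -> 1 apparent methylation
        meth[i, :] = rng.binomial(cov[i, :], np.clip(apparent, 0.01, 0.99))

    planted = [
        GenomicInterval(str(matrix.chrom[i]), int(matrix.pos[i]), int(matrix.pos[i]) + 1)
        for i in picks
    ]
    out = MethylMatrix(
        chrom=matrix.chrom,
        pos=matrix.pos,
        coverage=cov,
        methylated=meth,
        samples=matrix.samples,
    )
    return out, planted
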