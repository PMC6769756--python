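"""Synthetic panels with the statistical structure the analysis assumes.

The generative model is deliberately simple but captures every feature the
downstream estimators rely on:

* per-site allele-frequency trajectories under a discrete Wright-Fisher
  model with recessive selection against the deleterious allele
  (``s = -k * phyloP`` at constrained sites, ``h = 0``), an ancestral
  population of constant size and a recent bottleneck emulating the
  collapse of breeding stocks (default: effective size 80 from 250 years
  before present, the census-derived figure for a stud of 20 stallions and
  5000 mares);
* ancient individuals drawn at Hardy-Weinberg proportions from the
  frequency of their epoch; modern individuals drawn with autozygosity:
  a two-state Markov chain along each chromosome switches between
  identical-by-descent (IBD) and outbred segments, with stationary IBD
  probability equal to the breed's target inbreeding coefficient and
  exponentially distributed tract lengths;
* read counts with Poisson depth, uniform sequencing error to the three
  non-template bases, and optional post-mortem C->T / G->A damage applied
  to transition sites only (reduced tenfold when libraries are treated
  with a uracil-excising enzyme mix, as most ancient extracts were);
* an optional "purging" regime in which the allele copied into an IBD
  segment is drawn at a reduced deleterious frequency, emulating selection
  removing recessive variants once exposed as homozygotes inside runs of
  homozygosity.

All randomness flows from a single integer seed through
``numpy.random.default_rng``; outputs are byte-identical across runs.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .datamodel import AlleleCountMatrix, SampleMeta, SiteAnnotation
from . import io as pio

NUCS = np.array(list("ACGT"))

# mean phyloP of the constrained tail per region class, mirroring the
# observed ordering (coding most constrained, intergenic least)
REGION_TAIL_MEAN = {
    "coding": 2.316,
    "upstream2kb": 2.096,
    "downstream2kb": 2.097,
    "intron": 2.0,
    "intergenic": 1.964,
}

DEFAULT_REGION_MIX = {
    "coding": 0.05,
    "upstream2kb": 0.05,
    "downstream2kb": 0.05,
    "intron": 0.35,
    "intergenic": 0.50,
}


@dataclass
class BreedSpec:
    """One synthetic modern breed: sample size, inbreeding target, depth."""

    name: str
    group: str
    n: int
    f_target: float
    depth_mean: float


def default_breeds() -> list:
    """Modern panel: 150 genomes across six breeds spanning the observed
    range of inbreeding, from heavily bottlenecked draft-like breeds to an
    outbred line."""
    return [
        BreedSpec("draft_a", "working", 25, 0.30, 12.0),
        BreedSpec("draft_b", "working", 25, 0.25, 10.0),
        BreedSpec("pony_a", "working", 20, 0.20, 8.0),
        BreedSpec("hot_a", "hotblood", 25, 0.10, 15.0),
        BreedSpec("warm_a", "warmblood", 30, 0.06, 12.0),
        BreedSpec("outbred", "other", 25, 0.02, 20.0),
    ]


@dataclass
class ScenarioParams:
    """Full specification of a synthetic study.

    Defaults encode the "horse-like" scenario: ~3500 years of sampled
    history, a recent bottleneck-driven inbreeding burst, 150 ancient and
    150 modern genomes.
    """

    n_sites: int = 12_000
    constrained_mass: float = 0.85  # fraction of sites with phyloP >= 1.5
    region_mix: dict = field(default_factory=lambda: dict(DEFAULT_REGION_MIX))
    n_chrom: int = 2
    chrom_length_bp: int = 60_000_000

    span_years: float = 4000.0
    generation_time_years: float = 8.0
    ancestral_ne: int = 10_000
    bottleneck_time_years: float = 250.0
    bottleneck_ne: int = 80  # 4*Nm*Nf/(Nm+Nf) for 20 stallions x 5000 mares

    # s = -scale * phyloP, recessive (h = 0).  Segregating load is dominated
    # by *slightly* deleterious variants (strong-effect alleles are purged
    # long before they become standing variation), hence the small scale.
    sel_coeff_scale: float = 5e-4
    # initial-frequency mixture: anciently fixed / rare / intermediate
    p0_fixed_weight: float = 0.11
    p0_rare_weight: float = 0.70
    p0_rare_beta: tuple = (0.5, 30.0)
    p0_mid_range: tuple = (0.02, 0.4)

    # ancient sampling: stratified so every millennium window has
    # comparable support, with a dedicated historical stratum covering the
    # collapse period — the design of a genome time series
    ancient_strata: list = field(
        default_factory=lambda: [
            (50.0, 250.0, 35),
            (250.0, 750.0, 15),
            (750.0, 1750.0, 34),
            (1750.0, 2750.0, 33),
            (2750.0, 3700.0, 33),
        ]
    )
    ancient_depth_range: tuple = (2.0, 20.0)

    breeds: list = field(default_factory=default_breeds)
    mean_roh_length_bp: float = 5_000_000.0
    purging_strength: float = 0.0  # 0 = no purging; 1 = full purging inside IBD

    # counts are modelled as quality-filtered (minQ 30) pileups, so the
    # residual per-base error is ~1e-3; damage is the post-filtering excess
    error_rate: float = 0.001
    damage_rate: float = 0.02
    user_treated: bool = True

    include_outgroup: bool = True
    outgroup_neutral_divergence: float = 0.02
    outgroup_constraint_decay: float = 0.25  # dN reduction: q_s * exp(-decay*phyloP)
    outgroup_depth: float = 30.0

    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.region_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region_mix must sum to 1, got {total}")
        for b in self.breeds:
            if not (0.0 <= b.f_target <= 1.0):
                raise ValueError(f"f_target out of [0,1] for breed {b.name}")
        if not (0.0 <= self.error_rate < 1.0 and 0.0 <= self.damage_rate < 1.0):
            raise ValueError("error and damage rates must lie in [0, 1)")

    @property
    def n_ancient(self) -> int:
        return sum(c for _, _, c in self.ancient_strata)

    @property
    def n_generations(self) -> int:
        return int(round(self.span_years / self.generation_time_years))

    def age_to_generation(self, age_bp: float) -> int:
        """Map an age in years BP to a forward generation index
        (0 = start of the simulation, n_generations = present)."""
        g = self.n_generations - int(round(age_bp / self.generation_time_years))
        return min(max(g, 0), self.n_generations)


@dataclass
class TruthSet:
    """Ground truth emitted alongside a synthetic dataset."""

    freq_by_gen: dict  # generation index -> per-site frequency array
    sample_generation: np.ndarray  # per sample
    dosage: np.ndarray  # per (sample, site) true deleterious-allele copies
    f_true: np.ndarray  # per sample realized IBD fraction (by bp)
    tracts: list  # per sample: list of (chrom, start, end)
    s: np.ndarray  # per-site selection coefficient (<= 0)
    p0: np.ndarray

    def to_json(self, path) -> None:
        payload = {
            "freq_by_gen": {str(k): v.tolist() for k, v in self.freq_by_gen.items()},
            "sample_generation": self.sample_generation.tolist(),
            "dosage": self.dosage.tolist(),
            "f_true": self.f_true.tolist(),
            "tracts": self.tracts,
            "s": self.s.tolist(),
            "p0": self.p0.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# allele-frequency trajectories


def deterministic_recursion(p: np.ndarray, s: np.ndarray) -> np.ndarray:
    """One generation of recessive selection, infinite population size.

    With deleterious-homozygote fitness ``1 - |s|`` and no heterozygote
    effect, the post-selection frequency is
    ``p' = (p^2 (1-|s|) + p(1-p)) / (1 - |s| p^2)``.
    """
    a = np.abs(s)
    num = p * p * (1.0 - a) + p * (1.0 - p)
    return num / (1.0 - a * p * p)


def simulate_frequency_trajectories(
    p0: np.ndarray,
    s: np.ndarray,
    ne_per_generation: Sequence[int],
    rng: np.random.Generator,
    record_generations: Sequence[int] = (),
    deterministic: bool = False,
) -> dict:
    """Forward Wright-Fisher simulation of deleterious-allele frequencies.

    Each generation applies the recessive-selection recursion and then
    binomially resamples ``2*Ne`` allele copies (skipped when
    ``deterministic``).  Frequencies 0 and 1 are absorbing.  Returns a dict
    mapping each requested generation index (plus the final one) to a copy
    of the frequency vector; generation 0 is the initial state.
    """
    p = np.asarray(p0, dtype=float).copy()
    n_gen = len(ne_per_generation)
    record = set(int(g) for g in record_generations) | {n_gen}
    out = {}
    if 0 in record:
        out[0] = p.copy()
    for g, ne in enumerate(ne_per_generation, start=1):
        p = deterministic_recursion(p, s)
        if not deterministic:
            n_copies = 2 * int(ne)
            p = rng.binomial(n_copies, p) / n_copies
        if g in record:
            out[g] = p.copy()
    return out


# ---------------------------------------------------------------------------
# individual genotypes with autozygosity


def _simulate_ibd_segments(length, f_target, mean_tract, rng):
    """Alternating IBD / outbred segments along one chromosome.

    Segment lengths are exponential with mean ``mean_tract`` (IBD) and
    ``mean_tract * (1-F)/F`` (outbred), so the stationary IBD fraction is
    ``f_target``.  Returns a list of (start, end, is_ibd) covering
    [0, length).
    """
    if f_target <= 0.0:
        return [(0.0, length, False)]
    if f_target >= 1.0:
        return [(0.0, length, True)]
    mean_out = mean_tract * (1.0 - f_target) / f_target
    segs = []
    pos = 0.0
    state = bool(rng.random() < f_target)
    while pos < length:
        mean = mean_tract if state else mean_out
        seg = rng.exponential(mean)
        segs.append((pos, min(pos + seg, length), state))
        pos += seg
        state = not state
    return segs


def sample_individual_genotypes(
    freqs: np.ndarray,
    positions: np.ndarray,
    chroms: np.ndarray,
    f_target: float,
    mean_tract_bp: float,
    rng: np.random.Generator,
    chrom_length_bp: float,
    purging_gamma: float = 0.0,
    constrained: Optional[np.ndarray] = None,
):
    """Draw one diploid genome given per-site frequencies and an
    inbreeding target.

    Inside IBD segments a single allele is drawn and duplicated (at a
    purging-reduced frequency for constrained sites when
    ``purging_gamma > 0``); outside, two independent Hardy-Weinberg draws
    are made.  Returns ``(dosage, tracts, f_realized)`` where ``tracts``
    lists IBD segments as (chrom, start, end) and ``f_realized`` is the
    IBD fraction of the genome by length.
    """
    n = len(freqs)
    ibd_state = np.zeros(n, dtype=bool)
    tracts = []
    ibd_bp = 0.0
    total_bp = 0.0
    for chrom in dict.fromkeys(chroms.tolist()):
        mask = chroms == chrom
        segs = _simulate_ibd_segments(chrom_length_bp, f_target, mean_tract_bp, rng)
        total_bp += chrom_length_bp
        pos = positions[mask]
        state = np.zeros(pos.shape, dtype=bool)
        for start, end, is_ibd in segs:
            if is_ibd:
                ibd_bp += end - start
                tracts.append((str(chrom), int(start), int(end)))
                state |= (pos >= start) & (pos < end)
        ibd_state[mask] = state
    p_auto = freqs.copy()
    if purging_gamma > 0.0 and constrained is not None:
        p_auto = np.where(constrained, freqs * (1.0 - purging_gamma), freqs)
    dosage = rng.binomial(2, freqs)
    auto = 2 * rng.binomial(1, p_auto)
    dosage = np.where(ibd_state, auto, dosage).astype(np.int8)
    f_realized = ibd_bp / total_bp if total_bp else 0.0
    return dosage, tracts, f_realized


# ---------------------------------------------------------------------------
# read counts


def simulate_read_counts(
    dosage: np.ndarray,
    depth_mean: np.ndarray,
    error_rate: float,
    damage_rate: float,
    user_treated: bool,
    is_ancient: np.ndarray,
    major: np.ndarray,
    deleterious: np.ndarray,
    rng: np.random.Generator,
):
    """Simulate per-(sample, site) deleterious-allele read counts.

    Depth is Poisson per cell; each read is drawn from the true genotype
    with error ``error_rate`` spread uniformly over the three other bases.
    For ancient samples, cytosine deamination converts C->T (and the
    complementary G->A) with probability ``damage_rate``, reduced tenfold
    under USER treatment; damage therefore only perturbs transition sites.
    """
    dosage = np.asarray(dosage)
    n_samples, n_sites = dosage.shape
    depth_mean = np.broadcast_to(np.asarray(depth_mean, dtype=float)[:, None], dosage.shape)
    d = rng.poisson(depth_mean)

    e = error_rate
    g2 = dosage / 2.0
    p_del = g2 * (1.0 - e) + (1.0 - g2) * (e / 3.0)

    delta = damage_rate * (0.1 if user_treated else 1.0)
    if delta > 0.0:
        damage_product = {"C": "T", "G": "A"}
        gain = np.array(
            [damage_product.get(m) == a for m, a in zip(major, deleterious)]
        )
        loss = np.array(
            [damage_product.get(a) == m for m, a in zip(major, deleterious)]
        )
        anc = np.asarray(is_ancient, dtype=bool)[:, None]
        # major-template reads misread as the deleterious base
        p_del = p_del + anc * gain[None, :] * (1.0 - g2) * (1.0 - e) * delta
        # deleterious-template reads converted to the major base
        p_del = p_del - anc * loss[None, :] * g2 * (1.0 - e) * delta
    r = rng.binomial(d, np.clip(p_del, 0.0, 1.0))
    return r.astype(np.int32), d.astype(np.int32)


# ---------------------------------------------------------------------------
# site panel


def _simulate_sites(params: ScenarioParams, rng: np.random.Generator) -> list:
    n = params.n_sites
    region_names = list(params.region_mix)
    regions = rng.choice(region_names, size=n, p=[params.region_mix[k] for k in region_names])

    is_constrained = rng.random(n) < params.constrained_mass
    phylop = np.empty(n)
    tail_means = np.array([REGION_TAIL_MEAN[r] for r in regions])
    phylop[is_constrained] = 1.5 + rng.exponential(
        tail_means[is_constrained] - 1.5
    )
    # neutral bulk: standard normal truncated below the constraint threshold
    u = rng.random((~is_constrained).sum())
    phylop[~is_constrained] = norm.ppf(u * norm.cdf(1.5))

    major_idx = rng.integers(0, 4, size=n)
    offset = rng.integers(1, 4, size=n)
    del_idx = (major_idx + offset) % 4
    major = NUCS[major_idx]
    deleterious = NUCS[del_idx]

    # deleterious allele is a rare (count 1) or absent member of the
    # 46-species alignment column
    rare_in_column = rng.random(n) < 0.5

    per_chrom = n // params.n_chrom + 1
    sites = []
    pos_by_chrom = {}
    for j in range(n):
        chrom = f"chr{j // per_chrom + 1}"
        pos_by_chrom.setdefault(chrom, []).append(j)
    for chrom, idx in pos_by_chrom.items():
        pos = np.sort(
            rng.choice(params.chrom_length_bp, size=len(idx), replace=False)
        ) + 1
        for k, j in enumerate(idx):
            if rare_in_column[j]:
                cc = {str(major[j]): 45, str(deleterious[j]): 1}
                alleles = ()
            else:
                cc = {str(major[j]): 46}
                alleles = (str(major[j]), str(deleterious[j]))
            sites.append(
                SiteAnnotation.from_fields(
                    chrom,
                    int(pos[k]),
                    str(regions[j]),
                    float(np.round(phylop[j], 4)),
                    cc,
                    alleles,
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


# ---------------------------------------------------------------------------
# full dataset


@dataclass
class SimulatedDataset:
    params: ScenarioParams
    sites: list
    samples: list
    acm: AlleleCountMatrix
    truth: TruthSet
    outgroup_hap: Optional[np.ndarray]  # per-site 0 = major, 1 = deleterious


def simulate_dataset(params: ScenarioParams) -> SimulatedDataset:
    """Run the full generative model and return in-memory objects."""
    rng = np.random.default_rng(params.seed)
    sites = _simulate_sites(params, rng)
    n = len(sites)
    phylop = np.array([s.phylop for s in sites])
    constrained = np.array([s.constrained for s in sites])
    positions = np.array([s.pos for s in sites])
    chroms = np.array([s.chrom for s in sites])
    major = np.array([s.major_allele for s in sites])
    deleterious = np.array(
        [s.deleterious_allele if s.deleterious_allele else "N" for s in sites]
    )

    s_coef = np.where(constrained, -params.sel_coeff_scale * np.maximum(phylop, 0.0), 0.0)
    s_coef = np.clip(s_coef, -0.9, 0.0)

    # initial frequencies
    u = rng.random(n)
    p0 = np.empty(n)
    fixed = u < params.p0_fixed_weight
    rare = (~fixed) & (u < params.p0_fixed_weight + params.p0_rare_weight)
    mid = ~(fixed | rare)
    p0[fixed] = 1.0
    a, b = params.p0_rare_beta
    p0[rare] = rng.beta(a, b, size=rare.sum())
    lo, hi = params.p0_mid_range
    p0[mid] = rng.uniform(lo, hi, size=mid.sum())

    # demographic schedule
    n_gen = params.n_generations
    bneck_gen = params.age_to_generation(params.bottleneck_time_years)
    ne = np.full(n_gen, params.ancestral_ne, dtype=int)
    ne[bneck_gen:] = params.bottleneck_ne

    # sample metadata
    samples = []
    ancient_ages = []
    for lo, hi, count in params.ancient_strata:
        ancient_ages.extend(rng.uniform(lo, hi, size=count))
    dlo, dhi = params.ancient_depth_range
    for i, age in enumerate(sorted(ancient_ages, reverse=True)):
        samples.append(
            SampleMeta(
                sample_id=f"anc{i:03d}",
                breed="ancient",
                group="ancient",
                age_bp=float(np.round(age, 1)),
                mean_depth=float(np.round(rng.uniform(dlo, dhi), 2)),
            )
        )
    for breed in params.breeds:
        for k in range(breed.n):
            samples.append(
                SampleMeta(
                    sample_id=f"{breed.name}_{k:02d}",
                    breed=breed.name,
                    group=breed.group,
                    age_bp=0.0,
                    mean_depth=breed.depth_mean,
                )
            )

    sample_gen = np.array([params.age_to_generation(s.age_bp) for s in samples])
    freq_by_gen = simulate_frequency_trajectories(
        p0, s_coef, ne, rng, record_generations=sorted(set(sample_gen.tolist()))
    )

    # genotypes
    f_by_breed = {b.name: b.f_target for b in params.breeds}
    dosage = np.zeros((len(samples), n), dtype=np.int8)
    f_true = np.zeros(len(samples))
    tracts: list = []
    for i, meta in enumerate(samples):
        freqs = freq_by_gen[sample_gen[i]]
        f_target = 0.0 if meta.is_ancient else f_by_breed.get(meta.breed, 0.0)
        dos, trs, f_real = sample_individual_genotypes(
            freqs,
            positions,
            chroms,
            f_target,
            params.mean_roh_length_bp,
            rng,
            params.chrom_length_bp,
            purging_gamma=params.purging_strength,
            constrained=constrained,
        )
        dosage[i] = dos
        f_true[i] = f_real
        tracts.append(trs)

    is_ancient = np.array([s.is_ancient for s in samples])
    depth_mean = np.array([s.mean_depth for s in samples])
    r, d = simulate_read_counts(
        dosage,
        depth_mean,
        params.error_rate,
        params.damage_rate,
        params.user_treated,
        is_ancient,
        major,
        deleterious,
        rng,
    )
    acm = AlleleCountMatrix(samples=samples, sites=sites, r=r, d=d)

    outgroup_hap = None
    if params.include_outgroup:
        q = np.full(n, params.outgroup_neutral_divergence)
        q = np.where(
            constrained,
            q * np.exp(-params.outgroup_constraint_decay * np.maximum(phylop, 0.0)),
            q,
        )
        outgroup_hap = rng.binomial(1, q).astype(np.int8)

    truth = TruthSet(
        freq_by_gen=freq_by_gen,
        sample_generation=sample_gen,
        dosage=dosage,
        f_true=f_true,
        tracts=tracts,
        s=s_coef,
        p0=p0,
    )
    return SimulatedDataset(
        params=params,
        sites=sites,
        samples=samples,
        acm=acm,
        truth=truth,
        outgroup_hap=outgroup_hap,
    )


def generate_dataset(params: ScenarioParams, outdir) -> SimulatedDataset:
    """Simulate a dataset and write every exchange format to ``outdir``.

    Emits: ``sites.tsv``, ``counts.tsv``, ``metadata.tsv``, ``modern.vcf``
    (true modern genotypes plus the outgroup), ``truth.json`` and
    ``scenario.yaml``.  Deterministic given the scenario seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(params)

    pio.write_site_table(outdir / "sites.tsv", ds.sites)
    pio.write_metadata(outdir / "metadata.tsv", ds.samples)
    pio.write_counts(outdir / "counts.tsv", ds.acm)

    modern_idx = [i for i, s in enumerate(ds.samples) if not s.is_ancient]
    vcf_samples = [ds.samples[i].sample_id for i in modern_idx]
    vcf_dosage = ds.truth.dosage[modern_idx]
    if ds.outgroup_hap is not None:
        vcf_samples = vcf_samples + ["outgroup"]
        vcf_dosage = np.vstack([vcf_dosage, 2 * ds.outgroup_hap])
    pio.write_vcf(outdir / "modern.vcf", vcf_samples, ds.sites, vcf_dosage)

    ds.truth.to_json(outdir / "truth.json")
    scenario = dataclasses.asdict(params)
    scenario["breeds"] = [dataclasses.asdict(b) for b in params.breeds]
    with open(outdir / "scenario.yaml", "w") as fh:
        import yaml

        yaml.safe_dump(scenario, fh, sort_keys=False)
    return ds
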