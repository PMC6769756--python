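# Methods

This note documents the statistical models implemented in `paleoload`, the
generative model behind its synthetic data, the numerical choices made
where the design was genuinely open, and the known limits of what the test
suite demonstrates.

## The mutational-load statistic

For one genome and a set of annotated positions, the load is

    load = ( Σ_i phyloP_i ) / n_hom

where `i` runs over the called-homozygous positions carrying the
deleterious allele with phyloP at or above the constraint threshold
(default 1.5, which discriminates fourfold- from zerofold-degenerate
coding sites), and `n_hom` counts *all* called homozygous positions in the
region set, whether or not they carry a deleterious allele. Masked
positions enter neither term. The denominator choice matters: it makes the
statistic a per-homozygous-site burden, robust to differences in
callable-genome size between samples, and it is the reason the statistic
can *fall* with inbreeding under purging (see below).

The deleterious allele at a site is the less frequent allele in the
multi-species alignment column, or a sample allele absent from a
monomorphic column, and is only assigned when at most two variants
segregate across the column plus the sample; a tie between the two column
alleles leaves it undefined (the site then contributes to denominators but
never to numerators). Constraint is `phyloP >= threshold` — the boundary
value counts as constrained.

## Genotype likelihoods and strict homozygous calling

Reads are modelled with the standard per-read error model: a read matches
its template allele with probability `1 - e` and is each other base with
probability `e/3`; a diploid genotype contributes the even mixture of its
two alleles. Likelihoods are computed for the three genotypes of the
biallelic site and normalised (a flat-prior posterior). A genotype is
called only when it is homozygous *and* its normalised likelihood strictly
exceeds 0.99; heterozygous winners and sub-threshold homozygotes are
masked, because the phenotypic effect of a heterozygous deleterious allele
depends on its unknown dominance. Two consequences worth knowing:

* the threshold is applied to the *normalised* likelihood (the raw-vs-
  normalised reading is ambiguous in the protocol this mirrors; normalised
  is the interpretation implemented and tested);
* at `e = 0` the heterozygote hypothesis retains probability `2^-d` for
  `d` concordant reads, so a call needs at least 8 reads to clear 0.99.
  Zero-depth cells are masked with a `no_data` reason code.

The matrix caller receives only deleterious-allele counts `r` and depths
`d` and treats the `d - r` remaining reads as the major allele; read-level
quality filtering (mapping quality, base quality ≥ 30, proper pairs) is
assumed upstream of the counts input.

## Temporal allele-frequency trajectories

Within a pool of individuals the frequency of a deleterious allele is the
maximiser of `Π_i Binomial(r_i; d_i, p)`, which has the closed form
`Σr / Σd`; the package carries both a bounded scalar optimiser (polished
with two Newton steps on the score, agreeing with the closed form to
1e-9) and the vectorised closed form used in production. Ancient samples
are pooled in sliding 1000-year windows stepped every 250 years, with
half-open membership `[c - 500, c + 500)`; a bin is usable for a site only
when at least 10 individuals have read data there (the per-site reading of
the bin-occupancy rule — stricter than a per-bin global count).

Trajectories over all usable bins plus the modern panel are classified
*fixed* (every estimate ≥ 0.99), *absent* (every estimate < 0.01) or
*dynamic*. Frequency shifts Δ are measured between non-overlapping
1000-year bins centred at 3250, 2250, 1250 and 250 years BP — overlapping
windows share samples and would understate Δ — with the modern panel
entering as its own bin at 0 BP; each Δ is reported at the younger centre.
A transversions-only switch removes transition sites, the standard guard
against post-mortem cytosine-deamination artefacts.

## Drift phylogenetics

Genomes are pseudo-haploidized (one allele per site, drawn proportionally
to read counts; the standard low-coverage ancient-DNA convention), reduced
to nearly-neutral sites (phyloP below threshold, at most one missing call
across the panel), and compared by mismatch fraction over pairwise-shared
sites. The neighbor-joining implementation is the plain Saitou–Nei
algorithm with the usual Q-criterion; ties break to the lowest-index pair
so output is deterministic, and a negative branch length is clamped to
zero with the deficit moved to its sibling. NJ is consistent on additive
matrices and the tests verify *exact* recovery (topology and branch
lengths) against an enumerate-all-topologies least-squares oracle for up
to six taxa. Topology refinement (nearest-neighbour-interchange /
minimum-evolution polishing) is deliberately out of scope: on additive and
near-additive input the plain algorithm already recovers the topology.
Bootstrap support is by site resampling; note that resampling *observed*
noise still leans toward the observed resolution, so "null" supports sit
well above the naive 1/3 for a quartet.

Clade drift is read off as the stem branch length of each named tip set
(substitutions per nearly-neutral site); non-monophyletic sets are
reported missing. Rooting is available both on an outgroup and at the
midpoint — the two are distinct operations and both are exposed.

## Inbreeding: the two-state IBD HMM

Per-genome inbreeding is estimated from heterozygosity indicators at
LD-pruned polymorphic sites. Hidden states are outbred and IBD
(identical-by-descent); emissions are

    P(het | outbred) = 2p(1-p)(1-ε) + (1 - 2p(1-p)) ε
    P(het | IBD)     = ε

with `p` the population allele frequency and `ε` a genotyping-error /
recent-mutation leak. Transitions over a physical gap `g` follow a
reversible exponential kernel with a single rate `r` and stationary IBD
probability `F`:

    P(i→j | g) = π_j (1 - e^{-rg}) + δ_ij e^{-rg},   π = (1-F, F).

Chromosome breaks are treated as infinite gaps (the chain resets to its
stationary law). The triple `(F, r, ε)` is fit by EM: an exact scaled
forward–backward E-step and an M-step that numerically maximises the
expected complete-data log-likelihood over the unconstrained
parameterisation `(logit F, log r, logit ε)` (L-BFGS-B, falling back to
the previous point if the optimiser fails to improve). Because the M-step
never decreases the Q-function, the observed-data likelihood is
non-decreasing across iterations — asserted in the tests. Convergence is
declared when the largest parameter change (absolute for `F` and `ε`,
log-scale for `r`) drops below `em_epsilon` (default 1e-7, the strict
criterion the pipeline standardises on), with an iteration cap as a
safety. The reported `F` is the mean posterior IBD occupancy, which agrees
with the decoded tract coverage (posterior > 0.5, merged runs) to within a
bin or two; the fitted stationary probability is also reported. Recovery
on synthetic data is well within ±0.05 for `F ∈ {0, 0.1, 0.3}` at 10^5
sites.

LD pruning: r² (squared dosage correlation, pairwise-complete) for SNP
pairs closer than 50 Kb on the same chromosome; pairs with r² ≥ 0.2
(configurable — no canonical cutoff exists for this step) become edges;
connected components are blocks; the representative is the maximum-degree
node with ties to the leftmost position. This replaces a Markov-clustering
step with an equivalent, simpler graph clustering. Sites with more than
10% missingness are excluded first.

## The dN − dS purging proxy

For each genome, dN is the mismatch fraction against the outgroup at
constrained sites and dS the same at neutral sites, on pseudo-haploid
calls restricted to sites where both genomes are called. Efficient
negative selection removes derived alleles at constrained sites, so
dN − dS is negative; relaxed selection lets dN approach dS. The helper
`Ne = 4·Nm·Nf/(Nm+Nf)` quantifies why a stud of 20 stallions and 5000
mares drifts like a population of ~80, and ROH tract lengths are reported
on a log2(bp) axis (18 ↔ 262 Kb).

## The synthetic-data generator

The generator emulates the statistical structure of a horse genome
time-series panel; its defaults are the study conditions the tests run
under.

**Sites.** 12 000 positions on two 60-Mb chromosomes; region classes drawn
from {coding 5%, upstream 5%, downstream 5%, intron 35%, intergenic 50%};
phyloP from a truncated-normal neutral bulk (< 1.5) plus, for 85% of
sites, an exponential constrained tail whose per-region means mirror the
observed ordering (coding 2.316 > upstream/downstream ≈ 2.10 > intergenic
1.964). The deleterious allele is a rare (count 1) or absent member of a
46-species alignment column.

**Frequencies.** Discrete Wright–Fisher with recessive selection
(`s = -k·phyloP`, `h = 0`, default `k = 5e-4`): segregating load is
dominated by *slightly* deleterious variants — strong-effect alleles are
purged before they become standing variation. 4000 years at 8 years per
generation; ancestral Ne 10 000 (the domestication bottleneck was mild);
collapse to Ne 80 from 250 years BP, the breeding-stock effective size
implied by the stallion/mare arithmetic above. Initial frequencies are a
mixture: 11% anciently fixed, 70% rare (Beta(0.5, 30)), the rest
intermediate (Uniform(0.02, 0.4)).

**Samples.** 150 ancient genomes on a stratified age schedule (35 in the
historical stratum 50–250 BP, 15 in 250–750, and ~33 per earlier
millennium) — the design of a time-series panel in which museum-era
specimens are well represented — with per-sample depths Uniform(2, 20);
150 modern genomes across six breeds whose inbreeding targets span 0.02 to
0.30. Modern autozygosity is a two-state Markov chain along each
chromosome with stationary probability F and exponential tract lengths
(mean 5 Mb); inside a tract one allele is drawn and duplicated, outside
the draw is Hardy–Weinberg. An optional purging regime draws the
autozygous allele at a reduced deleterious frequency `p(1-γ)` at
constrained sites, emulating selection against homozygotes exposed in
runs of homozygosity.

**Reads.** Poisson depth; per-read error 1e-3 (the counts input represents
quality-filtered, minQ-30 pileups); ancient samples additionally get
C→T/G→A deamination at rate 0.02, reduced tenfold under USER treatment
(the default, as for most ancient extracts), which perturbs transition
sites only. An outgroup haplotype diverges at 2% at neutral sites, with
divergence damped as `e^{-0.25·phyloP}` at constrained sites when
selection operates.

**What the generator does not contain** — and hence what passing tests do
not show about real data: recombination and coalescent structure beyond
the IBD chain, breed-structured allele sharing, reference bias against
non-reference alleles in ancient reads, radiocarbon age uncertainty,
indels, and linked selection. One consequence is quantitative: under pure
drift plus the modern-segregation ascertainment, the fraction of dynamic
variants that *increase* over the most recent interval is a thin majority
(~51%), not the large excess real panels show; reproducing that excess
appears to require exactly the omitted forces (reference bias,
breed-structured discovery), so the end-to-end check asserts the direction
(majority), not a magnitude.

A second qualitative observation: with the all-homozygous-sites
denominator, enabling purging does not merely attenuate the load–F
correlation — it can invert it, because inbreeding keeps inflating the
denominator while purging stalls the numerator. The paired-simulation
check therefore asserts attenuation (ρ with purging < ρ without), which is
robust to the purging strength.

## Problem sizes and determinism

The acceptance script and the end-to-end tests run the full default
scenario (12 000 sites, 300 genomes) and fit the IBD HMM to the first 40
modern genomes at an EM cap of 30 iterations — sizes chosen so a complete
run finishes in about a minute on one core while leaving every direction
check with comfortable statistical margin. All randomness descends from a
single integer seed through `numpy.random.default_rng`; child seeds are
derived with `numpy.random.SeedSequence`, and regenerated datasets are
byte-identical across runs and platforms.
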