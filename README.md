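# paleoload

Deleterious-variant dynamics in genome panels that mix modern and ancient
individuals — built around the horse, where centuries of closed studs,
breed collapses and conservation programs left measurable genomic scars,
but applicable to any diploid panel with conservation scores and
time-stamped samples.

Population collapses and inbreeding expose recessive deleterious alleles
as homozygotes. `paleoload` quantifies that process end to end:

* **Mutational load** per genome: `load = Σᵢ phyloPᵢ / n_hom`, summing the
  conservation (phyloP) scores of called-homozygous deleterious sites and
  normalising by *all* called homozygous sites, per region class
  (coding, 2-kb flanks, intron, intergenic) and genome-wide. Genotypes
  come from a GATK-style read-likelihood model with a strict rule: only
  homozygous calls whose normalised likelihood exceeds 0.99 count;
  everything else is masked.
* **Temporal trajectories** of each deleterious allele from ancient read
  counts: the within-bin frequency is the maximum-likelihood value under
  `f = argmax_p Πᵢ Binomial(rᵢ; dᵢ, p)` (closed form `Σr/Σd`), pooled in
  sliding 1000-year windows stepped every 250 years with at least 10
  genotyped individuals per bin. Trajectories are classified
  fixed / absent / dynamic, and frequency shifts Δ are measured between
  non-overlapping bins (3250, 2250, 1250, 250 years BP and the modern
  panel at 0).
* **Drift phylogenetics**: pseudo-haploid genomes, mismatch distances over
  nearly-neutral sites (phyloP < 1.5, ≤ 1 missing call), a deterministic
  Saitou–Nei neighbor-joining tree with bootstrap supports; internal
  branch lengths (substitutions per nearly-neutral site) flag past
  episodes of drift.
* **Inbreeding and purging**: a two-state hidden Markov model along the
  genome co-estimates the inbreeding coefficient F and
  identical-by-descent tracts from heterozygosity indicators at LD-pruned
  SNPs (EM with distance-scaled transitions, convergence at 1e-7); the
  dN−dS proxy (divergence to an outgroup at constrained vs neutral sites)
  measures how efficiently selection purges exposed variants; and
  `Ne = 4·Nm·Nf/(Nm+Nf)` translates breeding-stock census numbers into
  drift-effective sizes.
* **Synthetic data**: a seeded generator producing the full input stack
  (site table, read counts, VCF, metadata) plus ground truth under a
  Wright–Fisher model with recessive selection, a recent bottleneck,
  modern autozygosity and ancient-DNA read noise — the oracle every
  estimator is tested against.

## Worked example

Simulate the default horse-like scenario (150 ancient genomes over 3500
years, 150 modern genomes across six breeds with inbreeding targets up to
0.30, a collapse to Ne = 80 at 250 years BP) and summarise the deleterious
variants segregating in the modern panel:

```python
from paleoload import simdata, workflows
from paleoload.datamodel import Config

params = simdata.ScenarioParams(seed=0)
ds = simdata.simulate_dataset(params)
metrics = workflows.trajectory_metrics(ds.acm, Config(), params.error_rate)
```

which prints, when formatted:

```
tracked deleterious variants: 4648
  absent    11.8 %
  dynamic   65.8 %
  fixed     22.4 %
pooled modern - ancient frequency difference:
  transition    +2.02 %
  transversion  +1.63 %
median |delta| per interval (years BP):
   2250  0.0321
   1250  0.0338
    250  0.0402
      0  0.0520
increasing at the last interval: 52.6 %
```

Read this as the signature of a recent inbreeding-driven burst: deleterious
alleles are slightly more common in moderns than in ancients (for both
transitions and transversions, so not a DNA-damage artefact), and the
largest per-interval frequency shifts land in the most recent interval —
the last 250 years — with increases in the majority among dynamic
variants. The fixed class (alleles near frequency 1 in every epoch)
predates the sampled window entirely.

The same pipeline is available from the shell:

```sh
paleoload simulate -o run/data --seed 0
paleoload genotype --datadir run/data -o run/genotype --error-rate 0.001
paleoload load     --datadir run/data --callsdir run/genotype -o run/load
paleoload traject  --datadir run/data -o run/traject
paleoload tree     --datadir run/data -o run/tree
paleoload inbreed  --datadir run/data -o run/inbreed --max-samples 40
paleoload report   --rundir run -o run/report
```

Every stage writes TSV outputs plus a JSON manifest (config snapshot,
inputs, seed, version, timestamps). `traject --transversions-only`
repeats the temporal analysis without transition sites.

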