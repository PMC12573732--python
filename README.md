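# aphidqtl

QTL mapping, regional heritability and chemosensory-gene enrichment for
an achiasmatic F2 intercross, modelled on a pea-aphid
(*Acyrthosiphon pisum*) host-race cross.

Pea-aphid host races specialise on different legumes, and because
aphids mate on the plant they accept, the genetics of host-plant
acceptance is central to how these races stay distinct. The package
re-implements the full inference chain such a study needs, on synthetic
crosses with the real design's structure (192 F2 clones, four
chromosomes, female-only recombination because males are achiasmatic,
an X with a hemizygous father):

- **simulate** — founder/F1/F2 genomes, acceptance and survival
  phenotypes with target heritabilities, chemosensory-gene positions;
- **linkage** — marker QC (parentage rule, 1:2:1 distortion filter,
  redundancy collapse), female recombination fractions with closed-form
  ML under male achiasmy, LOD-threshold grouping, marker ordering,
  Haldane maps, HMM-based error-LOD screening;
- **marey** — rearranged-block detection from genetic-vs-physical
  position plots, recombination-suppressed regions, and exact minimum
  inversion (signed-reversal) counts;
- **scan** — hidden-Markov genotype probabilities, a rank
  (Kruskal–Wallis) scan for non-normal acceptance traits, a two-part
  spike model for survival (point mass at "alive through the assay"),
  permutation thresholds, 1.5-LOD intervals,
  PVE = 1 − 10^(−(2/n)·LOD);
- **rhm** — VanRaden relatedness matrices, 20 cM / 10 cM sliding
  windows, REML (Gaussian) and PQL (binomial counts of 4) variance
  components, and the regional-matrix permutation test with a
  95th-percentile suggestive cutoff;
- **power** — analytic F2 QTL detection power from a noncentral
  chi-square, with a Monte-Carlo oracle;
- **regions** — gene–region containment, subset-resampling enrichment,
  Fisher exact category enrichment;
- **pipeline / CLI** — one-configuration orchestration with a master
  seed and per-stage derived seeds.

## Worked example: how much power did the design have?

The study design genotyped 192 F2s at an average marker spacing of
0.8 cM and scanned at α = 0.01. Given the four genome-wide trait
heritabilities, the power to detect a *single* QTL carrying all of a
trait's heritable variation, versus any one of *ten equal-effect* QTL:

```python
from aphidqtl.power import power_table
from aphidqtl.simulate import TRAIT_H2

print(power_table(TRAIT_H2).to_string(index=False))
```

```
             trait    h2  power_single_qtl  power_10_equal_qtl
    acceptance_pea 0.097          0.965096            0.111510
acceptance_alfalfa 0.299          1.000000            0.428124
      survival_pea 0.388          1.000000            0.562856
  survival_alfalfa 0.148          0.998260            0.184758
```

A single QTL would have been found essentially surely for every trait
(0.97–1.00), but if a trait's heritability is spread over ten loci of
equal effect, each one is detected with probability only 0.11–0.56 —
which is why finding no QTL for the pea traits points to a polygenic
architecture rather than absent heritability. The same numbers are
available from the shell:

```sh
aphidqtl power --n 192 --h2 0.097 --spacing 0.8 --alpha 0.01 --json
```

```json
{
 "n": 192, "h2": 0.097, "spacing_cm": 0.8, "alpha": 0.01, "n_qtl": 1,
 "power": 0.9651, "noncentrality": 19.2632, "threshold": 6.6349
}
```

The `noncentrality` is the expected likelihood-ratio statistic at the
marker nearest the QTL, λ = −n·ln(1 − h²(1−2r)²), and `threshold` the
α = 0.01 quantile of the 1-df chi-square it is compared against.

An end-to-end synthetic analysis (simulate → QC → map → Marey → scans
→ RHM → power → enrichment) runs from one seed:

```sh
aphidqtl run --seed 1 --outdir runs/demo
```

writing genotype/phenotype/map files, scan profiles with permutation
thresholds, window-level Vr with cutoffs, and a JSON report that is
byte-identical across runs with the same seed.

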