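# microems

Metacommunity structure and beta diversity for host-associated microbiome
OTU tables — built for the question of how skin bacterial communities vary
across a host's range: do OTUs respond to a shared environmental gradient,
do their ranges clump into compartments (Clementsian structure), turn over
individually (Gleasonian), nest, or exclude one another (checkerboards)?
And does compositional divergence track host population genetics or
geography?

The package provides, over a samples × OTUs count table, a rooted OTU
phylogeny, sample metadata, and an optional pairwise Fst matrix:

- **Preprocessing** (`microems.tables`): relative-abundance filtering
  (default: drop OTUs under 0.005 % of the total read count), rarefaction
  without replacement (default 8,800 reads/sample), 80 %-prevalence core
  microbiome, per-sample richness and Shannon diversity, animal–water
  shared-OTU proportions.
- **Elements of Metacommunity Structure** (`microems.ems`): reciprocal-
  averaging (correspondence analysis) ordination of the incidence matrix;
  coherence (embedded absences), turnover (species replacements on the
  range-filled matrix), and boundary clumping (Morisita's index
  `I_M = T·Σnᵢ(nᵢ−1)/(N(N−1))`), each against the fixed-proportional
  ("r1") null that preserves site richness and fills species by their
  marginal totals (default 99 permutations); structure classification;
  compartment splitting with per-compartment re-analysis; ordination-score
  × covariate correlations.
- **Beta diversity** (`microems.beta`): Jaccard, unweighted/weighted
  UniFrac, PCoA, ANOSIM, one-factor PERMANOVA (Adonis), and Mantel tests
  against Fst and great-circle geographic distance (default 10,000
  permutations).
- **Synthetic studies** (`microems.synthetic`): generators for incidence
  matrices with known Clementsian / Gleasonian / nested / evenly-spaced /
  checkerboard / random structure on a latent gradient, a skewed abundance
  overlay (dominant OTU ≈ 46.5 % relative abundance, 9 core OTUs, long rare
  tail), coalescent OTU trees, study-design metadata (8 river populations
  in 2 genetic demes; 43 animal + 8 water samples), and Fst matrices —
  every downstream stage is validated against this ground truth.
- **Pipeline** (`microems.pipeline`, CLI `microems`): one-command
  orchestration and a self-contained synthetic demo.

Statistical conventions and design rationale are documented in
[docs/methods.md](docs/methods.md).

## Worked example

The `analysis/` scripts run the full study shape on a simulated dataset
(`python analysis/01_simulate_study.py` … `04_beta_diversity.py`); the demo
wraps the same flow in one call:

```sh
microems demo --out demo_out --seed 1
```

or in Python:

```python
from microems import pipeline
report = pipeline.demo("demo_out", seed=1)
```

On the simulated study (51 samples: 43 hellbender-style animal hosts and 8
river-water samples across 8 populations in 2 demes; 2,219 OTUs before
preprocessing, 1,125 after the 0.005 % filter) the analysis prints:

```
full metacommunity:
  coherence: absences 22102 (null 51602.0 +- 329.8, z -89.4, p 0)
  turnover: replacements 33550193 (null 4999155.5 +- 267977.8, z 106.5, p 0)
  boundary clumping: Morisita 2.92 (Monte Carlo null 1.51 +- 0.19, p 0.02)
  classification: clementsian
  ordination score vs elevation: r 0.95 (p 2.91e-22)
  ordination score vs latitude: r -0.96 (p 4.3e-25)
compartment boundary after ordered site 17
compartment 1 (17 hosts):  classification: clementsian
compartment 2 (26 hosts):  classification: clementsian
unweighted_unifrac by population: Adonis R2 0.88 (p 0.001); ANOSIM R 0.86 (p 0.001)
Mantel Fst vs unweighted_unifrac: r 0.64 (p 0.0001)
Mantel geographic distance vs 1-Jaccard: r 0.62 (p 0.0001)
```

Reading this: observed embedded absences (22,102) fall far below the r1
null (51,602 ± 330), so OTU ranges are coherent along one latent gradient;
replacements far exceed the null, so communities turn over along it; and
range boundaries clump (I_M = 2.92 against a random-placement Monte Carlo
null of 1.51 ± 0.19) — together a Clementsian metacommunity. The automatic
compartment split falls exactly at the deme boundary (17 animals vs 26),
both compartments re-classify as Clementsian, ordination scores track the
environmental covariates, and community dissimilarity is structured by
population and correlated with genetic distance — the generating truth of
the simulation, recovered end to end.

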