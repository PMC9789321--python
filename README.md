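# streamgut

Diversity and hierarchical Beta-regression analysis of freshwater
macroinvertebrate gut microbiomes.

Stream insects (mayflies, stoneflies, caddisflies, true flies, beetles,
dragonflies, dobsonflies) host gut bacterial communities whose variation
may be driven by where an insect lives (stream site), what it is
(taxonomy: family, genus) or how it feeds (functional feeding group, FFG:
filtering collectors, gathering collectors, scrapers, predators,
shredders/detritivores). `streamgut` is a pipeline for asking which of
these factors structures gut-microbiome beta diversity, built for 16S ASV
count tables with sample metadata from multi-site field surveys such as the
NEON stream network.

The pipeline covers:

- **Curation** — removal of domain-unassigned and eukaryotic taxa, then of
  samples under 1000 reads; collapse to the family rank; rarefaction to
  1110 reads with 10 replicates (`streamgut.community`).
- **Diversity** — observed richness, bias-corrected Chao1, Shannon (bits),
  evenness, with Kruskal–Wallis group tests; Bray–Curtis distance matrices
  (`streamgut.diversity`).
- **Community tests** — NMDS ordination (Kruskal stress-1), PERMANOVA (with
  an exhaustive-enumeration oracle for small instances), PERMDISP, and a
  per-taxon Kruskal–Wallis indicator screen with Benjamini–Hochberg FDR
  control (`streamgut.multivariate`).
- **The hierarchical model** — a Bayesian Beta regression on pairwise
  Bray–Curtis values (`streamgut.model`):

  ```
  y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi)
  logit(mu_i) = alpha + a_family + a_genus + a_ffg + a_site
  alpha ~ Normal(0, 1);  a_f[l] ~ Normal(0, sigma_f)
  sigma_f ~ Exponential(0.5);  phi ~ Gamma(0.01, 0.01)
  ```

  with partial pooling across the levels of each factor, its own adaptive
  Metropolis-within-Gibbs sampler (split-R̂/ESS diagnostics), WAIC
  comparison of four fixed-factor variants, Bayesian R², variance
  partitioning among the four `sigma_f`, and per-level posterior
  predictions.
- **Synthetic data** — generators with known ground truth that emulate the
  survey design (10 sites, 41 samples, 7 orders, 26 families, 5 FFGs,
  1.2k–100k reads) for end-to-end validation (`streamgut.synthetic`).

See `docs/methods.md` for the modelling choices and their rationale.

## Worked example

Generate a survey-scale synthetic dataset, preprocess it, and partition
beta-diversity variance:

```python
from streamgut import GeneratorConfig, ModelSpec, build_pair_observations, sample_posterior
from streamgut.synthetic import generate_metadata, generate_counts
from streamgut import community, diversity, model

cfg = GeneratorConfig.paper_like(seed=7)      # 10 sites, 41 samples
metadata = generate_metadata(cfg)
table, truth = generate_counts(metadata, cfg)

curated, log = community.curate_table(table, min_reads=1000)
family = community.collapse_to_rank(curated, rank="family")
rr = community.rarefy(family, depth=1110, replicates=10, seed=7)
dms = [diversity.bray_curtis(rep) for rep in rr.replicates]
dm, _ = diversity.aggregate_distance_matrices(dms)

obs = build_pair_observations(dm, metadata)   # 41*40/2 = 820 pairs
draws = sample_posterior(obs, ModelSpec(fixed_factor=None),
                         chains=4, iterations=2000, warmup=1000, seed=7)
vp = model.variance_partition(draws)
for f, s in vp["summary"].items():
    print(f"sigma_{f:<6} {s['mean']:.2f}  95% CI [{s['q2.5']:.2f}, {s['q97.5']:.2f}]")
print("Pr(sigma_ffg largest) =", vp["pr_largest"]["ffg"])
```

prints

```
sigma_family 0.17  95% CI [0.02, 0.38]
sigma_genus  0.15  95% CI [0.01, 0.41]
sigma_ffg    0.30  95% CI [0.14, 0.70]
sigma_site   0.22  95% CI [0.11, 0.41]
Pr(sigma_ffg largest) = 0.54125
```

The generator's FFG effect is the largest by construction, and the model
ranks `sigma_ffg` first — while the wide intervals show how much
uncertainty a 41-sample survey leaves about the variance components.

The package ships the survey's 41-sample metadata table; its summary
reproduces the published breakdown:

```sh
$ streamgut summarize-metadata --metadata src/streamgut/data/neon_table1a.tsv --out summary.json
41 samples; distinct levels: {'site': 10, 'order': 7, 'family': 26, 'ffg': 5, 'genus': 36}
```

A full run (curation through model comparison, with a JSON report) is one
command:

```sh
streamgut fixture --scale small --seed 7 --out-dir fixture
streamgut pipeline --config config.yaml        # paths + settings, see PipelineConfig
```

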