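# pitmud

Microbial biogeography of *Baijiu* fermentation-pit mud, as a tested,
reusable Python pipeline.

Strong-flavor *Baijiu* is brewed by anaerobic solid-state fermentation in
clay-lined pits, and the mud lining those pits hosts the bacterial
community that makes the liquor's signature flavor precursors.  Cellars
stay in continuous use for decades to centuries, which turns each pit
into a natural experiment in community succession: which taxa dominate
at which cellar age, whether communities assemble by chance or by
environmental selection, and how their interaction networks change as
the habitat matures.  `pitmud` implements the statistical toolbox such a
study runs on an OTU table, a rooted phylogeny, a taxonomy and sample
metadata (cellar-age groups Aa–Ad, longitude groups La–Ld):

* **Diversity gradients** — Chao1 / Shannon / Pielou with age-trend
  regression and Tukey HSD group tests; Bray–Curtis and normalized
  weighted UniFrac distances; NMDS ordination; multi-term sequential
  PERMANOVA; within-group dissimilarity trends; group taxon-overlap
  (Venn) partitions.
* **Community assembly** — between-community mean nearest taxon
  distance, abundance weighted,

  βMNTD = ½ [ Σᵢ f<sub>ik</sub> min<sub>j∈m</sub> Δ<sub>ij</sub> +
  Σᵢ f<sub>im</sub> min<sub>j∈k</sub> Δ<sub>ij</sub> ],

  standardized against a taxon-shuffling null into
  βNTI = (βMNTD<sub>obs</sub> − mean βMNTD<sub>null</sub>) / sd(βMNTD<sub>null</sub>).
  βNTI > 2 reads as heterogeneous selection, βNTI < −2 as homogeneous
  selection, |βNTI| ≤ 2 as stochastic assembly; per-age-group fractions
  summarize the balance.
* **Co-occurrence networks** — Spearman screen (|ρ| > 0.7, P < 0.01),
  topology with seeded-Louvain modularity, focal-class edge
  decomposition, robustness under random node removal with secondary
  extinctions, and vulnerability (worst single-node efficiency drop).
* **Age biomarkers** — random-forest regression with repeated
  cross-validation over nested feature subsets, and a from-scratch
  LEfSe (Kruskal–Wallis screen + bootstrapped LDA effect size on a
  log10 scale, threshold 4).
* **Synthetic data** — birth–death phylogenies, Brownian niche traits,
  Dirichlet-multinomial reads, dominant-clade succession, planted
  biomarkers and correlation blocks, all with exposed ground truth, so
  the whole pipeline is testable without any download.

## Worked example

```bash
python examples/03_assembly_processes.py
```

simulates three single-regime scenarios and runs the βNTI partition on
each:

```
neutral_drift:
  mean betaNTI +0.30; stochastic 92%, homogeneous 0%, heterogeneous 7%
homogeneous_selection:
  mean betaNTI -2.63; stochastic 17%, homogeneous 83%, heterogeneous 0%
heterogeneous_selection:
  mean betaNTI +4.82; stochastic 33%, homogeneous 5%, heterogeneous 62%
```

Each scenario's dominant recovered class matches the process that
generated it: drift leaves phylogenetic turnover at chance level,
a shared environmental optimum pulls communities closer together than
chance (βNTI < −2), and divergent optima push them further apart
(βNTI > 2).

`examples/02_diversity_gradient.py` runs the diversity stage on the
default succession scenario; its PERMANOVA table

```
           term  sum_of_squares  df  pseudo_F  r2_fraction  p_value
      age_group          0.9665   3   33.8822       0.6972    0.001
longitude_group          0.0300   3    1.0512       0.0216    0.370
```

shows cellar age explaining far more community variation than
production region, and the within-group Bray–Curtis medians fall from
0.81 (youngest) to 0.50 (oldest) — communities converge as cellars age.
The other examples cover simulation and ground truth (`01`),
co-occurrence networks and stability (`04`), and biomarker discovery
(`05`).  A thin CLI mirrors the library
(`pitmud simulate | diversity | assembly | network | biomarkers |
pipeline`); `pitmud pipeline --config run.toml` executes all stages from
a TOML file and writes a manifest of every artifact.

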