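# tebodymap

Transposable-element (TE) expression analysis across organs, developmental
stages and sexes.

Mammalian genomes are pervaded by TEs — SINEs, LINEs, LTR elements and DNA
transposons — whose subfamilies are transcribed in strongly organ-, age-
and sex-dependent ways and can influence the expression of nearby genes.
`tebodymap` is a tested, reusable implementation of the downstream analysis
of a rat body-map style survey: 11 organs x 4 developmental stages
(2, 6, 21, 104 weeks) x both sexes (testis male-only, uterus female-only)
x 4 biological replicates = 320 RNA-seq samples, quantified as RPKM per TE
subfamily, per TE instance and per gene. It is aimed at transcriptomics
researchers who want the paper-style TE statistics as composable library
functions rather than one-off scripts.

The pipeline starts at RPKM matrices (quantification is upstream) and
provides:

* **Genomic compartments** — every TE instance is assigned to CDS exon >
  UTR exon > intron > intergenic, requiring a single feature to cover >= 50%
  of the TE (`bedtools intersect -f` semantics), with per-class summaries.
* **Expression classes** — a subfamily is *expressed* in a group when its
  mean RPKM >= 1; over the 80 (organ, stage, sex) groups this yields the
  commonly / zero / organ-specific / group-specific expressed taxonomy,
  plus pairwise replicate-reproducibility PCCs.
* **Differential calling** — DETE = fold change >= 2 (or <= 0.5) *and*
  Bonferroni-corrected t-test p <= 0.05 on log2(RPKM+1); derived callers
  for organ-enriched subfamilies (over vs *every* other organ),
  development-dependent sets, male-vs-female effects per (organ, stage)
  cell, and the 27-pattern temporal taxonomy (U/M/D per adjacent-stage
  transition, older stage as numerator).
* **Variance structure** — principal variance component analysis (PVCA)
  attributing expression variance to organ, age, sex, replicate and their
  interactions, and average-linkage sample clustering scored against organ
  labels.
* **Gene-TE links** — nearest gene by TSS-to-midpoint distance with a
  strand-aware upstream/downstream side, expression correlation per pair
  over group-mean profiles, empirical-null background/random pair sets, a
  from-scratch (oracle-validated) Hartigan dip test for bimodality of the
  correlation distribution, and distance-independence checks.
* **Synthetic data** — a seeded generator that emulates the 320-sample
  design with planted, recoverable structure (organ-dominant variance,
  enriched / sex-dependent / temporally patterned subfamilies, gene-TE
  pairs at target correlations in chosen compartments and distance strata),
  so every stage is testable without any download.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

```python
from tebodymap import (default_config, simulate_dataset, classify_expression,
                       pvca, cluster_samples, organ_enriched)

ds = simulate_dataset(default_config(seed=1))   # 320 samples, planted truth

classes = classify_expression(ds.subfamily_matrix)
print(classes.counts().to_string())

enriched = organ_enriched(ds.subfamily_matrix, stage=6)
print({organ: sorted(subs) for organ, subs in enriched.items() if subs})

result = pvca(ds.subfamily_matrix)
print(result.proportions.round(3).to_string())

print(f"clustering ARI vs organ labels: {cluster_samples(ds.subfamily_matrix).ari:.2f}")
```

prints

```
label
common            150
zero               40
organ_specific      5
group_specific      3
other               2
{'Ad': ['ERVK_12'], 'Br': ['ERVL_12'], 'He': ['ERV1_13'], 'Ki': ['ERVK_13'],
 'Li': ['hAT_2'], 'Lu': ['TcMar_2'], 'Mu': ['hAT_3'], 'Sp': ['L1_5'],
 'Th': ['L2_5'], 'Te': ['ERV1_18', 'ERVK_17', 'ERVK_18', 'ERVL_17', 'ERVL_18', 'L1_6']}
organ        0.914
age          0.000
sex          0.005
replicate    0.000
organ:age    0.001
organ:sex    0.066
age:sex      0.000
residual     0.014
clustering ARI vs organ labels: 1.00
```

Reading this: of 200 simulated subfamilies, the 40 planted silent ones are
recovered as *zero expressed* and the high-baseline majority as *commonly
expressed*; the 5 testis-only and 3 single-group subfamilies surface as
organ-/group-specific. The enrichment caller finds the ten planted fold-8
subfamilies, one per organ, plus the testis-only subfamilies — which really
are testis-enriched by construction. PVCA attributes 91% of expression
variance to organ (age, sex and replicate are negligible), and clustering
the 320 samples at k = 11 reproduces the organ labels exactly — the
organ-dominant structure the generator plants.

A CLI mirrors the library
(`tebodymap simulate|compartments|classify|dete|enriched|patterns|sexdiff|pvca|cluster|link|pairstats|run-all`);
`tebodymap run-all --seed 1 --out-dir out/` writes every stage artifact
plus a `summary.yaml`.

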