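# stressregulon

Replicate-free transcriptome evaluation of oxidative-stress regulons in
*Aspergillus nidulans*, comparing a control strain with a ΔatfA
transcription-factor deletion mutant across three oxidative stressors
(menadione sodium bisulfite, *t*-butylhydroperoxide and diamide).

## Who this is for

Experiments of this design pool biological replicates onto a single
one-color microarray per strain × condition, so there is no within-condition
variance to feed a t-test or limma.  `stressregulon` implements the
evaluation pipeline such data require, end to end:

1. **D1 differential-expression calling** (`stressregulon.de`).  For a
   treated-vs-untreated contrast with per-gene difference
   `d_g = x_treated,g − x_untreated,g`, the J5-family statistic

   ```
   d1_g = d_g / ( (1/N) Σ_j |d_j| )
   ```

   normalizes each gene's difference by the genome-wide mean absolute
   difference over the N background genes.  A gene is called up when
   `d1 ≥ 3` and down when `d1 ≤ −3` (boundary inclusive).  Expression
   ratios are reported as `log2 R` with `R = SI_treated / SI_untreated`.

2. **Regulon set classification** (`stressregulon.classify`):
   *coregulated* genes (unidirectional response under all three stresses),
   *uniquely regulated* genes (responsive under exactly one stress),
   *AtfA-dependent* genes (regulated in the control, unregulated or
   oppositely regulated in the mutant), three-set Venn partitions, and a
   transition taxonomy for genes whose (stress, direction) signature changes
   between strains (lost/gained responsiveness, gained dependence on another
   stress, lost/gained coregulation).

3. **Gene-group enrichment** (`stressregulon.enrichment`): GO gene groups
   with transitive `is_a`/`part_of` annotation propagation, flat FunCat
   groups, curated ID lists, and one-sided over-representation
   (hypergeometric upper tail) of selected gene lists against the
   post-revision chip background, with Benjamini–Hochberg-adjusted p-values
   reported alongside raw ones.

4. **Validation statistics** (`stressregulon.validation`): ΔΔCP relative
   quantification against the *actA* (AN6542) reference gene, one- and
   two-sample Student t-tests from either raw replicates or printed
   mean ± SD summaries, and microarray/qPCR Pearson correlation.  Two small
   published validation panels (a 35-gene qPCR ΔΔCP panel and an
   enzyme-activity/sterol panel) ship with the package
   (`stressregulon.datasets`).

5. **Synthetic data with planted truth** (`stressregulon.simulate`):
   log-normal baseline intensities, planted up/down regulation per stress
   with configurable effect sizes and cross-stress overlap, configurable
   AtfA dependence (erased or sign-flipped mutant response), and matching
   qPCR crossing-point tables — every downstream stage is testable against
   an exact `TruthTable` oracle.

## Worked example

Count upregulated iron-sulfur-cluster-assembly genes per strain and stress
on the packaged qPCR panel (significant positive ΔΔCP):

```python
from stressregulon import count_group_calls
from stressregulon.datasets import load_qpcr_panel, load_curated_groups
from stressregulon.validation import calls_from_qpcr_summary

profiles = calls_from_qpcr_summary(load_qpcr_panel())
fes = set(load_curated_groups()["iron_sulfur"]["genes"])
for strain in ("control", "atfa"):
    print(strain, [count_group_calls(profiles, fes, strain, s, "up")
                   for s in ("MSB", "tBOOH", "diamide")])
```

prints

```
control [11, 11, 9]
atfa [5, 8, 8]
```

— all 11 panel genes are induced by MSB in the control strain but only 5
remain induced in the ΔatfA mutant, the hallmark of AtfA-dependent
regulation, while the tBOOH and diamide responses are largely AtfA
independent.  A full synthetic round trip:

```python
from stressregulon import SimulationConfig, generate_dataset, de_table, \
    profile_table, classify

cfg = SimulationConfig(n_genes=3000, noise_log2_sd=0.0, effect_log2fc_sd=0.0,
                       seed=17)
matrix, design, truth = generate_dataset(cfg)
table = de_table(matrix, design, scale="log2")
res = classify(profile_table(table))
print("responsive calls:", (table["call"] != "none").sum())
print("AtfA-dependent up per stress:",
      {s: len(g) for s, g in res.atfa_dependent_up.items()})
```

prints

```
responsive calls: 1370
AtfA-dependent up per stress: {'MSB': 68, 'diamide': 79, 'tBOOH': 82}
```

and at zero noise these detected sets equal the planted ones exactly.

The same stages are available from a shell via the `stressregulon` CLI
(`simulate`, `de-call`, `classify`, `enrich`, `qpcr`, `report`); every
subcommand writes TSV products plus a JSON run summary.

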