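# snpmeta

Case-control genotype meta-analysis for a biallelic SNP. From per-study
GG/GA/AA counts (or printed genotype proportions plus sample sizes),
`snpmeta` computes per-study odds ratios under four genetic contrasts
(AA vs GG, GA vs GG, dominant AA+GA vs GG, recessive AA vs GA+GG),
checks Hardy-Weinberg equilibrium in controls, pools with either the
Mantel-Haenszel fixed-effects estimator (Robins-Breslow-Greenland CI)
or DerSimonian-Laird random effects — chosen per analysis by the
Cochran Q-test rule (fixed iff Q p-value > 0.05) — and runs stratified,
publication-bias (Egger, Begg), and leave-one-out sensitivity analyses.

A seven-study glioma case-control collection ships as a bundled fixture
(counts reconstructed from published sample sizes and genotype
proportions), and a simulation module generates collections with known
truth for calibration testing.

## Library use

```python
import snpmeta as sm

studies = sm.bundled_fixture()                 # or sm.parse_study_table("my.csv")
res = sm.select_and_pool(studies, sm.GeneticModel.AA_VS_GG)
print(res.or_pooled, res.ci_low, res.ci_high, res.method)

for r in sm.stratified_analysis(studies, "ethnicity", sm.GeneticModel.DOMINANT):
    print(r.stratum_label, r.or_pooled)

effects = sm.collection_effects(studies, sm.GeneticModel.DOMINANT)
print(sm.egger_test(effects).t_statistic)
```

Input tables are CSV/TSV with columns
`study,year,ethnicity,source,n_case,n_control` followed by either
count columns (`case_GG,case_GA,case_AA,ctrl_GG,ctrl_GA,ctrl_AA`) or
frequency columns (`case_fGG,...,ctrl_fAA`); frequency rows are
reconstructed to integer counts summing exactly to the declared sample
size.

## CLI

```bash
# full analysis of the bundled fixture (or any study table)
snpmeta analyze --input fixture --out report/
snpmeta analyze --input my_studies.csv --models dom,rec --stratify ethnicity --out report/

# simulation calibration study from a JSON config
snpmeta simulate --config sim.json --out simout/
```

`analyze` writes per-study effects, an HWE QC table, pooled results
(one row per stratum x model with the selected method and Q p-value),
Egger/Begg results, leave-one-out tables, funnel-plot data, and a
`summary.json`. Run with `snpmeta --log-level INFO analyze ...` to see
each model-selection decision.

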