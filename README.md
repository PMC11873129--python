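# comethnet

DNA co-methylation network analysis for post-mortem brain cohorts, aimed
at researchers relating regional methylation signatures to
neuropsychiatric traits in neurodegenerative disease. The package builds
weighted co-methylation networks per brain region, associates module
eigengenes with binary clinical traits, tests the cell-type specificity of
a trait-associated module's genes against a single-nucleus expression
reference, and asks whether polygenic risk scores refined to the module's
genomic neighbourhood sharpen prediction of depression onset. A
synthetic-data generator with planted ground truth supplies every input,
so the whole analysis is reproducible and testable end to end.

## The method

Per region, probes variable in every region (MAD above the median probe
MAD) are residualised on age, sex, batch, neuronal proportion and
post-mortem interval. An unsigned weighted network is built with
adjacency `a_ij = |cor(x_i, x_j)|^β` (β chosen by scale-free fit),
topological overlap

    TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),

as similarity, average-linkage clustering of 1 − TOM, and a simplified
dynamic cut (minimum module size 100). Each module is summarised by its
eigengene — the first principal-component sample score — which is tested
against each binary trait with Spearman correlation under a per-region
Bonferroni threshold of 0.05 / #modules.

For a significant module, the annotated genes are tested for cell-type
enrichment with an expression-weighted bootstrap (EWCE): the observed
mean specificity of the module genes in each cell type is compared with
random same-sized gene sets, reported as standard deviations from the
bootstrap mean with BH-corrected q-values, plus a conditional variant
that matches null sets on a controlled cell type's specificity profile.
Finally, GWAS summary statistics are clumped (r² > 0.1 within 1000 kb)
and scored at nine p-value thresholds, both genome-wide (base) and
restricted to ±1 Mb windows around the module's CpG sites (refined);
incremental R² for depression status is FDR-corrected across all 18
tests, and conversion to depression (GDS ≥ 5, confirmed at two visits) is
modelled with a counting-process Cox model (sex fixed; age and UPDRS-III
time-dependent) and Kaplan-Meier strata of polygenic risk.

## Worked example

```python
from comethnet import SimConfig, simulate_methylation_study
from comethnet.preprocess import mad_variable_probes, residualize_covariates
from comethnet.network import soft_threshold_scan, detect_modules, module_eigengenes
from comethnet.association import module_trait_correlations
from comethnet.stats import format_p_threshold

cfg = SimConfig(n_samples=80, seed=1)           # planted 3-module study
study = simulate_methylation_study(cfg)
kept = mad_variable_probes(study.betas.values())
beta = study.betas["SN"].loc[sorted(kept)]
res = residualize_covariates(beta, study.meta[study.meta.region == "SN"],
                             ["age", "sex", "batch", "neun_prop", "pmi"])
scan = soft_threshold_scan(res)
modules = detect_modules(res, scan.selected_power, min_size=100)
me = module_eigengenes(res, modules)
assoc = module_trait_correlations(me, study.traits.set_index("sample"),
                                  {"depression": "binary"})
print(f"variable probes shared across regions: {len(kept)}")
print(f"soft power: {scan.selected_power}; modules: {len(modules.modules)} "
      f"(Bonferroni p < {format_p_threshold(assoc.bonferroni)})")
print(assoc.table[["module", "coefficient", "p", "significant"]])
```

prints

```
variable probes shared across regions: 752
soft power: 5; modules: 3 (Bonferroni p < 0.017)
   module  coefficient        p  significant
     blue        0.139    0.217        False
turquoise        0.524 6.13e-07         True
    brown       0.0694     0.54        False
```

The MAD filter kept 752 of 2000 probes (the planted module probes plus a
noise minority), detection found the three planted modules, and exactly
one eigengene — the turquoise module, which carries the planted
depression link — is Bonferroni-significant for depression (Spearman
ρ = 0.52). Against the planted labels this partition has an adjusted Rand
index of 0.96.

The same workflow runs from the shell:

```bash
comethnet run-all --outdir run --seed 1        # simulate → … → PRS + report
comethnet simulate --outdir data --seed 1      # just the fixture bundle
```

`run/report.md` then contains per-region module counts and thresholds,
the module-trait table, enrichment tables, the PRS association grid and
the Cox/Kaplan-Meier summaries, with the full configuration echoed for
provenance.

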