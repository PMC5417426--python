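# castkit

Allele-specific qPCR mutation calling and analytical-validation toolkit.

`castkit` is for laboratory scientists and biostatisticians who run or
validate competitive allele-specific TaqMan PCR (castPCR-style) mutation
assays — e.g. screening FFPE tumor DNA for a low-prevalence hotspot mutation
such as *AKT1* E17K — and who need the desk side of an analytical validation
to be reproducible: plate interpretation, threshold derivation, limit of
blank, cross-method concordance, and reference-standard design.  A synthetic
data module emulates qPCR and digital-PCR measurements so every stage can be
exercised, end to end, without instrument data.

## The model in brief

A sample is measured by two reactions: a mutant-allele assay (wild-type
amplification suppressed by an MGB blocker) and a gene-reference assay in the
same gene.  The decision statistic is

```
dCt = Ct(mutant assay) − Ct(reference assay) ≈ log2(1/MAF) + δ
```

where MAF is the mutant allele fraction and δ a fixed assay offset.  A sample
is called *mutation detected* when `dCt < 8.1` (with an evaluable mutant Ct
≤ 37 and reference Ct in `[18, 30]`); calls in the confirmation band
`7 ≤ dCt < 8.1` are repeated in duplicate and confirmed only if **both**
duplicates re-detect.  Plate-level no-template controls with signal before
cycle 30 void the plate.  Every constant is a `RuleSet` parameter.

Validation statistics follow standard assay-validation practice: replicate
level summaries (n−1 SD, censored runs excluded), detection cut-off =
`min |dCt|` over wild-type observations minus a guard, parametric limit of
blank `LoB = mean + 1.645·SD`, overall/positive/negative percent agreement,
and OLS regression of paired MAF measurements (R² = squared Pearson r).

## Worked example

```python
import numpy as np
import castkit as ck

# 1. interpret one sample: reference Ct 23.5, mutant Ct 27.5
call = ck.classify_sample(ct_reference=23.5, ct_mutant=27.5,
                          ipc_ct_mutant=24.0, ipc_ct_reference=24.0)
print(call.delta_ct, call.state.value)
# 4.0 mutation_detected

# 2. replicate summaries of the bundled reference-standard run table
runs = ck.load_reference_standard_runs()
ffpe_1pct = next(r for r in runs
                 if r.material is ck.Material.FFPE and r.level_maf == 0.01)
s = ck.summarize_level(ffpe_1pct)
print(s.n_present, s.n_absent, round(s.mean_delta_ct, 2), round(s.sd_delta_ct, 2))
# 6 5 -6.68 2.32          (absent runs are censored, never imputed)

# 3. cross-method regression on the bundled digital-PCR MAF table
pairs = ck.pair_replicates_to_level(ck.load_ctdna_maf_table())
print(len(pairs), round(ck.regress_maf(pairs).r_squared, 4))
# 18 0.9655

# 4. design a 5% MAF standard from a heterozygous line at 2e5 copies/mL
recipe = ck.design_admixture(0.05, 2e5)
print(recipe.fraction_mutant_line_genomes,
      recipe.mass_mutant_line_per_ml / 1000, recipe.mass_wildtype_per_ml / 1000)
# 0.1 66.0 594.0           (genome fraction, ng/mL mutant line, ng/mL wild type)

# 5. simulate a 195-sample FFPE screening cohort and recover the truth
rng = np.random.default_rng(31)
plates, truth = ck.simulate_cohort(195, prevalence=0.031, material=ck.Material.FFPE,
                                   params=ck.QpcrSimParams(), rng=rng,
                                   maf_range=(0.1, 0.5))
detected = {c.sample_id for p in plates for c in ck.call_plate(p)[0]
            if c.state is ck.CallState.MUTATION_DETECTED}
print(detected == {sid for sid, maf in truth.items() if maf > 0})
# True
```

The same operations are available from the shell:

```
castkit call --plate plate.csv --rules rules.yaml --out calls.json
castkit calibrate --runs reference_runs.csv --guard 0
castkit lob --blanks blanks.csv --confidence 0.95
castkit concord --a calls_a.csv --b calls_b.csv
castkit regress --maf-table maf_table.csv
castkit design-standard --maf 0.05 --copies-per-ml 2e5
castkit design-spike --levels 0.0005,0.005,0.01,0.02,0.05 --target 6e4
castkit simulate --kind cohort --seed 1 --out sim/
```

`castkit call` optionally emits a VCF (`--vcf out.vcf --vcf-config site.yaml`)
with the variant site taken from the config, one record per detected sample.

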