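# figgkin

Kinship-inference evaluation toolkit for forensic investigative genetic
genealogy (FIGG).  Crime-scene samples are routinely low-quality: fewer usable
SNPs and more genotyping errors than the dense, clean microarray data that
relative-matching methods were built for.  `figgkin` provides a controlled
test bench for that regime: it simulates extended families on a genetic map,
injects genotyping errors of the three canonical types, estimates pairwise
kinship with four approaches, classifies relationship degrees, and fuses the
estimators into a combination model that stays usable at error rates where
the individual methods break down.

## The methods

For a pair of individuals, let L(IBD1) and L(IBD2) be the summed genetic
lengths (cM) of detected segments where the pair shares one or both
haplotypes identically by descent, and L(genome) the total autosomal map
length.  The Cotterman coefficients and kinship coefficient are

    κ1 = L(IBD1)/L(genome),  κ2 = L(IBD2)/L(genome),  κ0 = 1 − κ1 − κ2
    θ  = κ2/2 + κ1/4

Four estimators of θ are implemented from scratch:

| estimator | type | detection rule | key thresholds |
|---|---|---|---|
| `king_theta` | method of moments | genome-wide IBS counts: θ = (N_het,het − 2·N_opp) / (N_het^a + N_het^b) | — |
| `ibis_segments` | phase-free IBD runs | maximal opposite-homozygote-free marker runs | ≥ 2 cM and ≥ 186 markers; θ gets a +0.00138 constant |
| `truffle_segments` | phase-free IBD1/IBD2 | IBS runs passing a chance-match probability bound | P_chance < 10⁻⁸; ≥ 5 Mb (IBD1), ≥ 2 Mb (IBD2) |
| `germline_segments` | phased IBD | exact haplotype matches, word-seeded | ≥ 3 cM; 64-marker seed words |

Degrees are called from θ by the halving ladder of thresholds
[1/2^((2k+3)/2)): θ ≥ 1/2^1.5 is a twin/same-individual call, then first
(expected θ = 1/4) through seventh degree (1/256), and unrelated below
1/2^8.5.  Performance is scored by sensitivity, PPV, accuracy, and the
overlapping rate against reference ranges learned on an error-free reference
panel.

The combination model expands the four estimates into 13 features (the four
θ values, six pairwise differences θΔ(A,B) = θA − θB, and three ratios
θ(A/IBIS) — IBIS is the only estimator bounded away from zero) and predicts
the *expected kinship coefficient* (the four-method mean at zero error) by
stepwise multiple linear regression with 10-fold cross-validation
(`StepwiseThetaRegressor`, a scikit-learn regressor).  The published models
M1–M7 ship as bundled constants (`BUNDLED_MODELS`); M7, using all four
tools, is the default fused estimator.

## Worked example

```python
import figgkin as fk

gmap = fk.generate_map(22, 400.0, 1e6)                      # 22 autosomes, 400 cM
panel, founders = fk.generate_founders(208, 20_000, gmap, seed=1)
fam = fk.simulate_family(fk.template_pedigree(), panel, founders, gmap, seed=2)

est = fk.estimate_all(
    fam.genotypes_of("F1"), fam.genotypes_of("A1"),        # a parent-offspring pair
    panel, gmap.total_cm,
    fam.haplotypes_of("F1"), fam.haplotypes_of("A1"),
)
print(est.as_dict())
print(fk.classify_degree(est.theta_king))
```

prints

```
{'theta_king': 0.251012423639234, 'theta_ibis': 0.2509216293765308,
 'theta_truffle': 0.2495416293765308, 'theta_germline': 0.2495416293765308}
1st
```

— all four estimators recover the parent–offspring kinship of 1/4 (the IBIS
value carries its +0.00138 constant), and the threshold classifier calls the
pair first-degree.  `run_panel_grid` and `run_error_grid` (or the
`figgkin` CLI: `simulate`, `panel-grid`, `error-grid`, `fit-combo`,
`infer`, `report`) sweep the panel-size ladder and the error ladder
{0, 0.1, 0.5, 1, 5, 10}% and emit per-method metric tables;
`real_data_entry` runs the same estimators on paired reference/query VCFs
after MAF and Hardy–Weinberg filtering.

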