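# epijack

Case-only gene–gene interaction tests for SNP pairs, including pairs where
one or both markers are **untyped** and only marginal imputation posteriors
are available — with a delete-1 jackknife variance estimator that properly
propagates imputation uncertainty into the test.

## The problem

Detecting epistasis between two unlinked loci G and H from cases alone is
more powerful than case-control logistic regression, but it requires a test
built on the case genotype distribution. The interaction parameter is the
vector of four local log odds ratios of the 3×3 joint genotype table,

    β_lm = log( p_lm p_{l+1,m+1} / (p_{l,m+1} p_{l+1,m}) ),   l, m ∈ {0, 1},

with β = 0 exactly under multiplicative penetrances ("no interaction").
Two tests are provided:

* **WTT** — the Wald-type statistic β̂ᵀV̂⁻¹β̂ against χ²₄;
* **WTT_c** — the same statistic minus the squared V̂⁻¹-distance from β̂ to
  the sign-constraint cone {β ≥ 0} ∪ {β ≤ 0} (which contains every classical
  dominant/recessive epistasis archetype), against a Monte Carlo
  chi-bar-square mixture Σ w_l P(χ²_l ≥ t). The constraint buys power.

For untyped markers, β̂ is computed from expected counts — products of the
marginal imputation posteriors, valid under the null — and the crucial
ingredient is V̂: plugging expected counts into the usual multinomial
variance (the "dosage-as-observed" shortcut) overestimates the variance and
makes the test badly conservative. `epijack` instead estimates V̂ by a
delete-1 jackknife over individuals, which is valid whenever imputation of
one individual does not depend on the others (reference-panel-based
imputation, e.g. IMPUTE-style output) and stays consistent even when the
imputation is nearly uninformative. A grouping shortcut makes the jackknife
O(#distinct posterior rows), not O(n).

The package also ships a two-locus penetrance simulator (six
union/intersection dominant×recessive models plus the multiplicative null),
a single-tag-SNP imputation emulator with tunable information content and
reference-panel noise, and a study harness that reruns the full size/power
design. See `docs/methods.md` for the model, approximations and defaults.

## Worked example

Simulate 5000 cases under recessive∩recessive epistasis (f = 0.02,
g = 0.01, so β = (0, 0, 0, log 2)), emulate imputation of both markers, and
test the pair:

```sh
epijack simulate --model RnR --f 0.02 --g 0.01 --n 5000 --seed 7 \
        --out-prefix demo
epijack test --gen-g demo_G.gen --gen-h demo_H.gen \
        --method wtt --method wttc --method naive --seed 1
```

```text
method	statistic	pvalue	variance	reference	weights
WTT	6.270855652950711	0.17981314714711888	jackknife	chi2_4	
WTT_c	6.089688185760562	0.09308497840152231	jackknife	chibar[two-sided]	0.00000,0.64525,0.71895,0.35275,0.06350
naive_dosage_WTT	3.460618788543632	0.48389155356123803	naive_dosage	chi2_4	
```

The constrained statistic is slightly below the unconstrained one (β̂ is
nearly, not exactly, sign-coherent) but its sharper reference distribution
roughly halves the p-value; the naive dosage test, with its inflated
variance, sees much weaker evidence on the same data. On the true genotypes
(`epijack test --calls demo_truth.tsv --method wtt --method wttc`) the same
pair gives truth_WTT = 31.40 (p = 2.5e-06): the imputation regime here
(dosage r² ≈ 0.90 and 0.76 at the two markers) costs real information, and
a single pair at n = 5000 with β₁₁ = log 2 sits near the detection
boundary — power differences between the arms are what the study harness
quantifies.

```sh
epijack study --config study.yaml --out study.tsv   # size/power experiments
```

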