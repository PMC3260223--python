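# epiforest

Detection of **epistatic SNP interactions** in case-control association
panels with a modified random forest.

Complex-disease loci can act purely through interactions: each locus alone
shows no marginal association, so single-SNP tests — and ordinary random
forests, whose nodes split on one variable at a time — miss them entirely.
`epiforest` addresses this with two changes to the random-forest framework:

1. **Multi-locus node splits.** At every tree node, candidate split
   variables are drawn from the union of all single SNPs and all unordered
   SNP pairs. A pair variable takes 3² = 9 genotype-cell values and its
   split is chosen among the 2⁸ − 1 = 255 bipartitions of those cells by
   maximal Gini decrease Δφ = φ(γ) − f_l φ(γ_l) − f_r φ(γ_r), with
   φ = 1 − f₀² − f₁². Purely epistatic pairs therefore compete at nodes on
   their *joint* signal.
2. **Branch co-occurrence interaction scores.** A combination G of SNPs
   that genuinely interacts keeps appearing together on root-to-leaf
   branches. Its count inter(G) over the forest is normalized against a
   topology- and usage-preserving label-randomization null:
   INTER(G) = (inter(G) − mean_random(G)) / sd_random(G), and combinations
   with INTER > 25σ are called — no per-test p-values, no multiple-testing
   correction.

The package also provides out-of-bag permutation importance
I(A) = (1/T) Σ_j (1/N_j) Σ_i [F(V_j(X_i)=y_i) − F(V_j(X_i^(A,j))=y_i)] t_ij,
the full simulation benchmark (pure-epistasis penetrance tables with exact
zero marginals at a target heritability h², weak-marginal
additive/multiplicative/threshold odds models with LD markers, three-locus
amplifier models, hybrid/heterogeneous/null panels), a per-pair power and
false-positive benchmark harness, the single-locus chi-square reference
test, and a CLI.

## Worked example

```python
import numpy as np
import epiforest as ef

# a purely epistatic pair: h^2 = 0.4, MAF = 0.2, no marginal effects
rng = np.random.default_rng(7)
table = ef.pure_epistasis_penetrance(0.4, 0.2, rng=rng)
spec = ef.SimulationSpec(
    n_cases=200, n_controls=200, n_snps=1000,
    models=[ef.ModelAssignment(table, slots=(100, 500))], rng_seed=11)
ds = ef.sample_case_control(spec)

forest = ef.EpistasisForest(n_trees=500, mtry=5000, random_state=3)
forest.fit(ds.X, ds.y)

table = ef.normalized_scores(forest, ef.InteractionConfig(), random_state=5)
print(table.head(3)[["snps", "raw", "baseline_mean", "normalized"]])
```

prints (a minute or two on one CPU):

```
         snps  raw  baseline_mean  normalized
0  (100, 500)   31           1.35   29.650000
1    (4, 780)   18           4.41    7.046948
2   (29, 780)    8           1.12    6.452292
```

The planted pair (columns 100 and 500) appears together in branches of 31
of the 500 trees against a randomization baseline of ~1.4, scoring ≈ 30σ —
the only combination above the 25σ detection threshold; the strongest of
the ~107,000 noise combinations reaches ≈ 7σ. `ef.call_interactions(table)`
returns exactly the planted pair. Note that neither SNP is detectable
marginally: `ef.chi_square_single_locus(ds)` leaves both far from
Bonferroni significance.

The same pipeline is scriptable from the shell:

```bash
epiforest simulate -c spec.yaml -o panel.tsv --truth-out truth.json
epiforest forest -d panel.tsv -o forest.json --n-trees 1200 --mtry 5000
epiforest interact -d panel.tsv -f forest.json -o scores.tsv --called-only
epiforest importance -d panel.tsv -f forest.json -o importance.tsv
```

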