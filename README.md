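# thigblup

Bivariate genomic evaluation for comparing SNP effects and direct
genomic breeding values between two environments, built for
genotype-by-environment studies in dairy cattle where the environments
are levels of the temperature–humidity index (THI): one in the heat
comfort zone (THI ≈ 59) and one in the heat stress zone (THI ≈ 74,
above the conventional comfort threshold of 72).

## Who it is for

Animal breeders and quantitative geneticists who have per-animal
pseudo-phenotypes (breeding values from a prior evaluation) at two
environmental levels plus SNP genotypes, and want to know whether the
genetic architecture — which markers matter and which animals rank
best — changes between environments. A synthetic-data module generates
populations with a controlled between-environment genetic correlation,
so the whole pipeline is testable without any proprietary data.

## The model

Pseudo-phenotypes at the two THI levels are treated as two traits in a
bivariate GBLUP:

    [y1; y2] = [1μ1; 1μ2] + [Z1 0; 0 Z2][a1; a2] + [e1; e2]

with `[a1; a2] ~ N(0, G0 ⊗ G)` and `[e1; e2] ~ N(0, R0 ⊗ I)`, where
`G` is the VanRaden (method 1) genomic relationship matrix
`ZZ′ / 2Σp(1−p)` and `G0`, `R0` are the 2×2 additive and residual
covariance matrices between the environment-traits, estimated by
genomic REML (AI-accelerated EM). From the animal solutions `â`,
per-marker effects are back-solved as

    û = DM′(MDM′)⁻¹â            (D = I, single pass)

and each SNP's explained additive variance is `σ²ᵤ,ᵢ = 2pᵢ(1−pᵢ)ûᵢ²`,
reported as a percentage of the environment's summed SNP variance. The
two environments are then compared by (i) the overlap of the top-50
SNPs and the quadrants defined by each environment's truncation point
T (the 50th-largest percentage), (ii) gene-interval annotation of the
differing SNPs, and (iii) Spearman rank correlations of direct genomic
breeding values `DBV = M û` over the top 10%, top 40% and all animals.

## Worked example

```python
import thigblup as tg

cfg = tg.SimulationConfig(n_animals=500, n_markers=1000, seed=42, genetic_corr=0.9)
g = tg.simulate_genotypes(cfg)
pheno, _ = tg.simulate_pseudo_phenotypes(g, cfg)
freq = tg.allele_frequencies(g)
G = tg.vanraden_g(g, freq)
vc = tg.fit_greml(pheno, G)
print(f"genetic correlation between environments: {vc.genetic_correlation:.3f}")
gebv = tg.solve_mme(pheno, G, vc)
effects = tg.snp_effects_from_gebv(gebv, g, freq)
cmp_ = tg.top_k(effects, k=50)
print(f"top-50 SNPs in common: {cmp_.n_common}/50 "
      f"(truncation points {cmp_.T_env1:.3f}%, {cmp_.T_env2:.3f}%)")
dbv = tg.compute_dbv(g, effects, freq)
for _, r in tg.rank_correlations(dbv).data.iterrows():
    print(f"top {int(r['fraction']*100):3d}%: Spearman rho = {r['spearman_rho']:.3f}, "
          f"{int(r['n_not_retained'])} animals not retained")
```

prints

```
genetic correlation between environments: 0.924
top-50 SNPs in common: 45/50 (truncation points 0.431%, 0.431%)
top  10%: Spearman rho = 0.877, 9 animals not retained
top  40%: Spearman rho = 0.909, 17 animals not retained
top 100%: Spearman rho = 0.971, 0 animals not retained
```

The population was simulated with a between-environment genetic
correlation of 0.9; the fitted bivariate model recovers 0.92, most of
the high-variance SNPs are shared between environments (45/50), and
animals rerank only mildly (ρ ≥ 0.88 in every selection fraction) —
the signature of weak genotype-by-environment interaction. "Not
retained" counts how many animals in the comfort environment's top set
fall outside the stress environment's top set of the same size.

The same analysis runs from the shell via the `thigblup` console
script (`simulate`, `qc`, `grm`, `reml`, `backsolve`, `compare`, `thi`
subcommands); see `thigblup --help`.

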