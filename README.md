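# ensemble-gp

Ensemble genomic prediction on simulated recombinant inbred line (RIL)
populations. The package simulates biparental BC1S4 RIL families with known
trait architectures, runs six diverse genomic predictors — ridge BLUP
(rrBLUP), a spike-and-slab Bayesian marker model (BayesB), Gaussian-kernel
regression (RKHS), random forest, ε-SVR, and a graph attention network — and
combines them with a naïve equal-weight ensemble. The ensemble's advantage is
quantified by the error/diversity decomposition (ensemble error = average
individual error − prediction diversity) and per-model marker-effect
attribution (coefficients, Shapley values, impurity importance, integrated
gradients).

## Layout

| module | contents |
| --- | --- |
| `ensemble_gp.synthetic_data` | marker maps, meiosis/pedigree simulator, trait architectures, phenotypes, missing-call injection |
| `ensemble_gp.preprocess` | >10%-missingness filter, modal & flanking imputation, windowed LD pruning (r² > 0.8, 30 kb windows, step 5), environment concatenation, train/test splits |
| `ensemble_gp.models` | the six predictors under one `fit(X, y, hyper, seed) -> FittedModel` / `predict(model, X)` contract; the attention network is pure numpy with hand-derived backprop |
| `ensemble_gp.ensemble` | equal-weight averaging, error/diversity decomposition, pooled mean ± SE summaries |
| `ensemble_gp.interpret` | coefficient effects, Monte-Carlo Shapley, impurity importance, integrated gradients, pairwise model association reports |
| `ensemble_gp.experiment` | populations × traits × ratios × replicates orchestration, Pearson/MSE metrics, best-model percentage tables |
| `ensemble_gp.io`, `ensemble_gp.cli` | CSV/PED/MAP/JSON writers and the `ensemble-gp` command line |

## CLI

```bash
ensemble-gp simulate --config sim.yaml --out sim/ --seed 1
ensemble-gp preprocess --geno sim/POP1.geno.csv \
    --pheno sim/POP1.additive_trait.pheno.csv --map sim/POP1.map.csv \
    --impute mode --out pre/
ensemble-gp run --config exp.yaml --out results/ --seed 1   # --full for the 500-replicate design
```

`run` simulates populations, cleans them, fits every requested model over the
ratio × replicate grid, and writes `results.tsv`, `decompositions.tsv`,
`dpt_summary.tsv`, `best_pct.tsv`, and `failures.tsv`.

## Notes

- All generators and fits are bit-reproducible from `(data, hyper, seed)`.
- Dosages count the donor-parent allele (recurrent parent is all-zero), so
  Mendelian invariants are directly checkable: donor allele frequency ≈ 0.25
  and residual heterozygosity ≈ 0.03125 under the default BC1S4 pedigree.
- The environment indicator enters linear/kernel models as a fixed effect and
  the machine-learning models as an ordinary feature.
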