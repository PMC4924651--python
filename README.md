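# orthokinetics

Cross-species comparison of gene-expression time-course kinetics.

When the same biological process — here, CD4+ T cells polarizing toward
the Th17 lineage over 72 hours — is profiled by RNA-seq in two species,
the interesting question per ortholog pair is not just *whether both genes
respond* but *whether they follow the same kinetics*, possibly offset in
time. `orthokinetics` implements that comparison and the companion
analyses around it, for anyone comparing replicated expression time
courses between human and mouse (or any two species with a one-to-one
ortholog map):

* a **Gaussian-process Bayes-factor test** of conserved kinetics with a
  bounded time shift,
* expression filtering, top-20% fold-change **ranking** and cross-species
  **concordance**,
* joint k-means **profile clustering** of both species' DE genes,
* **SNP-window trait enrichment** (±100 kb, hypergeometric) and generic
  functional-class enrichment,
* chromosomal **co-localization** with permutation p-values,
* **lncRNA** filtering, biotype representation and co-expression analysis,
* a **synthetic-data module** that generates every input with planted
  ground truth, so the whole pipeline runs and is tested without any
  download.

## The core model

For an ortholog pair with replicated, log-transformed, standardized
profiles Y_h, Y_m observed at times X, two models are compared:

* *shared*: one zero-mean GP f ~ GP(0, k) generates the pooled data, with
  a time shift Δt ∈ [−24, 24] h added to the mouse time points;
* *independent*: separate GPs per species.

The covariance is the neural-network kernel
k(x,x′) = sf² · asin( x̃ᵀΣx̃′ / √((1+x̃ᵀΣx̃)(1+x̃′ᵀΣx̃′)) ) with x̃ = [1, x],
Σ = diag(l⁻²), plus noise variance σn². Hyperparameters are MAP estimates
under Gamma priors — l ~ Γ(6,30) on rescaled time, sf² ~ Γ(10,10),
σn² ~ Γ(2, 1/m) truncated to [ε, 1] with mode m equal to the mean
replicate variance — optimized by quasi-Newton ascent; Δt by a 2-h grid.
The decision statistic is the Bayes factor

    BF = P(Y_h ∪ Y_m | shared) / ( P(Y_h) · P(Y_m) ),

computed from plug-in marginal likelihoods, and **BF > 10 calls the pair
"shared"** (conserved kinetics, with Δt̂ the estimated shift).

See `docs/methods.md` for the full model, priors, standardization
conventions and known limitations.

## Worked example

Simulate six ortholog pairs (three shared, two shifted by +12 h, one
divergent) and test each pair:

```python
from orthokinetics.simulate import simulate_ortholog_timecourse
from orthokinetics.gp import compare_orthologs

human, mouse, orthologs, truth = simulate_ortholog_timecourse(
    n_pairs=6, frac_shared=0.5, frac_shifted=0.25, shift_set=[12],
    noise_sd=0.2, seed=42)
results = compare_orthologs(human, mouse, orthologs, seed=0)
for t, row in zip(truth, results.itertuples()):
    print(f"{row.pair_id:22s} planted={t.klass:9s} "
          f"true_shift={t.true_shift_hours:+5.1f}h "
          f"dt_hat={row.dt_hat_hours:+5.1f}h "
          f"log_bf={row.log_bf:7.2f} call={row.call}")
```

which prints:

```
hs_pair0001|mm_pair0001 planted=shared    true_shift= +0.0h dt_hat= +0.0h log_bf=  19.30 call=shared
hs_pair0002|mm_pair0002 planted=shared    true_shift= +0.0h dt_hat= -2.0h log_bf=   9.53 call=shared
hs_pair0003|mm_pair0003 planted=shared    true_shift= +0.0h dt_hat= +0.0h log_bf=  20.58 call=shared
hs_pair0004|mm_pair0004 planted=shifted   true_shift=+12.0h dt_hat=+12.0h log_bf=   6.26 call=shared
hs_pair0005|mm_pair0005 planted=shifted   true_shift=+12.0h dt_hat=+10.0h log_bf=   7.82 call=shared
hs_pair0006|mm_pair0006 planted=divergent true_shift= +0.0h dt_hat= -8.0h log_bf=   1.40 call=different
```

Reading it: `log_bf` is ln BF, so the call threshold BF > 10 is
log_bf > 2.30. The three planted-shared pairs are called shared with
strong evidence and shifts at or near 0; the two +12 h pairs are called
shared with the shift recovered within one 2-h grid step; the divergent
pair falls below threshold. On larger cohorts the fitted shift's median
absolute error is 0 h and the BF > 10 rule reaches ~88% balanced accuracy
(sensitivity 0.98, specificity 0.78) at noise sd 0.2 — the residual false
positives are independent smooth curves that happen to align under some
time shift.

The same works from the shell:

```bash
orthokinetics simulate --out run --seed 42 --n-pairs 6
orthokinetics run-all --out run2 --seed 1        # full pipeline, all stages
orthokinetics gp-compare --expression-human run/inputs/expression_human.tsv \
    --expression-mouse run/inputs/expression_mouse.tsv \
    --orthologs run/inputs/orthologs.tsv --out bf.tsv
```

`run-all` writes one TSV per stage (ranked sets, concordant pairs, Bayes
factors, cluster assignments, trait and functional enrichment,
co-localization clusters, lncRNA tables) plus `manifest.json` recording
the config hash, seed and per-stage row counts; identical config + seed
gives byte-identical outputs.

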