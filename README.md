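# regscore

TF-gene scores from ChIP-seq and open-chromatin peak data, and
confounder-aware elastic-net models of gene expression.

Predictive models of gene expression built from transcription-factor
(TF) binding evidence are a standard way to nominate regulators: genes ×
TF-score matrices are regressed against expression and the coefficients
are read as TF importance. The catch is that such scores embed generic
chromatin context — how many peaks sit near a gene, how long they are,
how strong the accessibility signal is — so a model can predict
expression well while its columns are largely exchangeable, and
coefficient rankings can mislead. `regscore` is for computational
biologists who build such models and want to (a) compute the scores
under explicit, comparable conventions, (b) quantify how confounded they
are, and (c) check whether a fitted model survives the randomisation
diagnostics before interpreting it.

## What it computes

**Scores.** Peak evidence is aggregated over a 50 kb window centred on
the most 5' TSS of each gene, weighted by exponential decay
`exp(−d/d0)` with `d0 = 5 kb`, under nine variants. From per-TF
ChIP-seq peaks with scores `c_{p,t}`:

    C:    a_{g,t} = Σ_p  c_{p,t} e^(−d_{p,g}/d0)
    CN:   a_{g,t} / c_g   plus the aggregate features c_g, l_g
    CPF:  c_g, l_g only

where `c_g` and `l_g` are the decay-weighted peak count and total peak
length over all TFs. From open-chromatin (DNase) peaks, per-peak TF
affinities `a_{p,t}` are computed TRAP-style — every sequence window of
motif width on both strands contributes the occupancy probability
`expit(ln R0 − E/λ)` for its summed mismatch energy `E` — and
aggregated as the raw decay sum (**D**), signal-scaled (**DS**),
normalised per peak by the number of possible binding sites
`|p| − |m| + 1` (**DN**, **DSN**), or reduced to the aggregate peak
features alone (**DPF**, **DPFS**).

**Model.** Expression and features are `log2(x+1)`-transformed and fit
with the elastic net

    β̂ = argmin_β ‖y − Xβ‖² + λ[α‖β‖₂² + (1−α)‖β‖₁]

under 10-fold Monte-Carlo outer cross-validation (random 80/20 splits,
per-fold standardisation on training rows only), with `(α, λ)` chosen
by 6-fold inner CV over an α grid and per-α λ path. Held-out
performance is reported as Spearman correlation.

**Diagnostics.** Row-wise (per-gene) permutation of the matrix destroys
TF identity while preserving gene-level aggregates; comparing original
and permuted fits, pairwise TF-score correlations, correlations against
the peak features, the expression of top-ranked TFs, and precision/
recall against a gold-standard TF set shows how much of a model is
TF-specific signal versus chromatin context.

A synthetic-data generator produces complete input sets (genome, GTF,
narrowPeak, PSEMs, expression) with planted causal TFs and a tunable
length-confounding dial, so the whole pipeline is testable end to end
with a known answer.

## Worked example

```python
import numpy as np
from regscore import (FixtureConfig, generate_fixture, dnase_scores, DecayParams,
                      ExpressionModel, ModelConfig, PermutationScheme, permute_rows,
                      feature_confounder_correlation)

fx = generate_fixture(FixtureConfig(seed=7, n_genes=500, n_tfs=12, n_causal=3),
                      "example")
print("causal TFs:", fx.ground_truth["causal_tfs"])

cfg = ModelConfig(seed=7, alpha_grid=tuple(np.round(np.linspace(0, 1, 21), 3)))
res = ExpressionModel.from_feature_matrix(fx.d_matrix, fx.expression, cfg).fit()
print(res.summary())
```

prints

    causal TFs: ['TF001', 'TF004', 'TF011']
    Expression model (elastic net), 10 outer folds x 6 inner folds
    penalty=elastic_net  alpha grid: 21 values  lambda path: 100 values
    test Spearman  mean=0.9054  sd=0.0116
    test MSE       mean=0.4396  sd=0.0568
    nonzero coefs  mean=7.4  sd=1.0 of 12 features

    top features by |mean coefficient| (standardized scale):
      TF011                +0.3119  sd=0.0327
      TF001                +0.2474  sd=0.0152
      TF004                +0.2013  sd=0.0099
      TF005                +0.1405  sd=0.0347
      ...

The three planted causal TFs head the coefficient ranking, selected
stably across folds. The diagnostics show the confounding this package
is about:

```python
perm = permute_rows(fx.d_matrix, PermutationScheme(seed=7, scope="all_columns"))
res_p = ExpressionModel.from_feature_matrix(perm, fx.expression, cfg).fit()

dn = dnase_scores(fx.genes, fx.dnase_peaks, fx.affinities, DecayParams(), "DN")
joined = fx.d_matrix.values.join(fx.peak_features[["Peak_Length"]])
```

    permuted input: mean Spearman 0.8680 (original 0.9054), nonzero 12/12 features
    median corr(TF score, peak length): D 0.726 -> DN 0.600

Row-permuted input still predicts expression almost as well — the
shared chromatin context carries that much — but the elastic net then
selects *all* features with flat coefficients (the grouping effect), so
the permuted model is uninterpretable rather than wrong. Normalising
affinities by the number of possible binding sites (DN) reduces the
peak-length confounding and, at scale, widens the original-vs-permuted
performance gap.

The same steps are available as a CLI
(`regscore simulate | annotate | permute | train | diagnose | evaluate`,
or `regscore run --config config.yaml` for the whole chain).

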