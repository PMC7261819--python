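# deqms

Differential protein expression analysis for quantitative mass-spectrometry
proteomics, with an empirical-Bayes variance prior that depends on the number
of PSMs or peptides used to quantify each protein — a Python implementation
of the DEqMS approach.

## The problem

In shotgun proteomics a protein's abundance is summarized from a variable
number of peptide-spectrum matches (PSMs, for isobaric labelling such as TMT)
or peptides (label-free). Proteins quantified from one or two PSMs have far
noisier log-ratios than proteins quantified from dozens, so the within-group
variance is strongly count-dependent. Classic moderated-t analysis shrinks
every protein's variance toward one common prior, which *underestimates* the
variance of low-count proteins (inflating false positives) and
*overestimates* it for high-count proteins (costing power). This package
makes the prior variance a smooth function of quantification depth instead.

## The model

For protein *g* with pooled within-group variance *s²ₚ* on *d_g* residual
degrees of freedom, assume a scaled inverse-χ² variance prior with parameters
*s₀²(x)* and *d₀*, where the covariate *x* = log₂(PSM or peptide count).
Because log *s²ₚ* is a constant plus a Fisher's-Z variable,

    e_g = log s²ₚ − ψ(d_g/2) + log(d_g/2)

has mean log s₀² − ψ(d₀/2) + log(d₀/2) and variance ψ′(d_g/2) + ψ′(d₀/2)
(ψ, ψ′ the digamma and trigamma functions). The per-protein prior mean is
obtained from a loess regression of log *s²ₚ* on *x* (tricube weights,
span 0.75, degree 2), and *d₀* is solved from

    ψ′(d₀/2) = mean[(e_g − pred e_g)²] − ψ′(d_g/2)

on a 0.1-step grid, stopping when the absolute moment mismatch first stops
decreasing (+∞ when the spread is at or below the sampling floor). Testing
then uses the posterior variance (d_g s²ₚ + d₀ s₀²)/(d_g + d₀) in a
moderated t on d_g + d₀ degrees of freedom, with Benjamini–Hochberg FDR
control. Setting the covariate to mean log₂ abundance gives the
intensity-trend variant; a constant covariate recovers the classic flat
prior.

The package also provides the surrounding pipeline: median-sweep and
reference-channel summarization of PSM tables to protein log₂-ratio
matrices, per-batch PSM-count metrics for multi-TMT-set designs (minimum
recommended), ordinary Welch-t and ANOVA-F baselines, variance-profile /
RSS / partial-AUC diagnostics, and synthetic null, spike-in and multi-batch
generators with known ground truth.

## Worked example

```python
from deqms import SpectraCountEBayes
from deqms.simulate import simulate_spikein
from deqms.summarize import median_sweep

# spike-in benchmark: 2000 background + 400 spiked proteins at a 2-fold ratio
table, truth, design = simulate_spikein(
    n_background=2000, n_spike=400, ratio=2.0, seed=1
)
matrix = median_sweep(table)                  # PSM table -> protein log2 ratios

X = matrix.values.T.to_numpy()                # samples x proteins
y = [design.sample_to_group[s] for s in matrix.sample_ids]
est = SpectraCountEBayes(covariate="count").fit(X, y, counts=matrix.count)
print(f"prior df d0 = {est.d0_:.1f}; residual df d_g = {est.resid_df_}")

res = est.test("spike", "ctrl")
res.index = matrix.protein_ids
print(res.nsmallest(5, "p_mod").round(4))
```

prints

```
prior df d0 = 60.1; residual df d_g = 4
            log2FC    t_ord   p_ord   t_mod  p_mod  q_mod
spike00339  1.0845  20.4673  0.0009  8.5685    0.0    0.0
spike00254  1.2507  14.6059  0.0018  7.8453    0.0    0.0
spike00195  1.0233   5.2262  0.0130  7.7257    0.0    0.0
spike00343  1.1857   6.1205  0.0036  7.4660    0.0    0.0
spike00053  1.0900   9.5829  0.0085  7.3518    0.0    0.0
```

The estimated log₂ fold changes sit near the true value of 1; moderation
borrows 60.1 prior degrees of freedom on top of the 4 residual ones, so the
moderated p-values are far smaller than the triplicate Welch-t ones (values
below 1e-4 print as 0 at this rounding). At BH q < 0.01 the fit reports 211
proteins, 208 of them true spikes. `est.posterior_var_`, `est.prior_var_`
and `est.trend_` expose the fitted variance machinery;
`deqms.spectra_count_ebayes` offers the same pipeline as a plain function
on a `ProteinMatrix` + `DesignSpec`.

The same workflow is available from the shell:

```sh
deqms simulate spikein -o sim/
deqms summarize sim/quant.tsv --method median-sweep -o matrix.tsv
deqms fit matrix.tsv --design sim/design.tsv --contrast spike:ctrl -o results.tsv
deqms diagnose matrix.tsv --design sim/design.tsv -o profile.tsv
```

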