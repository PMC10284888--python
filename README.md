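# bulkdecon

Cell-type deconvolution of bulk PBMC RNA-seq and composition-aware analysis
of treatment cohorts, built around the question that dominates blood
transcriptomics of rheumatoid arthritis (RA): *when gene expression changes
with disease or treatment, is the change cell-intrinsic regulation, or just
a change in which cells are in the tube?*

The package is aimed at computational biologists analyzing paired
pre/post-treatment bulk expression cohorts (e.g. methotrexate or TNF-inhibitor
arms plus healthy controls) who want to:

1. estimate per-sample **cell contribution scores** for K blood cell types
   from marker-gene signatures,
2. validate those scores against flow cytometry,
3. test disease- and treatment-associated composition changes in paired
   designs,
4. attribute differential gene expression to composition change versus
   cell-intrinsic regulation,
5. predict treatment non-response from baseline composition, and
6. meta-analyze case/control cell differences across studies.

A synthetic-cohort generator with known ground truth (cell fractions,
planted composition shifts, cell-intrinsic effects, latent glucocorticoid
exposure, matched noisy flow table) makes every stage testable without any
external download.

## The methods in brief

**Deconvolution.** For sample *j* with linear-scale CPM vector `x_j`
restricted to marker genes, scores solve the non-negative least squares
problem

```
s_j = argmin_{s >= 0} || A s - x_j ||^2
```

where the columns of `A` are the signature-matrix columns normalized to
unit sum over marker genes. Markers are genes whose signature value is at
least `min_fold` (default 4) times the second-highest cell type. The score
is an arbitrary-unit RNA-mass proxy: non-negative, scale-equivariant, and
monotone in the true cell fraction — which is why validation against flow
cytometry uses Spearman correlation.

**Glucocorticoid exposure proxy.** A per-sample ssGSEA score of a
glucocorticoid-response gene set: the integrated difference between the
weighted in-set rank ECDF (`rank^0.25` weights) and the uniform out-of-set
ECDF, walking each sample's expression ranking.

**Cell statistics.** Per cell type, paired treatment effects are estimated
by OLS on `cells ~ subject + GC_signature + treatment` with subjects as
fixed-effect indicators; response enters as a `treatment:response`
interaction; two-group contrasts use Wilcoxon rank tests; everything is
Benjamini–Hochberg corrected across cell types.

**DGE attribution.** Genes are tested on `log2`-CPM with mean–variance
precision weights and empirical-Bayes moderated t statistics
(`s~^2 = (d0*s0^2 + d_g*s_g^2)/(d0 + d_g)`), fitting the treatment contrast
twice — without (model A) and with (model B) cell-contribution covariates.
The **explained fraction** `(N_before - N_both) / N_before` summarizes how
much treatment-associated expression is attributable to composition change.

**Response prediction.** Elastic-net logistic regression on inverse-rank
normalized baseline scores under nested cross-validation (stratified 4/5
outer splits repeated 100×, 10-fold inner tuning by AUC), reporting AUC-ROC
and precision–recall AUC for the non-responder class.

**Meta-analysis.** Per-study Hedges' g per cell type pooled by
DerSimonian–Laird random effects (`tau^2` from Cochran's Q, weights
`1/(v_i + tau^2)`), BH-corrected across cell types.

## Worked example

```python
import bulkdecon as bd

# synthetic paired cohort: 30 healthy, 53 MTX, 37 TNFi subjects, 29 cell types
sim = bd.synthetic.simulate_cohort(design=bd.synthetic.CohortDesign(seed=1), seed=1)
scores = bd.deconv.deconvolve(sim.counts, sim.reference)
report = bd.deconv.correlate_with_flow(scores, sim.flow, bd.synthetic.DEFAULT_FLOW_MAP)
print(report["matched"][["population", "rho"]].round(2).to_string(index=False))
```

prints

```
     population  rho
 Mature B cells 0.94
   CD4+ T cells 0.86
Mature NK cells 0.98
      Monocytes 0.91
   CD8+ T cells 0.92
```

— the Spearman correlation between each flow-cytometry population and the
matching aggregated contribution scores across the 240 samples: the scores
track measured proportions well despite 20% flow noise and count-level
negative-binomial noise. An end-to-end run of every stage:

```bash
bulkdecon run-all --out run1 --seed 1       # writes TSV/JSON + manifest.json
```

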