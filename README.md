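# ribocomp

Resource competition and cell-to-cell heterogeneity in bacterial
multi-gene expression.

When a cell expresses several genes at once, the genes draw on shared
expression machinery — ribosomes for translation, RNA polymerases for
transcription. `ribocomp` implements an analytic framework for what this
competition does to *single-cell* protein and mRNA outputs when the inputs
themselves (mRNA pools, machinery totals) vary from cell to cell. It is
aimed at people modeling heterologous expression burden in engineered
bacteria, and at anyone analyzing two-color single-cell expression data
where within-condition and pooled correlations tell different stories.

## The model

A heterologous module (1) and an endogenous module (2) compete for a
conserved ribosome pool. In a cell with total mRNA pools
$M_1^T, M_2^T$ and total ribosomes $Rib^T$, the free pool $Rib^F$ solves

$$Rib^T = Rib^F + \frac{n_1\,Rib^F}{\beta_1 + Rib^F}M_1^T
                + \frac{n_2\,Rib^F}{\beta_2 + Rib^F}M_2^T,$$

with $n_i$ the ribosomes loaded per mRNA at saturation and $\beta_i$ the
ribosome–mRNA dissociation constant. Protein output is proportional to the
ribosomes each module sequesters, $P_i = c_i\,n_i Rib^F/(\beta_i+Rib^F)\,M_i^T$.
The left side is strictly monotone in $Rib^F$, so the steady state is
unique and its sensitivities follow from implicit differentiation.

Treating $(M_1^T, M_2^T, Rib^T)$ as random across cells and linearizing
around the population mean, the protein covariance propagates as
$\mathrm{Cov}(P_1,P_2) = (J\,\Sigma\,J^{\mathsf T})_{12}$ with $J$ the
2×3 sensitivity matrix; when only $Rib^T$ and $M_1^T$ vary appreciably,

$$\mathrm{Cov}(P_1,P_2) \approx
  \underbrace{\frac{\partial P_1}{\partial Rib^T}\frac{\partial P_2}{\partial Rib^T}\mathrm{Var}(Rib^T)}_{\ge\,0}
+ \underbrace{\frac{\partial P_1}{\partial M_1^T}\frac{\partial P_2}{\partial M_1^T}\mathrm{Var}(M_1^T)}_{\le\,0}.$$

Shared-resource variation pushes the two proteins up and down *together*;
burden variation pushes them *apart*. Within one induction condition the
resource term wins and $r(P_1,P_2) > 0$; pooling conditions inflates
$\mathrm{Var}(M_1^T)$ until the competition term wins and the pooled
correlation flips negative — a Simpson-type sign reversal.

The package also contains:

- a **transcription analogue** (three gene classes competing for RNAP)
  showing why the reversal does *not* arise at the mRNA level — promoter
  occupancy is near-saturated, so mRNAs inherit the promoter-copy
  correlation and heterologous genes barely repress endogenous transcripts;
- an **antibiotic-survival simulation**: populations with correlated
  resistance proteins $(R_1, R_2)$ under a two-drug threshold kill rule,
  with the latent-bivariate-normal orthant probability as closed-form
  cross-check;
- **synthetic data generators** for protein fluorescence and FISH-like
  mRNA intensity tables (with negative control), so the full analysis runs
  without any experimental download;
- a **statistics pipeline**: Pearson $r$ with percentile-bootstrap CIs,
  CV² (variance over squared mean), fluorescence→integer-copy
  quantization, Poisson/negative-binomial count fits, and the grouped
  correlation analysis with even subsampling.

## Worked example

```python
from ribocomp import (KineticParams, CellInputs, steady_state,
                      ProteinDatasetConfig, generate_protein_dataset,
                      grouped_correlation_analysis)

# one cell at the default operating point
ss = steady_state(KineticParams(), CellInputs(M1T=300, M2T=900, RibT=10_000))
print(f"RibF={ss.RibF:.1f}  free_fraction={ss.free_fraction:.3f}  "
      f"P1={ss.P1:.1f}  P2={ss.P2:.1f}")

# the default synthetic experiment: 7 induction conditions x 3000 cells
table = generate_protein_dataset(ProteinDatasetConfig(), seed=1)
report = grouped_correlation_analysis(table,
                                      subsample_sizes=[70, 700, 2100],
                                      replicates=100, seed=1)
for label, res in report.per_group.items():
    print(f"{label}: r = {res.r:+.3f} (n={res.n})")
print(f"merged: r = {report.merged.r:+.3f} (n={report.merged.n})")
print(report.subsample_curve.to_string(index=False))
```

Output:

```
RibF=2000.0  free_fraction=0.200  P1=2000.0  P2=6000.0
cond1: r = +0.424 (n=3000)
cond2: r = +0.419 (n=3000)
cond3: r = +0.398 (n=3000)
cond4: r = +0.429 (n=3000)
cond5: r = +0.412 (n=3000)
cond6: r = +0.458 (n=3000)
cond7: r = +0.492 (n=3000)
merged: r = -0.313 (n=21000)
 total_n    mean_r     sd_r
      70 -0.323672 0.105519
     700 -0.312186 0.034108
    2100 -0.311407 0.015885
```

At the operating point a fifth of the ribosome pool is free. Every
induction condition shows a clearly *positive* single-cell correlation
between the two reporters, yet the merged population is *negative* —
the sign reversal described above. The even-subsampling curve shows the
merged estimate is stable in mean while its replicate-to-replicate spread
shrinks with sample size, i.e. the reversal is not a sampling artifact.

The same analyses are scriptable through a thin CLI
(`ribocomp simulate | surface | simpson | transcription | antibiotics |
generate-data | analyze`); run `ribocomp --help`.

## Documentation

`docs/methods.md` describes the models, their assumptions, the default
parameters and why they were chosen, what the synthetic generators do and
do not emulate, and the package's numerical conventions.
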