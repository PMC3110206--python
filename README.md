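# vcgrn — sample-specific, modulator-dependent gene regulatory networks

Bulk expression compendia average over deeply heterogeneous samples: the
strength of a regulator→target interaction in a cancer cell line can
depend on where that sample sits along a biological transition such as
the epithelial–mesenchymal transition (EMT), drug sensitivity or
prognosis risk.  `vcgrn` infers **one sparse gene regulatory network per
sample** from a genes × samples expression matrix by letting every
regression coefficient vary along a one-dimensional per-sample
*modulator* score, and then asks which regulators' influence the
modulator reshapes.

## Model

For target gene *l* with candidate regulators *x₁…x_q* (transcription
factors, nuclear receptors, miRNAs), the varying-coefficient structural
equation model is

    y_l = Σ_j β_j(m) · x_j + ε,

where *m* is the modulator.  For each focal sample *i*, β(m_i) is
estimated by minimising a Gaussian-kernel-weighted, adaptively
penalised residual sum of squares over all samples *k*:

    ½ Σ_k w_k (y_k − Σ_j β_j x_kj)² + λ₁ Σ_j γ_j |β_j| + ½ λ₂ Σ_j β_j²,
    w_k = exp(−(m_k − m_i)² / 2h²),

with importance weights γ_j = 1/(|β̂_j| + δ) re-estimated recursively
(adaptive elastic net) and (λ₁, λ₂) selected per fit by a bias-corrected
weighted AIC with effective sample size n_eff = Σ w_k.  The bandwidth
*h* is chosen by K-fold cross-validation on held-out prediction error.
Collecting the nonzero coefficients of every (target, sample) fit gives
the per-sample network ensemble.

Post-analyses:

* **Regulatory effect** — per sample, the sum over directed paths of
  length ≤ 2 from a regulator to a target of the product of edge
  coefficients; its max−min spread across samples ranks regulators by
  modulator dependence, labelled activator (A) or inhibitor (I).
* **Gene-set enrichment** — per sample and regulator, a one-sided
  Fisher exact test of the regulator's downstream targets against GMT
  gene sets with Benjamini–Hochberg correction; the per-set spread
  E = max(−log₁₀ q) − min(−log₁₀ q) across samples is Fisher-combined
  (T = 2·ln 10·ΣE, χ² with 2L df) into one *integral p-value* per
  regulator — small values flag master-regulator candidates.
* **Hidden-modulator extraction** — when the modulator is not directly
  observable, a seed gene signature is refined to a coherent subset and
  samples are scored by the first principal component of the
  single-factor model x = μ + b·z + ε, sign-anchored to a marker gene
  (e.g. E-cadherin for epithelial identity).

A seeded synthetic-data module generates every structure the method
assumes (coefficient switches, single-factor blocks, set-concentrated
regulation) with full planted truth, so the whole pipeline is testable
offline.

## Worked example

```sh
python examples/01_switch_networks.py
```

generates 200 samples in which regulator R01 drives the target only
above a modulator threshold (11 decoy regulators never do), infers the
200 per-sample networks at h = 0.2, and prints

```
m in [-1.0, -0.5):  mean fitted beta(R01->TGT) = 0.000   (true: 0.0)
m in [-0.5, +0.0):  mean fitted beta(R01->TGT) = 0.111   (true: 0.0)
m in [+0.0, +0.5):  mean fitted beta(R01->TGT) = 0.816   (true: 1.0)
m in [+0.5, +1.0):  mean fitted beta(R01->TGT) = 1.023   (true: 1.0)
```

— the fitted coefficient tracks the planted 0 → 1 switch, smoothed over
roughly a kernel bandwidth around the threshold.  The other examples
cover bandwidth selection (`03`), hidden-modulator extraction (`02`,
recovering the latent factor with |corr| = 0.997), effect-change
ranking (`04`, the planted regulator ranks 1 with change ≈ 1.01) and
gene-set enrichment (`05`, the planted regulator attains integral
p ≈ 1 × 10⁻⁴ vs ≥ 0.07 for decoys).

The same functionality is available from the shell:

```sh
vcgrn simulate --scenario switch --n-samples 200 --seed 7 --out-dir sim/
vcgrn infer --expr sim/expression.tsv --regulators sim/regulators.tsv \
            --targets TGT --modulator sim/modulator.tsv --h 0.2 --out nets.tsv
vcgrn effects --ensemble nets.tsv --target TGT --out-prefix tgt
```

## Layout

```
src/vcgrn/        io_formats, modulator, vc_solver, network_inference,
                  regulatory_effect, gene_set_analysis, synthetic, cli
examples/         one short narrative script per capability
tests/            unit, property and end-to-end acceptance tests
docs/methods.md   model, assumptions, parameter and design notes
```
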