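# fibrovae

Multimodal anomaly detection for pulmonary fibrosis cohorts: CT-derived
imaging embeddings are fused with standardized clinical and functional
variables, a variational autoencoder (VAE) learns the cohort's typical joint
profile, and per-patient anomaly scores surface *clinically–radiologically
discordant* patients — those whose imaging appearance and physiologic
impairment disagree (preserved function with deviant imaging, or the
converse).

The package is aimed at researchers studying heterogeneity in fibrotic
interstitial lung disease with small, real-world cohorts, where supervised
modeling is circular (severity labels already encode imaging and clinical
judgment) and unsupervised deviation from the learned cohort manifold is the
quantity of interest.

## Model

Each patient *i* is a vector **x**ᵢ ∈ ℝᵈ concatenating the z-scored core
clinical feature set (age, sex, SpO₂ at rest, DLCO%, DLCO/VA%, FEV₁%, 6MWT
distance, VO₂max, MIP, MEP, mMRC, three oxygen/inhaled-therapy indicators)
with a 512-dimensional CT embedding (32 evenly spaced axial slices →
lung window (level −600 HU, width 1500 HU) → 224×224×3 → frozen
convolutional-style feature extractor → average pooling across slices).

The VAE is

- encoder `q(z|x) = N(μ(x), diag σ²(x))`, `x → 256 → 128 → (μ, log σ²)`,
  latent `k = 8`;
- decoder `p(x|z) = N(g(z), I)`, `z → 128 → 256 → x̂`, linear output;
- objective (minimized, β = 1):
  `L = E_q‖x − x̂‖² + β·KL(q(z|x) ‖ N(0, I))`,
  with `KL = −½ Σⱼ (1 + log σⱼ² − μⱼ² − σⱼ²)`;
- anomaly score `A(x) = ‖x − x̂‖² + β·KL(q(z|x) ‖ N(0, I))`, evaluated with
  the deterministic posterior-mean reconstruction `x̂ = g(μ(x))`.

Patients at or above the 85th percentile of `A` (linear order-statistic
interpolation) are flagged as highly anomalous; for 41 distinct scores this
is exactly 7/41 patients (17.1%). Severity labels never enter training —
they are used only in downstream stratification and correlation analyses
(Kruskal–Wallis, Dunn–Holm, Cliff's δ, Spearman ρ, bootstrap CIs, PCA), all
implemented from first principles and pinned by oracle tests.

Because the study's patient data are private, the package ships a calibrated
synthetic cohort generator (41 patients, 19/8/14 across mild/moderate/severe,
group medians matched to the published summary table) that injects a
configurable fraction of ground-truth discordant patients, plus CT phantoms
for exercising the imaging pipeline.

## Worked example

```python
from fibrovae import CohortSimConfig, VAEConfig, generate_cohort
from fibrovae.vae import MultimodalVAE

clinical, embeddings, truth = generate_cohort(CohortSimConfig(seed=0))
model = MultimodalVAE.from_dataframes(clinical, embeddings, config=VAEConfig(seed=0))
results = model.fit()
severity = truth.loc[model.matrix.patient_ids, "severity"].tolist()
print(results.summary(severity=severity))
```

```
Multimodal VAE anomaly detection
========================================
patients            41
input dim d         526
latent dim k        8
beta                1.0
epochs              200
final mean ELBO     35.2953
----------------------------------------
anomaly score median 18.18  IQR 15.49-20.51
range                13.22-499.90   skewness 5.22
85th percentile   21.69
flagged              7/41 (17.1%)
flagged by severity  mild: 2, moderate: 1, severe: 4
```

The score distribution is strongly right-skewed: most patients sit near the
learned manifold (median 18.2) while the injected discordant profiles score
far above it (up to 499.9 here — an offset-discordant patient whose imaging
factor was displaced by 3 SD). Exactly 7/41 patients (17.1%) exceed the 85th
percentile, and they occur in every severity group — deviation from the
multimodal norm is not a surrogate for severity. `results.anomaly_scores()`
returns the per-patient table (`score`, `recon`, `kl`, severity);
`score = recon + β·kl` holds to float precision for every row.

The full pipeline — simulate, fuse, train, score, analyze, render figures,
write a reproducibility manifest — runs from one config:

```python
from fibrovae import PipelineConfig, run_pipeline
run_pipeline(PipelineConfig(seed=0, outdir="run0"))
```

or from the shell: `fibrovae run --seed 0 --out run0/` (see also
`fibrovae simulate|embed|train|score|analyze|stats --help`).

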