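# spectrafuse

Multi-modality fusion of ATR-FTIR serum spectra and clinical blood
biochemistry for screening of acute myeloid leukemia (AML).

Screening AML from a blood draw is attractive because it is minimally
invasive: the mid-infrared absorbance spectrum of (lyophilized) serum carries
a molecular fingerprint of proteins, lipids and carbohydrates, while the
routine clinical chemistry panel reports ~36 quantitative indicators
(albumin, total protein, lactate dehydrogenase, electrolytes, ...).  Each
modality alone supports a usable but imperfect classifier; this package
implements a fusion pipeline in which both are embedded into one latent
space before classification.

## Method

For a sample with spectrum $x_{\mathrm{FTIR}} \in \mathbb{R}^{d_{\mathrm{FTIR}}}$
(400–4000 cm⁻¹ at 2 cm⁻¹, $d_{\mathrm{FTIR}} = 1801$, replicate-averaged)
and standardized panel $x_{\mathrm{Chem}} \in \mathbb{R}^{36}$:

1. **Per-modality Q/K/V encoding.**  For each attention head, three fully
   connected layers map each modality to query/key/value vectors
   ($d_1 = 32$ for FTIR, $d_2 = 8$ for chemistry), each followed by batch
   normalization $y = \gamma \hat{x} + \beta$, with
   $\hat{x} = (x - \mu_B) / \sqrt{\sigma_B^2 + \varepsilon}$ over the batch.
2. **Dual-path attention.**  The per-modality vectors are concatenated
   ($Q = [Q_{\mathrm{FTIR}}; Q_{\mathrm{Chem}}]$, etc.) and each of the
   $d_1 + d_2 = 40$ latent coordinates is treated as a token of dimension 1:
   $\mathrm{Attention}(Q, K, V) = \mathrm{softmax}(QK^{\top}/\sqrt{d_k})\,V$.
   The diagonal blocks of the row-stochastic weight matrix carry intra-modal
   interactions and the off-diagonal blocks inter-modal ones.  Head outputs
   are averaged and batch-normalized into the final 40-dimensional latent.
3. **Contrastive pre-training.**  With latents $\theta(x_i)$ and labels
   $y_i$, the mean over batch pairs of
   $\mathbb{1}[y_i = y_j]\, D_{ij}^2 + \mathbb{1}[y_i \neq y_j]\,
   \max(0, \epsilon - D_{ij})^2$, $D_{ij} = \lVert\theta(x_i) -
   \theta(x_j)\rVert$, margin $\epsilon = 0.5$, is minimized with Adam
   (lr $10^{-3}$, halved every 60 epochs, 240 epochs, batch size 100).
4. **Classification.**  The encoder is frozen and a shrinkage-regularized
   two-class LDA is fitted on the training latents.  Performance is reported
   as accuracy, sensitivity $\mathrm{TP}/(\mathrm{TP}+\mathrm{FN})$ and
   specificity $\mathrm{TN}/(\mathrm{TN}+\mathrm{FP})$; with balanced test
   classes, accuracy $= (\text{sensitivity} + \text{specificity})/2$.

All splits are made at the **subject** level (a patient may contribute
several samples at different time points), stratified by class, at a
7 : 0.5 : 2.5 train/validation/test ratio.

Because no clinical data are distributed, the package includes a first-class
synthetic cohort generator (36 AML / 24 other-disease / 24 healthy subjects
by default) producing paired spectra (Gaussian vibrational bands with
class-dependent amplitudes, baseline drift, replicate noise) and panels
(class-shifted indicators with a heterogeneous negative class).  The neural
network, its backpropagation and the Adam optimizer are implemented in plain
numpy and verified against finite differences.

## Worked example

```python
import spectrafuse as sf

cohort = sf.generate_cohort(sf.default_config(seed=0))
model = sf.AmlScreeningModel(cohort, train_config=sf.TrainConfig(epochs=60, seed=0))
res = model.fit(split_seed=0)
print(res.summary())
```

```
        AML screening: contrastive encoder + LDA
==========================================================
modality set:      both          latent width: 40
samples (tr/va/te): 117/8/45    subjects: 84
epochs: 60     final train loss: 1.28191  final lr: 1.00e-03
----------------------------------------------------------
test confusion      predicted +   predicted -
  actual +                 20             0
  actual -                  3            22
----------------------------------------------------------
accuracy:     0.933
sensitivity:  1.000
specificity:  0.880
==========================================================
```

The cohort holds 84 subjects (166 samples); contrastive pre-training drove
the mean pair loss from 41.2 to 1.28 over 60 epochs, and the frozen-encoder
LDA classifies the 45 held-out test samples with no missed positives
(sensitivity 1.0) and three false alarms (specificity 0.88).  The repeated
ablation (`spectrafuse ablate`, or `run_ablation` in Python) averages such
trials over many splits and initializations and compares the fused arm
against FTIR-only and chemistry-only encoders.

A CLI mirrors the library:

```bash
spectrafuse simulate --seed 0 --out data/
spectrafuse train    --data data/ --epochs 60 --out run/
spectrafuse ablate   --data data/ --n-splits 5 --n-inits 2 --epochs 60 --out ablation/
spectrafuse visualize --run-dir run/
```

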