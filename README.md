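# ehrdae — patient representation learning from longitudinal EHR sequences

`ehrdae` is a toolkit for clinical-informatics researchers who need fixed-length
patient vectors from variable-length inpatient histories. A patient's record is a
chronological sequence of hospital admissions, each carrying diagnosis codes,
medication-group codes and lab results; most downstream models (SVMs, random
forests, logistic regression) want one fixed vector per patient. The usual fix —
averaging event frequencies over an observation window — throws away the *order*
of events, although a deterioration observed after a stable period means something
very different from the reverse.

The package's core is a **denoising GRU sequence autoencoder**: each admission is
encoded as a multi-hot vector x_t over a fixed clinical vocabulary (with the
default vocabulary of 1232 diagnosis codes, 11 medication groups and 22 lab tests,
each lab test contributing high/low/normal flags, d = 1309). The corrupted
sequence X̃ = X + ε, ε ~ N(0, 0.1), is read by a GRU

    z_t = σ(W_z·[h_{t−1}, x_t])
    r_t = σ(W_r·[h_{t−1}, x_t])
    h̃_t = tanh(W·[r_t ∗ h_{t−1}, x_t])
    h_t = (1 − z_t) ∗ h_{t−1} + z_t ∗ h̃_t

whose final hidden state c = h_n (300-dim by default) summarises the whole
sequence. A second GRU decodes n steps from s_0 = 0 with the constant input c, an
affine + logistic head maps each decoder state back to record space, and training
minimises the summed binary cross-entropy L(X, Y) = −Σ_ij [x_ij log y_ij +
(1−x_ij) log(1−y_ij)] between the *clean* sequence and its reconstruction. The
per-patient "Deep Feature" is [normalized age, gender, c] — 302 dimensions at the
defaults. Setting the noise variance to 0 gives the plain sequence-autoencoder
ablation.

Around the model, the package provides:

- **schema/encoding** — vocabulary definition, multi-hot record encoding, and
  prefix splitting (a patient with n admissions becomes n training samples of its
  first 1…n admissions, each labelled with the patient's final outcome);
- **synthetic cohorts** — a latent-Markov disease-progression simulator
  (stable → worsening → critical) whose in-hospital mortality depends on the final
  state *and* the trajectory slope, calibrated to a 12.1% death rate, ~2.3
  admissions per patient and ten comorbidity labels at heart-failure-cohort
  prevalences, so that every experiment here runs without access to protected
  clinical data;
- **baselines** — order-insensitive window statistics: Hand (elementwise mean),
  PCA scores, k-means centroids, GMM diagonal-covariance vectors;
- **evaluation** — patient-grouped stratified cross-validation for in-hospital
  mortality and ten binary comorbidity tasks (AUC, plus accuracy/F1 at a 0.8
  threshold), NearMiss-1 undersampling for comorbidities rarer than 30%, top-k
  comorbidity accuracy with its theoretical upper bound, and protocol sweeps;
- **similarity analysis** — t-SNE projection of Deep Features, a 30×30 grid over
  the plane, and smoothed block mortality rates H_ij = K_ij / (N_ij + F), F = 5.

## Worked example

The headline experiment — can a sequence encoder beat order-blind statistics when
outcomes genuinely depend on event order? — runs in a few minutes on a laptop:

```python
from ehrdae import experiments

res = experiments.mortality_comparison(n_patients=2000, seeds=(0, 1, 2))
for k in ("deep", "hand", "rnn_ae"):
    vals = " ".join(f"{v:.3f}" for v in res[k])
    print(f"{k:7s} per-seed AUC: {vals}   median: {res['median'][k]:.3f}")
```

prints

```
deep    per-seed AUC: 0.636 0.610 0.655   median: 0.636
hand    per-seed AUC: 0.542 0.539 0.566   median: 0.542
rnn_ae  per-seed AUC: 0.626 0.603 0.647   median: 0.626
```

Each line is the 5-fold patient-grouped cross-validated AUC of an SVM predicting
in-hospital death from one representation, over three simulated 2,000-patient
cohorts. Deep Features (denoising autoencoder) rank patients best; the noise-free
ablation (`rnn_ae`) trails slightly; the Hand average — identical for any
permutation of a patient's records — cannot see the trajectory direction that
partly drives mortality here, and lands far lower.

The same stages are scriptable from the shell:

```bash
ehrdae simulate --n-patients 500 --seed 7 --output patients.jsonl
ehrdae train --input patients.jsonl --latent-dim 32 --epochs 50 --seed 0 --output model.npz
ehrdae featurize --model model.npz --input patients.jsonl --output deep.csv
ehrdae eval-mortality --features deep.csv --labels patients.jsonl --report mortality.csv
ehrdae heatmap --features deep.csv --labels patients.jsonl --grid 30 --table blocks.csv
```

`ehrdae run --config run.yaml` executes the whole pipeline (simulate → encode →
train → featurize → baselines → evaluations → heatmap) with one global seed
fanned out to per-stage seeds; see `ehrdae.pipeline.RunConfig` for the keys.

## Layout

```
src/ehrdae/
  schema.py       vocabulary, multi-hot encoding, prefix splitting
  synthetic.py    latent-Markov cohort simulator
  dae.py          the denoising GRU autoencoder (numpy, manual gradients)
  baselines.py    Hand / PCA / k-means / GMM window representations
  evaluate.py     CV protocols, metrics, NearMiss-1, top-k, sweeps
  heatmap.py      t-SNE + grid mortality rates
  experiments.py  packaged end-to-end protocols
  pipeline.py     run configuration, seed fan-out, stage orchestration
  cli.py          the `ehrdae` command
docs/methods.md   modelling assumptions, defaults, limitations
```
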