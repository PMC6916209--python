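# Methods

This note records the modelling assumptions, default parameters and design
choices behind `ehrdae`, in the spirit of a model-documentation page: what the
procedures assume, which knobs matter, what the synthetic data does and does not
emulate, and where the genuinely open choices were made.

## Record encoding

An admission is encoded as a binary multi-hot vector partitioned as
`[diagnoses | medication groups | lab flags]` in schema order. Each lab test
owns three mutually exclusive flag dimensions (high / low / normal) derived
from its reference interval; a missing lab value sets none of the three. The
default full-scale vocabulary (1232 diagnosis codes, 11 medication groups, 22
lab tests) gives a clinical dimension d = 1232 + 11 + 66 = 1309 and a raw
record dimension of 1311 once normalized age and gender are appended.

Choices worth stating:

- **Reference-interval boundaries are inclusive**: a value exactly on a bound
  is `normal`. Flagging a healthy boundary value as pathological would inflate
  the abnormal-flag rate for analytes routinely reported at interval edges.
- **Unknown codes are skipped with a logged warning** by default; a strict mode
  raises instead. Real EHR extracts are noisy, and silently *counting* unknown
  events (e.g. into a rest bucket) would change d across sites.
- **Age normalization** is min–max over 0–120 years, clipping out-of-range
  values. The bounds are fixed constants of the schema so that encodings are
  comparable across cohorts.
- **Equal admission dates** keep their input order (stable sort). There is no
  principled tiebreak without intraday timestamps.
- **Prefix splitting** turns a patient with n admissions into n samples holding
  the first 1…n admissions. Every prefix inherits the patient's *final*
  in-hospital death flag and comorbidity set: prefix samples are meant to ask
  "what could have been predicted after admission k about this patient's
  eventual outcome", and final-outcome labelling is the only scheme consistent
  with one-sample-per-record accounting.

## The synthetic cohort generator

The generator exists so that every experiment in the package runs with no
access to protected clinical data, while preserving the statistical property
the method comparison depends on: **outcomes must depend on event order**, not
only on event frequencies, otherwise a sequence encoder has nothing to win.

Each patient follows a first-order Markov chain over three latent severity
states (stable, worsening, critical; default transition rows (0.70, 0.25,
0.05), (0.25, 0.50, 0.25), (0.10, 0.30, 0.60); initial distribution (0.70,
0.20, 0.10)). Admission counts are 1 + Poisson(mean − 1) truncated at 10, with
the mean of 2.3 chosen so that a 4,682-patient cohort yields roughly 10,900
records. Inter-admission gaps are uniform on 10–200 days, wide enough that
observation windows of 30/60/90/180 days actually discriminate.

Per admission, the current state tilts emissions: diagnosis codes are drawn
from a state-specific block (80% of probability mass on the own-state block),
medication groups are Bernoulli with per-state rates (0.12 / 0.25 / 0.45), and
lab values are Gaussian around the reference-interval centre shifted upward by
0 / 0.45 / 0.95 half-widths, so critical admissions carry more `high` flags.
Ten comorbidity labels are drawn independently at the prevalences of the
emulated heart-failure cohort (hypertension 0.694 down to valvular heart
disease 0.008); a patient's comorbidities leak a marker diagnosis code into
each admission with probability 0.8, which is what makes the comorbidity
prediction tasks learnable.

**Mortality** is Bernoulli with logit = intercept + w_state[final state] +
1.5·(final state − first state), w_state = (0, 1.0, 2.5). The slope term is the
deliberate order signal: two patients with the same multiset of admissions but
opposite trajectory directions get different death risks, so order-insensitive
features are structurally handicapped. The intercept is calibrated by bisection
so the expected cohort death rate is 12.1%. `order_sensitivity_probe` measures
the resulting ascending-vs-descending death-prevalence gap on matched
record-count strata (≈ +0.36 under defaults).

What the generator does **not** emulate: ICD-10 semantics or hierarchy, visit
seasonality, coding drift, missing-not-at-random labs, censoring, or any
correlation structure among comorbidities. Passing tests on this cohort show
that the pipeline recovers order signal where it exists and that the metrics
and protocols are implemented correctly — not that the learned representations
would reach any particular performance on real hospital data.

## The denoising sequence autoencoder

Both GRUs follow bias-free gate equations acting on the concatenation
`[state, input]`; biases can be enabled by config but default to off, matching
the minimal printed form of the model. Initial states are zero. The decoder
receives the latent vector c as a *constant input* at every step — there is no
autoregressive feedback and no teacher forcing — and reconstructs the sequence
in forward order. Since decoder states live in latent space but the loss needs
record-space probabilities, an affine map D→d with logistic squashing closes
the dimension gap; this output head is the minimal reconciliation of a
latent-width decoder with a d-dimensional cross-entropy target.

Training corrupts encoder inputs with fresh additive Gaussian noise (mean 0,
variance 0.1) at every presentation; the reconstruction target is always the
clean sequence — that pairing is the definition of *denoising*. Variance 0
yields the plain autoencoder ablation. Variable-length batches are padded with
zero rows; padded steps freeze the encoder state and are masked out of the
loss, so padding is mathematically invisible.

Numerical choices: cross-entropy probabilities are clamped to [1e−7, 1−1e−7];
the sigmoid is evaluated in its numerically stable split form; divergence
(non-finite loss) aborts with a diagnostic rather than continuing.

Optimisation is Adam at learning rate 1e−3, mini-batches of 100, 50 epochs by
default, all seeded; gradients are hand-derived backpropagation through both
GRUs and the head, and are verified against central finite differences in the
test suite (the verification is the reason the model can be pure numpy — no
autodiff framework is required at desk scale). Per-epoch mean loss is logged
on the model object. Training-length note: latent-state probes showed that 15
epochs leaves the encoder visibly under-trained on the default cohort (the
final-severity information in c jumps markedly between 15 and 40–50 epochs),
so packaged experiments use the 50-epoch default.

At inference the encoder reads the **clean** tensor. The Deep Feature is
[normalized age, gender, c]; demographics are appended rather than fed to the
encoder because their effect on clinical endpoints is strong enough to swamp
the event-sequence signal during reconstruction learning.

## Baselines

Window-based statistics anchor the observation window at the last admission
(inclusive), the only anchor available at prediction time. Records inside the
window are aggregated by elementwise mean — exactly the "Hand" feature — with
sum/max available by flag; PCA, k-means and GMM are then single unsupervised
transformations of the aggregate (scores, assigned centroid, and the diagonal
covariance of the most responsible mixture component, respectively). Study-
scale hyperparameters are 512 PCA components, 16 clusters, 512 mixture
components; the small synthetic vocabulary (d = 137) uses 32/16/32 presets
since 512 components would exceed its dimensionality.

Representation models — the autoencoder and the baselines alike — are fitted
unsupervised on the full sample set; labels never touch the representation
stage, and only the downstream classifier is cross-validated. This mirrors the
two-stage design in which 10,898 unlabelled samples feed representation
learning once, and supervised evaluation happens on top.

## Evaluation protocols

Cross-validation is stratified 5-fold at the **patient** level: all prefix
samples of a patient share a fold, otherwise a patient's own earlier
admissions would leak across the split. AUC is computed from midranks (exactly
the all-pairs probability with ties at ½); accuracy and F1 are computed at the
fixed decision threshold of 0.8 on predicted probabilities (for the SVM this
means Platt scaling; when only AUC is requested the SVM's decision margins are
used directly and calibration is skipped).

NearMiss-1 undersampling (keep all minority samples; keep the majority samples
with the smallest mean distance to their 3 nearest minority neighbours until
the classes balance) is applied on training folds of comorbidity tasks whose
positive prevalence is below 30%. The mortality task runs on the natural class
balance: rebalancing is a rare-outcome device for the comorbidity tasks, and
in our experiments NearMiss-1's preference for boundary-hugging majority
samples actively degrades the RBF-SVM's ranking on latent features.

Top-k comorbidity accuracy takes, per patient, the k highest out-of-fold
scores across tasks and counts the fraction that are truly present; patients
with no comorbidities are excluded from the mean. The theoretical upper bound
averages min(|true|, k)/k — strictly below 1 whenever some patient has fewer
than k comorbidities, which is why even a perfect classifier cannot reach
top-3 accuracy 1.0. Method comparisons across tasks use average ranks with
midrank ties.

## Similarity heatmap

Deep Features are projected to 2-D by t-SNE (perplexity 30, PCA
initialisation, fixed seed — the embedding is only reproducible *given* the
seed). The plane's bounding box is split into 30×30 equal-width blocks,
right-open except the top edge so every point lands in a block; whether to
trim outliers before gridding is left to the caller, as the bounding box is
the only parameter-free choice. Block mortality is smoothed as
H = K/(N + F) with F = 5, which keeps a block containing a single dead record
at 1/6 instead of a misleading 1.0; F = 0 recovers the raw rate.

## Problem sizes in packaged experiments

The packaged protocols run at deliberately desk-sized scales: 2,000-patient
cohorts (≈ 4,700 prefix samples), a 137-dim synthetic vocabulary, latent
dimension 32, 50 training epochs, three seeds for the mortality comparison,
and an 800-patient cohort for the top-k protocol. These sizes were chosen so
a full reproduction completes in minutes on one CPU while keeping every
qualitative conclusion (order sensitivity, method ordering, bound behaviour)
stable across seeds; the full-scale 1232-code schema and 300-dim latent are
presets away and change no code path.

## Known limitations

- The decoder's constant-input design reconstructs forward with no
  autoregression; it is a representation-shaping device, not a generative
  model of admissions.
- The synthetic cohort's comorbidities are independent Bernoulli draws;
  real comorbidity co-occurrence would change undersampling geometry and
  top-k bounds.
- AUC differences between representations at these scales have seed-level
  noise of a few hundredths; conclusions are stated on medians over seeds.
- t-SNE block counts depend on the embedding's bounding box, so grids are
  comparable only within one embedding, not across seeds.
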