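"""Pre-packaged experiment protocols over the synthetic study conditions.

These functions wire the full pipeline together for the package's headline
analyses: the mortality-prediction comparison between sequence-learned
Deep Features and order-insensitive Hand features (with the noise-free
autoencoder ablation), the order-sensitivity census of a trained encoder,
and the comorbidity top-k protocol.  They exist so that scripted runs and
the test suite execute the exact same procedure.
"""

from __future__ import annotations

import numpy as np

from . import baselines, dae, evaluate, synthetic
from .schema import split_cohort


def mortality_comparison(
    n_patients: int = 2000,
    seeds: tuple[int, ...] = (0, 1, 2),
    latent_dim: int = 32,
    epochs: int = 50,
    include_ablation: bool = True,
    classifier: str = "svm",
) -> dict:
    """Cross-validated mortality AUC of Deep vs Hand features over seeds.

    For each seed: simulate a cohort, prefix-split, train the denoising
    autoencoder (and optionally its noise-free ablation) unsupervised on
    all samples, then compare representations with a patient-grouped
    cross-validated classifier.  The mortality task runs on the natural
    class balance (undersampling belongs to the rare-comorbidity protocol,
    not here).  Returns per-seed AUCs and medians.
    """
    out: dict = {"deep": [], "hand": []}
    if include_ablation:
        out["rnn_ae"] = []
    for seed in seeds:
        cohort = synthetic.generate_cohort(
            synthetic.CohortConfig(n_patients=n_patients, seed=seed)
        )
        samples = split_cohort(cohort.patients, cohort.schema)
        tensors = [s.tensor for s in samples]
        died = np.array([s.died for s in samples])
        pid = np.array([s.patient_id for s in samples])
        ecfg = evaluate.EvalConfig(
            classifier=classifier, metrics=("auc",), seed=seed, undersampler="none"
        )

        model = dae.train(
            tensors,
            dae.DaeConfig(latent_dim=latent_dim, epochs=epochs, seed=seed),
            schema_fingerprint=cohort.schema.fingerprint(),
        )
        F = dae.sample_deep_features(samples, model, cohort.schema)
        out["deep"].append(evaluate.evaluate_mortality(F, died, pid, ecfg).auc)

        rec = {p.patient_id: p.records for p in cohort.patients}
        F = baselines.baseline_features(samples, rec, cohort.schema, "hand")
        out["hand"].append(evaluate.evaluate_mortality(F, died, pid, ecfg).auc)

        if include_ablation:
            ae = dae.train(
                tensors,
                dae.DaeConfig.autoencoder(latent_dim=latent_dim, epochs=epochs, seed=seed),
                schema_fingerprint=cohort.schema.fingerprint(),
            )
            F = dae.sample_deep_features(samples, ae, cohort.schema)
            out["rnn_ae"].append(evaluate.evaluate_mortality(F, died, pid, ecfg).auc)

    return {
        **{k: list(map(float, v)) for k, v in out.items()},
        "median": {k: float(np.median(v)) for k, v in out.items()},
        "n_patients": n_patients,
        "seeds": list(seeds),
    }


def order_sensitivity_census(model: dae.TrainedModel, samples, limit: int = 200) -> float:
    """Fraction of multi-record samples whose latent code changes under
    record-order reversal."""
    multi = [s for s in samples if s.prefix_length >= 2][:limit]
    if not multi:
        raise ValueError("no multi-record samples")
    changed = 0
    for s in multi:
        a = dae.encode_sequence(s.tensor, model.encoder)
        b = dae.encode_sequence(s.tensor[::-1], model.encoder)
        changed += not np.allclose(a, b, atol=1e-8)
    return changed / len(multi)


def comorbidity_topk(
    n_patients: int = 800,
    seed: int = 0,
    latent_dim: int = 32,
    epochs: int = 50,
    classifier: str = "lr",
    ks: tuple[int, ...] = (1, 2, 3),
) -> dict:
    """Deep-Feature comorbidity top-k accuracies with their upper bounds."""
    import pandas as pd

    cohort = synthetic.generate_cohort(
        synthetic.CohortConfig(n_patients=n_patients, seed=seed)
    )
    samples = split_cohort(cohort.patients, cohort.schema)
    model = dae.train(
        [s.tensor for s in samples],
        dae.DaeConfig(latent_dim=latent_dim, epochs=epochs, seed=seed),
        schema_fingerprint=cohort.schema.fingerprint(),
    )
    F = dae.sample_deep_features(samples, model, cohort.schema)
    pid = np.array([s.patient_id for s in samples])
    names = sorted({c for s in samples for c in s.comorbidities})
    labels = pd.DataFrame({c: [int(c in s.comorbidities) for s in samples] for c in names})
    results, scores = evaluate.evaluate_comorbidity(
        F, labels, pid, evaluate.EvalConfig(classifier=classifier, seed=seed)
    )
    cols = [j for j, c in enumerate(names) if c in results]
    kept = [names[j] for j in cols]
    sub = scores[:, cols]
    ok = np.all(np.isfinite(sub), axis=1)
    true_sets = [
        {kept.index(c) for c in s.comorbidities if c in kept} for s in samples
    ]
    out = {"auc": {t: r.auc for t, r in results.items()}}
    for k in ks:
        r = evaluate.topk_comorbidity(
            sub[ok], [t for t, o in zip(true_sets, ok) if o], k
        )
        out[f"top{k}"] = {"accuracy": r.accuracy, "upper_bound": r.upper_bound}
    return out
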