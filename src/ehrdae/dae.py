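"""Denoising GRU sequence autoencoder ("RNN-DAE") for patient representation.

The model reads a patient's chronological multi-hot records
X = (x_1, ..., x_n), corrupts them with additive Gaussian noise
X̃ ~ q_D(X̃ | X), and encodes X̃ with a GRU whose final hidden state is the
patient vector c.  A second GRU decodes n steps from s_0 = 0 with the
*constant* input c (no autoregressive feedback), and an affine map with
logistic squashing projects each decoder state s_t back to record space,
y_t ∈ (0,1)^d.  Training minimises the summed binary cross-entropy between
the clean X and the reconstruction Y, so the last hidden state is forced to
summarise the whole admission sequence — including its order — robustly to
input noise.  The per-patient "Deep Feature" is [normalized age, gender, c]
(302 dimensions at the default latent size of 300).

Both GRUs follow the bias-free gate equations

    z_t = σ(W_z · [h_{t-1}, x_t])        (update gate)
    r_t = σ(W_r · [h_{t-1}, x_t])        (reset gate)
    h̃_t = tanh(W · [r_t ∗ h_{t-1}, x_t])
    h_t = (1 − z_t) ∗ h_{t-1} + z_t ∗ h̃_t

with the decoder reading [s_{t-1}, c].  Optional biases are available via
config.  Implemented directly in numpy with hand-derived gradients (checked
against finite differences in the test suite) and Adam updates.

Setting the noise variance to 0 yields the plain sequence autoencoder
ablation ("RNN-AE").
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .schema import EncodingSchema, PatientHistory, Sample, encode_patient, normalize_age

EPS_CLAMP = 1e-7  # cross-entropy clamp


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class GRUParams:
    """Gate weight matrices, each (hidden, hidden + input); optional biases."""

    W_z: np.ndarray
    W_r: np.ndarray
    W: np.ndarray
    b_z: np.ndarray | None = None
    b_r: np.ndarray | None = None
    b_h: np.ndarray | None = None

    @property
    def hidden_size(self) -> int:
        return self.W_z.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_z.shape[1] - self.W_z.shape[0]

    def check_finite(self) -> None:
        for m in (self.W_z, self.W_r, self.W):
            if not np.all(np.isfinite(m)):
                raise FloatingPointError("non-finite GRU parameters")


@dataclass
class GRUState:
    """One cell step's outputs; gates exposed for testing."""

    h: np.ndarray
    z: np.ndarray
    r: np.ndarray
    candidate: np.ndarray


@dataclass
class NoiseSpec:
    """Additive Gaussian corruption of encoder inputs."""

    mean: float = 0.0
    variance: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("noise variance must be >= 0")


@dataclass
class OutputProjection:
    """Affine map latent→record space followed by logistic squashing."""

    P: np.ndarray  # (d, D)
    b: np.ndarray  # (d,)

    def __call__(self, s: np.ndarray) -> np.ndarray:
        return _sigmoid(s @ self.P.T + self.b)


@dataclass
class DaeConfig:
    latent_dim: int = 300
    noise_mean: float = 0.0
    noise_variance: float = 0.1
    batch_size: int = 100
    epochs: int = 50
    learning_rate: float = 1e-3
    use_bias: bool = False
    seed: int = 0

    @classmethod
    def autoencoder(cls, **kw) -> "DaeConfig":
        """The noise-free ablation (plain sequence autoencoder)."""
        kw.setdefault("noise_variance", 0.0)
        return cls(**kw)


@dataclass
class TrainedModel:
    encoder: GRUParams
    decoder: GRUParams
    projection: OutputProjection
    noise: NoiseSpec
    config: DaeConfig
    training_log: list = field(default_factory=list)  # per-epoch mean loss
    schema_fingerprint: str = ""

    @property
    def latent_dim(self) -> int:
        return self.encoder.hidden_size


# --------------------------------------------------------------------------
# primitives
# --------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def gru_cell(x: np.ndarray, prev: np.ndarray, params: GRUParams) -> GRUState:
    """One GRU step.  Accepts vectors (single step) or (batch, dim) arrays."""
    x = np.asarray(x, dtype=np.float64)
    prev = np.asarray(prev, dtype=np.float64)
    H, I = params.hidden_size, params.input_size
    if x.shape[-1] != I or prev.shape[-1] != H:
        raise ValueError(
            f"shape mismatch: input dim {x.shape[-1]} (expected {I}), "
            f"state dim {prev.shape[-1]} (expected {H})"
        )
    cat = np.concatenate([prev, x], axis=-1)
    z = _sigmoid(cat @ params.W_z.T + (params.b_z if params.b_z is not None else 0.0))
    r = _sigmoid(cat @ params.W_r.T + (params.b_r if params.b_r is not None else 0.0))
    cat_r = np.concatenate([r * prev, x], axis=-1)
    cand = np.tanh(cat_r @ params.W.T + (params.b_h if params.b_h is not None else 0.0))
    h = (1.0 - z) * prev + z * cand
    return GRUState(h=h, z=z, r=r, candidate=cand)


def corrupt(X: np.ndarray, noise: NoiseSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Add i.i.d. Gaussian noise to a tensor; exact copy when variance is 0."""
    X = np.asarray(X, dtype=np.float64)
    if noise.variance == 0.0 and noise.mean == 0.0:
        return X.copy()
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    return X + rng.normal(noise.mean, np.sqrt(noise.variance), size=X.shape)


def encode_sequence(X: np.ndarray, params: GRUParams) -> np.ndarray:
    """Run the encoder over an (n, d) sequence from h_0 = 0; returns c = h_n."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    if X.shape[0] < 1:
        raise ValueError("cannot encode an empty sequence")
    h = np.zeros(params.hidden_size)
    for t in range(X.shape[0]):
        h = gru_cell(X[t], h, params).h
    return h


def decode_sequence(
    c: np.ndarray, n: int, params: GRUParams, projection: OutputProjection
) -> np.ndarray:
    """Decode n steps from s_0 = 0 with constant input c; returns (n, d) in (0,1)."""
    if n < 1:
        raise ValueError("number of decoding steps must be >= 1")
    c = np.asarray(c, dtype=np.float64)
    s = np.zeros(params.hidden_size)
    out = []
    for _ in range(n):
        s = gru_cell(c, s, params).h
        out.append(projection(s))
    return np.stack(out)


def reconstruction_loss(X: np.ndarray, Y: np.ndarray, eps: float = EPS_CLAMP) -> float:
    """Summed binary cross-entropy between clean X and reconstruction Y."""
    X = np.asarray(X, dtype=np.float64)
    Y = np.clip(np.asarray(Y, dtype=np.float64), eps, 1.0 - eps)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch {X.shape} vs {Y.shape}")
    return float(-np.sum(X * np.log(Y) + (1.0 - X) * np.log(1.0 - Y)))


# --------------------------------------------------------------------------
# batched forward/backward (training internals)
# --------------------------------------------------------------------------

def _init_params(rng: np.random.Generator, hidden: int, inp: int, use_bias: bool) -> GRUParams:
    def glorot(h, w):
        lim = np.sqrt(6.0 / (h + w))
        return rng.uniform(-lim, lim, size=(h, w))

    b = (lambda: np.zeros(hidden)) if use_bias else (lambda: None)
    return GRUParams(
        W_z=glorot(hidden, hidden + inp),
        W_r=glorot(hidden, hidden + inp),
        W=glorot(hidden, hidden + inp),
        b_z=b(), b_r=b(), b_h=b(),
    )


def _pad_batch(tensors: list[np.ndarray], d: int) -> tuple[np.ndarray, np.ndarray]:
    """Stack variable-length (n_i, d) tensors into (B, T, d) plus a (B, T) mask."""
    B = len(tensors)
    T = max(t.shape[0] for t in tensors)
    X = np.zeros((B, T, d))
    mask = np.zeros((B, T))
    for i, t in enumerate(tensors):
        X[i, : t.shape[0]] = t
        mask[i, : t.shape[0]] = 1.0
    return X, mask


def _forward_backward(
    Xc: np.ndarray,  # corrupted encoder input (B, T, d)
    X: np.ndarray,   # clean reconstruction target (B, T, d)
    mask: np.ndarray,
    enc: GRUParams,
    dec: GRUParams,
    proj: OutputProjection,
    use_bias: bool,
) -> tuple[float, dict]:
    """Mean-per-sample masked loss and gradients for all parameters."""
    B, T, d = X.shape
    H = enc.hidden_size
    m = mask[..., None]  # (B, T, 1)

    # ---- encoder forward (masked: padded steps freeze the state) ----
    h = np.zeros((B, H))
    enc_cache = []
    for t in range(T):
        st = gru_cell(Xc[:, t], h, enc)
        h_new = m[:, t] * st.h + (1.0 - m[:, t]) * h
        enc_cache.append((h, st.z, st.r, st.candidate))
        h = h_new
    c = h  # (B, H)

    # ---- decoder forward (constant input c) ----
    s = np.zeros((B, H))
    dec_cache = []
    S = np.empty((B, T, H))
    for t in range(T):
        st = gru_cell(c, s, dec)
        dec_cache.append((s, st.z, st.r, st.candidate))
        s = st.h
        S[:, t] = s

    logits = S @ proj.P.T + proj.b  # (B, T, d)
    Y = _sigmoid(logits)
    Yc = np.clip(Y, EPS_CLAMP, 1.0 - EPS_CLAMP)
    ce = -(X * np.log(Yc) + (1.0 - X) * np.log(1.0 - Yc)) * m
    loss = float(ce.sum() / B)

    # ---- backward ----
    grads = {
        "enc_W_z": np.zeros_like(enc.W_z), "enc_W_r": np.zeros_like(enc.W_r),
        "enc_W": np.zeros_like(enc.W),
        "dec_W_z": np.zeros_like(dec.W_z), "dec_W_r": np.zeros_like(dec.W_r),
        "dec_W": np.zeros_like(dec.W),
        "proj_P": np.zeros_like(proj.P), "proj_b": np.zeros_like(proj.b),
    }
    if use_bias:
        for k in ("enc_b_z", "enc_b_r", "enc_b_h", "dec_b_z", "dec_b_r", "dec_b_h"):
            grads[k] = np.zeros(H)

    dlogits = (Y - X) * m / B  # (B, T, d)
    grads["proj_P"] = np.einsum("btd,bth->dh", dlogits, S)
    grads["proj_b"] = dlogits.sum(axis=(0, 1))
    dS = dlogits @ proj.P  # (B, T, H)

    def _cell_backward(dh_out, prev, z, r, cand, x, params, prefix):
        """Returns (d_prev, d_x); accumulates weight grads in `grads`."""
        dz = dh_out * (cand - prev)
        dcand = dh_out * z
        d_prev = dh_out * (1.0 - z)
        da_h = dcand * (1.0 - cand ** 2)
        grads[prefix + "_W"] += np.concatenate(
            [da_h.T @ (r * prev), da_h.T @ x], axis=1
        )
        d_rp = da_h @ params.W[:, :H]
        d_x = da_h @ params.W[:, H:]
        dr = d_rp * prev
        d_prev += d_rp * r
        da_r = dr * r * (1.0 - r)
        grads[prefix + "_W_r"] += np.concatenate([da_r.T @ prev, da_r.T @ x], axis=1)
        d_prev += da_r @ params.W_r[:, :H]
        d_x += da_r @ params.W_r[:, H:]
        da_z = dz * z * (1.0 - z)
        grads[prefix + "_W_z"] += np.concatenate([da_z.T @ prev, da_z.T @ x], axis=1)
        d_prev += da_z @ params.W_z[:, :H]
        d_x += da_z @ params.W_z[:, H:]
        if use_bias:
            grads[prefix + "_b_h"] += da_h.sum(0)
            grads[prefix + "_b_r"] += da_r.sum(0)
            grads[prefix + "_b_z"] += da_z.sum(0)
        return d_prev, d_x

    # decoder: gradient flows into states and, through the constant input, into c
    dc = np.zeros((B, H))
    ds = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        ds = ds + dS[:, t]
        prev, z, r, cand = dec_cache[t]
        ds, dx = _cell_backward(ds, prev, z, r, cand, c, dec, "dec")
        dc += dx

    # encoder: gradient enters only through c = h_T
    dh = dc
    for t in range(T - 1, -1, -1):
        prev, z, r, cand = enc_cache[t]
        dh_masked = dh * m[:, t]
        d_prev, _ = _cell_backward(dh_masked, prev, z, r, cand, Xc[:, t], enc, "enc")
        dh = d_prev + dh * (1.0 - m[:, t])

    return loss, grads


class _Adam:
    def __init__(self, params: dict, lr: float):
        self.lr = lr
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, b1=0.9, b2=0.999, eps=1e-8) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _param_dict(enc: GRUParams, dec: GRUParams, proj: OutputProjection, use_bias: bool) -> dict:
    p = {
        "enc_W_z": enc.W_z, "enc_W_r": enc.W_r, "enc_W": enc.W,
        "dec_W_z": dec.W_z, "dec_W_r": dec.W_r, "dec_W": dec.W,
        "proj_P": proj.P, "proj_b": proj.b,
    }
    if use_bias:
        p.update({
            "enc_b_z": enc.b_z, "enc_b_r": enc.b_r, "enc_b_h": enc.b_h,
            "dec_b_z": dec.b_z, "dec_b_r": dec.b_r, "dec_b_h": dec.b_h,
        })
    return p


# --------------------------------------------------------------------------
# training and feature extraction
# --------------------------------------------------------------------------

def train(
    tensors: list[np.ndarray],
    config: DaeConfig | None = None,
    schema_fingerprint: str = "",
) -> TrainedModel:
    """Fit the denoising autoencoder on a list of (n_i, d) record tensors.

    Encoder inputs are corrupted with fresh Gaussian noise every epoch; the
    clean tensor is always the reconstruction target.  Per-epoch mean loss
    (summed cross-entropy per sample, masked to true lengths) is logged.
    Deterministic under ``config.seed``.
    """
    config = config or DaeConfig()
    if not tensors:
        raise ValueError("no training samples")
    if config.latent_dim < 1:
        raise ValueError("latent_dim must be >= 1")
    d = tensors[0].shape[1]
    rng = np.random.default_rng(config.seed)
    enc = _init_params(rng, config.latent_dim, d, config.use_bias)
    dec = _init_params(rng, config.latent_dim, config.latent_dim, config.use_bias)
    lim = np.sqrt(6.0 / (d + config.latent_dim))
    proj = OutputProjection(
        P=rng.uniform(-lim, lim, size=(d, config.latent_dim)), b=np.zeros(d)
    )
    noise = NoiseSpec(config.noise_mean, config.noise_variance)
    params = _param_dict(enc, dec, proj, config.use_bias)
    opt = _Adam(params, config.learning_rate)

    n = len(tensors)
    log: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        total, seen = 0.0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = [tensors[i] for i in idx]
            X, mask = _pad_batch(batch, d)
            Xc = corrupt(X, noise, rng=rng)
            loss, grads = _forward_backward(
                Xc, X, mask, enc, dec, proj, config.use_bias
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged (non-finite loss at epoch {_epoch})"
                )
            opt.step(params, grads)
            total += loss * len(idx)
            seen += len(idx)
        log.append(total / seen)

    return TrainedModel(
        encoder=enc, decoder=dec, projection=proj, noise=noise,
        config=config, training_log=log, schema_fingerprint=schema_fingerprint,
    )


def encode_batch(tensors: list[np.ndarray], model: TrainedModel) -> np.ndarray:
    """Encode clean tensors (no corruption at inference); returns (N, D)."""
    d = tensors[0].shape[1]
    out = np.empty((len(tensors), model.latent_dim))
    B = 512
    for start in range(0, len(tensors), B):
        chunk = tensors[start : start + B]
        X, mask = _pad_batch(chunk, d)
        m = mask[..., None]
        h = np.zeros((len(chunk), model.latent_dim))
        for t in range(X.shape[1]):
            st = gru_cell(X[:, t], h, model.encoder)
            h = m[:, t] * st.h + (1.0 - m[:, t]) * h
        out[start : start + B] = h
    return out


def deep_feature(
    patient: PatientHistory, model: TrainedModel, schema: EncodingSchema
) -> np.ndarray:
    """[normalized age, gender, c] for one patient (default length 302)."""
    if model.schema_fingerprint and model.schema_fingerprint != schema.fingerprint():
        raise ValueError("model was trained under a different encoding schema")
    X = encode_patient(patient, schema)
    c = encode_sequence(X, model.encoder)
    return np.concatenate([[normalize_age(patient.age, schema), float(patient.gender)], c])


def sample_deep_features(
    samples: list[Sample], model: TrainedModel, schema: EncodingSchema
) -> np.ndarray:
    """Deep Features for prefix samples, batched; returns (N, D + 2)."""
    if model.schema_fingerprint and model.schema_fingerprint != schema.fingerprint():
        raise ValueError("model was trained under a different encoding schema")
    C = encode_batch([s.tensor for s in samples], model)
    demo = np.array(
        [[normalize_age(s.age, schema), float(s.gender)] for s in samples]
    )
    return np.hstack([demo, C])


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    """Persist parameters + config + training log as a .npz archive."""
    arrays = dict(_param_dict(model.encoder, model.decoder, model.projection,
                              model.config.use_bias))
    meta = {
        "config": asdict(model.config),
        "noise": asdict(model.noise),
        "training_log": model.training_log,
        "schema_fingerprint": model.schema_fingerprint,
    }
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        a = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = DaeConfig(**meta["config"])
    bias = cfg.use_bias
    enc = GRUParams(a["enc_W_z"], a["enc_W_r"], a["enc_W"],
                    *( (a["enc_b_z"], a["enc_b_r"], a["enc_b_h"]) if bias else (None,)*3 ))
    dec = GRUParams(a["dec_W_z"], a["dec_W_r"], a["dec_W"],
                    *( (a["dec_b_z"], a["dec_b_r"], a["dec_b_h"]) if bias else (None,)*3 ))
    proj = OutputProjection(P=a["proj_P"], b=a["proj_b"])
    return TrainedModel(
        encoder=enc, decoder=dec, projection=proj,
        noise=NoiseSpec(**meta["noise"]), config=cfg,
        training_log=list(meta["training_log"]),
        schema_fingerprint=meta["schema_fingerprint"],
    )
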