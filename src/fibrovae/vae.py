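"""Multimodal variational autoencoder and patient anomaly scoring.

The model learns the distribution of typical multimodal patient profiles
x in R^d (z-scored clinical variables concatenated with imaging embeddings)
through a Gaussian-latent VAE:

* encoder  q(z|x) = N(mu(x), diag sigma^2(x)),  x -> 256 -> 128 -> (mu, log sigma^2),
* latent   z in R^k with k = 8  (k << d, limiting capacity on a small cohort),
* decoder  p(x|z) = N(g(z), I),  z -> 128 -> 256 -> x_hat, linear output,
* objective (beta-ELBO, minimized):
      L = E_q ||x - x_hat||^2  +  beta * KL(q(z|x) || N(0, I)).

The per-patient anomaly score is the same quantity evaluated at score time,

      A(x) = ||x - x_hat||^2 + beta * KL(q(z|x) || N(0, I)),

with the deterministic mean-latent pass (x_hat = g(mu(x))) by default.  High
scores mark patients whose joint clinical-imaging profile deviates from the
learned cohort manifold.

Training is plain Adam over mini-batches with one Monte-Carlo latent sample
per input, a fixed seed controlling initialization, shuffling and sampling,
no validation split and no early stopping.  All numerics are numpy; the
network is small enough (d ~ 526, n ~ 41) that this trains in seconds.
Exact reproducibility is guaranteed for serial execution with a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (
    MultimodalMatrix,
    NormalizationStats,
    build_multimodal_matrix,
    encode_binaries,
    fit_normalizer,
)

__all__ = [
    "VAEConfig",
    "LatentPosterior",
    "TrainedVAE",
    "encode",
    "decode",
    "reparameterize",
    "kl_divergence",
    "elbo_loss",
    "train",
    "anomaly_score",
    "MultimodalVAE",
    "VAEResults",
]


@dataclass(frozen=True)
class VAEConfig:
    """Hyperparameters of the multimodal VAE.

    Defaults are the study settings: hidden layers 256/128, latent k = 8,
    beta = 1.0, Adam with learning rate 1e-3, batch size 8, 200 epochs, one
    Monte-Carlo latent sample per training input.
    """

    hidden_dims: tuple[int, int] = (256, 128)
    latent_dim: int = 8
    beta: float = 1.0
    learning_rate: float = 1e-3
    batch_size: int = 8
    epochs: int = 200
    seed: int = 0
    mc_samples_train: int = 1
    score_mode: str = "mean-latent"  # or "sampled"
    mc_samples_score: int = 32
    # Global L2 gradient-norm clip.  Stabilizes Adam against the very large
    # squared-error gradients that extreme multimodal outliers produce in
    # small batches; set to None to disable.
    grad_clip: float | None = 5.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.score_mode not in ("mean-latent", "sampled"):
            raise ValueError(f"unknown score_mode {self.score_mode!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["hidden_dims"] = list(self.hidden_dims)
        return d


@dataclass
class LatentPosterior:
    """Parameters of q(z|x): per-patient latent mean and log-variance."""

    mu: np.ndarray
    logvar: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.atleast_2d(np.asarray(self.mu, dtype=float))
        self.logvar = np.atleast_2d(np.asarray(self.logvar, dtype=float))
        if self.mu.shape != self.logvar.shape:
            raise ValueError("mu and logvar shapes differ")


_PARAM_SHAPES = (
    ("W1", "b1"),
    ("W2", "b2"),
    ("Wmu", "bmu"),
    ("Wlv", "blv"),
    ("V1", "c1"),
    ("V2", "c2"),
    ("V3", "c3"),
)


def _init_params(d: int, config: VAEConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Uniform fan-in initialization, U(-1/sqrt(fan_in), 1/sqrt(fan_in))."""
    h1, h2 = config.hidden_dims
    k = config.latent_dim
    if not k < d:
        raise ValueError(f"latent_dim ({k}) must be smaller than input_dim ({d})")
    dims = {
        "W1": (d, h1), "b1": (h1,),
        "W2": (h1, h2), "b2": (h2,),
        "Wmu": (h2, k), "bmu": (k,),
        "Wlv": (h2, k), "blv": (k,),
        "V1": (k, h2), "c1": (h2,),
        "V2": (h2, h1), "c2": (h1,),
        "V3": (h1, d), "c3": (d,),
    }
    params = {}
    for name, shape in dims.items():
        fan_in = shape[0] if len(shape) == 2 else dims[name.replace("b", "W").replace("c", "V")][0]
        bound = 1.0 / np.sqrt(fan_in)
        params[name] = rng.uniform(-bound, bound, size=shape)
    return params


@dataclass
class TrainedVAE:
    """A trained model: weights, config, per-epoch mean ELBO, and (optionally)
    the normalization statistics the inputs were produced with."""

    params: dict[str, np.ndarray]
    config: VAEConfig
    input_dim: int
    loss_curve: np.ndarray
    stats: NormalizationStats | None = None

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", loss_curve=self.loss_curve, **self.params)
        meta = {"config": self.config.to_dict(), "input_dim": self.input_dim}
        (directory / "model.json").write_text(json.dumps(meta, indent=1))
        if self.stats is not None:
            self.stats.to_json(directory / "normalization.json")

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedVAE":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        cfg = meta["config"]
        cfg["hidden_dims"] = tuple(cfg["hidden_dims"])
        config = VAEConfig(**cfg)
        with np.load(directory / "weights.npz") as z:
            arrays = {k: z[k] for k in z.files}
        loss_curve = arrays.pop("loss_curve")
        stats = None
        if (directory / "normalization.json").exists():
            stats = NormalizationStats.from_json(directory / "normalization.json")
        return cls(
            params=arrays,
            config=config,
            input_dim=int(meta["input_dim"]),
            loss_curve=loss_curve,
            stats=stats,
        )


def _relu(a: np.ndarray) -> np.ndarray:
    return np.maximum(a, 0.0)


def encode(x: np.ndarray, model: TrainedVAE) -> LatentPosterior:
    """Deterministic encoder pass: x -> (mu(x), log sigma^2(x))."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != model.input_dim:
        raise ValueError(f"input has {X.shape[1]} components, model expects {model.input_dim}")
    p = model.params
    h1 = _relu(X @ p["W1"] + p["b1"])
    h2 = _relu(h1 @ p["W2"] + p["b2"])
    mu = h2 @ p["Wmu"] + p["bmu"]
    logvar = h2 @ p["Wlv"] + p["blv"]
    if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(logvar))):
        raise FloatingPointError("encoder produced non-finite posterior parameters")
    return LatentPosterior(mu=mu, logvar=logvar)


def decode(z: np.ndarray, model: TrainedVAE) -> np.ndarray:
    """Decoder pass: z -> x_hat (linear output layer; Gaussian likelihood)."""
    Z = np.atleast_2d(np.asarray(z, dtype=float))
    p = model.params
    g1 = _relu(Z @ p["V1"] + p["c1"])
    g2 = _relu(g1 @ p["V2"] + p["c2"])
    return g2 @ p["V3"] + p["c3"]


def reparameterize(post: LatentPosterior, eps: np.ndarray) -> np.ndarray:
    """z = mu + sigma (.) eps, with sigma = exp(logvar / 2)."""
    eps = np.asarray(eps, dtype=float)
    if np.atleast_2d(eps).shape != post.mu.shape:
        raise ValueError("eps shape does not match the posterior")
    return post.mu + np.exp(post.logvar / 2.0) * np.atleast_2d(eps)


def kl_divergence(post: LatentPosterior) -> np.ndarray:
    """KL(q(z|x) || N(0, I)) per patient:
    -1/2 * sum_j (1 + log sigma_j^2 - mu_j^2 - sigma_j^2).  Nonnegative, zero
    iff mu = 0 and sigma^2 = 1."""
    return -0.5 * np.sum(1.0 + post.logvar - post.mu**2 - np.exp(post.logvar), axis=1)


def elbo_loss(
    x: np.ndarray, xhat: np.ndarray, post: LatentPosterior, beta: float = 1.0
) -> float:
    """Batch ELBO loss: mean over patients of ||x - x_hat||^2 + beta * KL."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    Xh = np.atleast_2d(np.asarray(xhat, dtype=float))
    recon = np.sum((X - Xh) ** 2, axis=1)
    return float(np.mean(recon + beta * kl_divergence(post)))


def _loss_and_grads(
    params: dict[str, np.ndarray], X: np.ndarray, eps: np.ndarray, beta: float
) -> tuple[float, dict[str, np.ndarray]]:
    """One forward/backward pass on a batch; returns (mean loss, grads)."""
    B = X.shape[0]

    # Forward.
    a1 = X @ params["W1"] + params["b1"]
    h1 = _relu(a1)
    a2 = h1 @ params["W2"] + params["b2"]
    h2 = _relu(a2)
    mu = h2 @ params["Wmu"] + params["bmu"]
    logvar = h2 @ params["Wlv"] + params["blv"]
    sigma = np.exp(logvar / 2.0)
    z = mu + sigma * eps
    a3 = z @ params["V1"] + params["c1"]
    g1 = _relu(a3)
    a4 = g1 @ params["V2"] + params["c2"]
    g2 = _relu(a4)
    xhat = g2 @ params["V3"] + params["c3"]

    resid = xhat - X
    recon = np.sum(resid**2, axis=1)
    kl = -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=1)
    loss = float(np.mean(recon + beta * kl))

    # Backward (gradients of the batch-mean loss).
    g = {}
    dxhat = 2.0 * resid / B
    g["V3"] = g2.T @ dxhat
    g["c3"] = dxhat.sum(axis=0)
    dg2 = (dxhat @ params["V3"].T) * (a4 > 0)
    g["V2"] = g1.T @ dg2
    g["c2"] = dg2.sum(axis=0)
    dg1 = (dg2 @ params["V2"].T) * (a3 > 0)
    g["V1"] = z.T @ dg1
    g["c1"] = dg1.sum(axis=0)
    dz = dg1 @ params["V1"].T

    dmu = dz + beta * mu / B
    dlogvar = dz * eps * 0.5 * sigma + beta * 0.5 * (np.exp(logvar) - 1.0) / B
    g["Wmu"] = h2.T @ dmu
    g["bmu"] = dmu.sum(axis=0)
    g["Wlv"] = h2.T @ dlogvar
    g["blv"] = dlogvar.sum(axis=0)
    dh2 = (dmu @ params["Wmu"].T + dlogvar @ params["Wlv"].T) * (a2 > 0)
    g["W2"] = h1.T @ dh2
    g["b2"] = dh2.sum(axis=0)
    dh1 = (dh2 @ params["W2"].T) * (a1 > 0)
    g["W1"] = X.T @ dh1
    g["b1"] = dh1.sum(axis=0)
    return loss, g


def train(
    matrix: MultimodalMatrix | np.ndarray,
    config: VAEConfig | None = None,
    stats: NormalizationStats | None = None,
) -> TrainedVAE:
    """Train the VAE with Adam on the full cohort.

    A single seeded generator drives initialization, per-epoch shuffling and
    latent sampling in a fixed order, so the loss curve of a shorter run is a
    prefix of a longer run with the same seed, and two serial runs are
    bit-identical.  The last incomplete batch is kept.  Raises on NaN loss
    with epoch/batch context.

    The recorded per-epoch loss curve is the full-cohort ELBO evaluated at the
    end of each epoch with the deterministic posterior-mean reconstruction
    (z = mu); it tracks optimization progress without the Monte-Carlo sampling
    noise of the in-epoch batch losses and consumes no randomness.
    """
    if config is None:
        config = VAEConfig()
    if isinstance(matrix, MultimodalMatrix):
        X = matrix.x
    else:
        X = np.atleast_2d(np.asarray(matrix, dtype=float))
    n, d = X.shape
    k = config.latent_dim
    rng = np.random.default_rng(config.seed)
    params = _init_params(d, config, rng)

    # Adam state.
    m = {kk: np.zeros_like(v) for kk, v in params.items()}
    v = {kk: np.zeros_like(vv) for kk, vv in params.items()}
    b1, b2, lr, eps_adam = 0.9, 0.999, config.learning_rate, 1e-8
    step = 0

    def cohort_elbo() -> float:
        p = params
        h1 = _relu(X @ p["W1"] + p["b1"])
        h2 = _relu(h1 @ p["W2"] + p["b2"])
        mu = h2 @ p["Wmu"] + p["bmu"]
        logvar = h2 @ p["Wlv"] + p["blv"]
        g1 = _relu(mu @ p["V1"] + p["c1"])
        g2 = _relu(g1 @ p["V2"] + p["c2"])
        xhat = g2 @ p["V3"] + p["c3"]
        recon = np.sum((X - xhat) ** 2, axis=1)
        kl = -0.5 * np.sum(1.0 + logvar - mu**2 - np.exp(logvar), axis=1)
        return float(np.mean(recon + config.beta * kl))

    loss_curve = np.empty(config.epochs)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            batch_idx = perm[start : start + config.batch_size]
            Xb = X[batch_idx]
            mc_losses = []
            grads_acc: dict[str, np.ndarray] | None = None
            for _ in range(config.mc_samples_train):
                eps = rng.standard_normal((len(batch_idx), k))
                loss, grads = _loss_and_grads(params, Xb, eps, config.beta)
                mc_losses.append(loss)
                if grads_acc is None:
                    grads_acc = grads
                else:
                    for kk in grads_acc:
                        grads_acc[kk] += grads[kk]
            loss = float(np.mean(mc_losses))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch}, batch starting at {start}"
                )
            assert grads_acc is not None
            if config.grad_clip is not None:
                gnorm = np.sqrt(
                    sum(np.sum((g / config.mc_samples_train) ** 2) for g in grads_acc.values())
                )
                if gnorm > config.grad_clip:
                    scale = config.grad_clip / gnorm
                    for kk in grads_acc:
                        grads_acc[kk] *= scale
            step += 1
            for kk in params:
                gk = grads_acc[kk] / config.mc_samples_train
                m[kk] = b1 * m[kk] + (1 - b1) * gk
                v[kk] = b2 * v[kk] + (1 - b2) * gk**2
                mhat = m[kk] / (1 - b1**step)
                vhat = v[kk] / (1 - b2**step)
                params[kk] -= lr * mhat / (np.sqrt(vhat) + eps_adam)
        loss_curve[epoch] = cohort_elbo()

    return TrainedVAE(
        params=params, config=config, input_dim=d, loss_curve=loss_curve, stats=stats
    )


def anomaly_score(
    x: np.ndarray,
    model: TrainedVAE,
    patient_ids: list[str] | None = None,
    severity: list[str] | None = None,
    score_mode: str | None = None,
    mc_samples: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score patients: A(x) = ||x - x_hat||^2 + beta * KL(q(z|x) || N(0, I)).

    With ``score_mode="mean-latent"`` (default) the reconstruction uses the
    deterministic latent mean, z = mu(x); with ``"sampled"``, the squared
    reconstruction error is averaged over ``mc_samples`` seeded latent draws.
    Returns a DataFrame with columns ``score``, ``recon``, ``kl`` (and
    ``severity`` if given), indexed by patient id, in input order.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    mode = score_mode or model.config.score_mode
    post = encode(X, model)
    kl = kl_divergence(post)

    if mode == "mean-latent":
        xhat = decode(post.mu, model)
        recon = np.sum((X - xhat) ** 2, axis=1)
    elif mode == "sampled":
        S = mc_samples or model.config.mc_samples_score
        rng = np.random.default_rng(model.config.seed if seed is None else seed)
        recon = np.zeros(X.shape[0])
        for _ in range(S):
            eps = rng.standard_normal(post.mu.shape)
            xhat = decode(reparameterize(post, eps), model)
            recon += np.sum((X - xhat) ** 2, axis=1)
        recon /= S
    else:
        raise ValueError(f"unknown score_mode {mode!r}")

    beta = model.config.beta
    out = pd.DataFrame(
        {"score": recon + beta * kl, "recon": recon, "kl": kl},
        index=pd.Index(
            patient_ids if patient_ids is not None else range(X.shape[0]), name="patient_id"
        ),
    )
    if severity is not None:
        out["severity"] = list(severity)
    return out


class MultimodalVAE:
    """Model object binding a fused multimodal matrix to the VAE.

    Construct directly from a prepared matrix, or with
    :meth:`from_dataframes`, which encodes binaries, fits the cohort
    normalizer and concatenates the modalities.  Severity labels are refused
    as model input by construction: the trainer sees only the multimodal
    matrix.

    >>> model = MultimodalVAE.from_dataframes(clinical, embeddings)
    >>> res = model.fit()
    >>> res.anomaly_scores()          # doctest: +SKIP
    """

    def __init__(
        self,
        matrix: MultimodalMatrix,
        config: VAEConfig | None = None,
        stats: NormalizationStats | None = None,
    ) -> None:
        self.matrix = matrix
        self.config = config or VAEConfig()
        self.stats = stats

    @classmethod
    def from_dataframes(
        cls,
        clinical: pd.DataFrame,
        embeddings: pd.DataFrame | None = None,
        config: VAEConfig | None = None,
    ) -> "MultimodalVAE":
        forbidden = {"severity", "severity_label", "group"} & set(map(str, clinical.columns))
        if forbidden:
            raise ValueError(
                f"severity labels must not enter the model input: remove columns {sorted(forbidden)}"
            )
        encoded = encode_binaries(clinical)
        stats = fit_normalizer(encoded, embeddings)
        matrix = build_multimodal_matrix(encoded, embeddings, stats)
        return cls(matrix, config=config, stats=stats)

    @property
    def n_patients(self) -> int:
        return self.matrix.x.shape[0]

    @property
    def input_dim(self) -> int:
        return self.matrix.d

    def fit(self) -> "VAEResults":
        trained = train(self.matrix, self.config, stats=self.stats)
        return VAEResults(self, trained)


class VAEResults:
    """Fit results: trained weights, loss curve, and anomaly scoring."""

    def __init__(self, model: MultimodalVAE, trained: TrainedVAE) -> None:
        self.model = model
        self.trained = trained

    @property
    def loss_curve(self) -> np.ndarray:
        return self.trained.loss_curve

    def anomaly_scores(
        self, severity: list[str] | None = None, score_mode: str | None = None
    ) -> pd.DataFrame:
        return anomaly_score(
            self.model.matrix.x,
            self.trained,
            patient_ids=self.model.matrix.patient_ids,
            severity=severity,
            score_mode=score_mode,
        )

    def summary(self, severity: list[str] | None = None, percentile: float = 85.0) -> str:
        from .analysis import flag_high_anomaly, summarize_scores

        scores = self.anomaly_scores(severity=severity)
        s = summarize_scores(scores["score"].to_numpy())
        flags = flag_high_anomaly(scores["score"].to_numpy(), severity, percentile=percentile)
        cfg = self.trained.config
        lines = [
            "Multimodal VAE anomaly detection",
            "=" * 40,
            f"patients            {self.model.n_patients}",
            f"input dim d         {self.model.input_dim}",
            f"latent dim k        {cfg.latent_dim}",
            f"beta                {cfg.beta}",
            f"epochs              {cfg.epochs}",
            f"final mean ELBO     {self.loss_curve[-1]:.4f}",
            "-" * 40,
            f"anomaly score median {s.median:.2f}  IQR {s.q25:.2f}-{s.q75:.2f}",
            f"range                {s.min:.2f}-{s.max:.2f}   skewness {s.skewness:.2f}",
            f"{percentile:g}th percentile   {flags.threshold:.2f}",
            f"flagged              {flags.flagged_count}/{s.n} "
            f"({100 * flags.flagged_count / s.n:.1f}%)",
        ]
        if flags.per_severity:
            per = ", ".join(f"{g}: {c}" for g, c in flags.per_severity.items())
            lines.append(f"flagged by severity  {per}")
        return "\n".join(lines)
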