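"""Variational autoencoders for fitness and MD-distance data.

Two variants are used:

* fitness VAE — encoder/decoder with 256/128/64-node dense layers on the
  63 fitness features, a 2-D (optionally 3-D) Gaussian latent;
* distance VAE — 128/64/32-node layers on the 62 distance features, with
  a self-attention layer applied after the 32-node layer on both the
  encoder and decoder side (an asymmetric placement relative to the pure
  mirror architecture).

The latent posterior is diagonal-Gaussian (mean + log-variance);
training samples via the reparameterisation trick and minimises
reconstruction error plus the standard-normal prior KL.  Projection uses
the posterior mean, and the latent space is grouped by k-means whose
clusters are relabelled in descending order of mean phenotype, so
cluster I is always the most GOF-like.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .metrics import Standardizer
from .nn.autodiff import Adam, Tensor
from .nn.layers import Dense, self_attention
from .nn.losses import vae_loss


@dataclass(frozen=True)
class VAESpec:
    """Architecture settings for the VAE variants."""

    input_width: int
    encoder_widths: tuple[int, ...]
    latent_dim: int = 2
    attention: bool = False
    #: scale attention similarities by 1/sqrt(d).  Softens the softmax and
    #: avoids saturated attention weights early in training, which
    #: otherwise traps the optimiser in poorly-reconstructing minima.
    scaled_attention: bool = True

    def __post_init__(self) -> None:
        if self.latent_dim not in (2, 3):
            raise ValueError("latent dimension must be 2 or 3")
        if not self.encoder_widths:
            raise ValueError("need at least one encoder layer")


def fitness_vae_spec(latent_dim: int = 2) -> VAESpec:
    return VAESpec(input_width=63, encoder_widths=(256, 128, 64), latent_dim=latent_dim)


def md_vae_spec(latent_dim: int = 2, attention: bool = True) -> VAESpec:
    return VAESpec(input_width=62, encoder_widths=(128, 64, 32),
                   latent_dim=latent_dim, attention=attention)


class VAE:
    """Encoder/decoder pair with a Gaussian latent.

    The decoder mirrors the encoder widths in reverse; with attention
    enabled, a self-attention layer follows the innermost (32-node) layer
    on both sides.
    """

    def __init__(self, spec: VAESpec, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng()
        self.spec = spec
        widths = [spec.input_width, *spec.encoder_widths]
        self.encoder_layers = [Dense(rng, widths[i], widths[i + 1])
                               for i in range(len(spec.encoder_widths))]
        inner = spec.encoder_widths[-1]
        self.mu_head = Dense(rng, inner, spec.latent_dim)
        self.logvar_head = Dense(rng, inner, spec.latent_dim)
        rev = [spec.latent_dim, *reversed(spec.encoder_widths)]
        self.decoder_layers = [Dense(rng, rev[i], rev[i + 1])
                               for i in range(len(spec.encoder_widths))]
        self.output_layer = Dense(rng, spec.encoder_widths[0], spec.input_width)

    # -- forward pieces ------------------------------------------------------

    def encode(self, x: Tensor) -> tuple[Tensor, Tensor]:
        h = x
        for layer in self.encoder_layers:
            h = layer(h).relu()
        if self.spec.attention:
            h = self_attention(h, scaled=self.spec.scaled_attention)
        return self.mu_head(h), self.logvar_head(h)

    def decode(self, z: Tensor) -> Tensor:
        h = z
        for i, layer in enumerate(self.decoder_layers):
            h = layer(h).relu()
            if i == 0 and self.spec.attention:   # after the 32-node layer
                h = self_attention(h, scaled=self.spec.scaled_attention)
        return self.output_layer(h)

    # -- parameters ----------------------------------------------------------

    @property
    def all_layers(self) -> list[Dense]:
        return [*self.encoder_layers, self.mu_head, self.logvar_head,
                *self.decoder_layers, self.output_layer]

    def parameters(self) -> list[Tensor]:
        return [p for layer in self.all_layers for p in layer.params]

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(weights):
            raise ValueError("weight count mismatch")
        for p, w in zip(params, weights):
            p.value = np.array(w, dtype=float)


@dataclass
class VAETrainConfig:
    learning_rate: float = 1e-4
    epochs: int = 2000
    batch_size: int = 4
    seed: int = 0
    recon: str = "sum"
    #: KL warm-up: the prior-KL weight ramps linearly from 0 to 1 over
    #: this many epochs, then stays at 1 (standard objective).  Prevents
    #: the regulariser from freezing latent directions before the
    #: encoder has learned them.
    kl_warmup_epochs: int = 500


def train_vae(model: VAE, X: np.ndarray, config: VAETrainConfig) -> list[float]:
    """Train with reparameterised sampling; returns the loss trajectory.

    ``X`` must already be standardised (see :class:`Standardizer`).
    Divergent loss aborts with the epoch reported.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate)
    trajectory: list[float] = []
    for epoch in range(1, config.epochs + 1):
        if config.kl_warmup_epochs > 0:
            kl_weight = min(1.0, epoch / config.kl_warmup_epochs)
        else:
            kl_weight = 1.0
        order = rng.permutation(n)
        total = 0.0
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb = Tensor.const(X[idx])
            mu, logvar = model.encode(xb)
            eps = Tensor.const(rng.standard_normal(mu.shape))
            z = mu + (logvar * 0.5).exp() * eps
            x_hat = model.decode(z)
            loss = vae_loss(xb, x_hat, mu, logvar, recon=config.recon,
                            kl_weight=kl_weight)
            if not np.isfinite(loss.value):
                raise FloatingPointError(f"VAE training diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.value)
            n_batches += 1
        trajectory.append(total / n_batches)
    return trajectory


def train_vae_restarts(spec: VAESpec, X: np.ndarray, config: VAETrainConfig,
                       n_restarts: int = 3, base_seed: int = 0
                       ) -> tuple[VAE, float]:
    """Train several VAEs from different initialisations; keep the best.

    Like k-means restarts, selection is by the final training loss — the
    VAE's own objective — which distinguishes well-fit models from runs
    stuck in poorly-reconstructing local minima.  Returns the winning
    model and its final training loss.
    """
    from dataclasses import replace

    best_model: VAE | None = None
    best_loss = np.inf
    for r in range(n_restarts):
        seed = base_seed + 1000 * r
        model = VAE(spec, rng=np.random.default_rng(seed))
        traj = train_vae(model, X, replace(config, seed=seed + 1))
        if traj[-1] < best_loss:
            best_model, best_loss = model, traj[-1]
    assert best_model is not None
    return best_model, best_loss


def evaluate_vae_loss(model: VAE, X: np.ndarray, recon: str = "sum") -> float:
    """Deterministic (mean-latent) loss for before/after comparisons."""
    xb = Tensor.const(np.asarray(X, dtype=float))
    mu, logvar = model.encode(xb)
    x_hat = model.decode(mu)
    return float(vae_loss(xb, x_hat, mu, logvar, recon=recon).value)


def project_latent(model: VAE, X: np.ndarray) -> np.ndarray:
    """Posterior-mean latent coordinates (no sampling): (n, latent_dim)."""
    mu, _ = model.encode(Tensor.const(np.asarray(X, dtype=float)))
    return mu.value


@dataclass
class ClusterModel:
    """k-means clusters of latent points, ordered by mean phenotype.

    Cluster 0 (reported as I) has the highest (most GOF-like) mean
    phenotype; the ordering makes cluster indices deterministic given the
    fitted model.
    """

    centroids: np.ndarray
    labels: np.ndarray
    cluster_phenotypes: np.ndarray = field(default=None)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


def cluster_latent(points: np.ndarray, k: int = 3, phenotypes=None,
                   seed: int = 0, n_init: int = 10) -> ClusterModel:
    """k-means with fixed seed and multiple restarts on latent points."""
    points = np.asarray(points, dtype=float)
    if k < 1 or k > points.shape[0]:
        raise ValueError(f"k={k} out of range for {points.shape[0]} points")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(points)
    labels = km.labels_
    centroids = km.cluster_centers_
    if phenotypes is not None:
        ph = np.asarray(phenotypes, dtype=float).ravel()
        means = np.array([ph[labels == c].mean() for c in range(k)])
        order = np.argsort(-means)                       # descending
        remap = np.empty(k, dtype=int)
        remap[order] = np.arange(k)
        labels = remap[labels]
        centroids = centroids[order]
        cluster_ph = means[order]
    else:
        cluster_ph = None
    return ClusterModel(centroids=centroids, labels=labels,
                        cluster_phenotypes=cluster_ph)


def decode_profiles(model: VAE, latent_points: np.ndarray,
                    standardizer: Standardizer, wt_profile: pd.Series,
                    names: list[str] | None = None) -> pd.DataFrame:
    """Decode latent points into distance profiles and Δdistance columns.

    The decoder output is de-standardised back to Å; Δdistance is the
    decoded profile minus the WT reference, per feature.
    """
    if wt_profile is None:
        raise ValueError("a WT reference profile is required")
    z = Tensor.const(np.atleast_2d(np.asarray(latent_points, dtype=float)))
    decoded = standardizer.inverse_transform(model.decode(z).value)
    names = list(wt_profile.index) if names is None else names
    frames = []
    for i, row in enumerate(decoded):
        frames.append(pd.DataFrame({
            "decoded_A": row,
            "delta_A": row - wt_profile.to_numpy(),
        }, index=pd.Index(names, name="pair")).assign(point=i))
    return pd.concat(frames)
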