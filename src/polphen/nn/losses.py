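"""Loss functions for the phenotype predictors and VAEs.

The supervised nets train on mean squared error, optionally combined 1:1
with a moment-matching Kullback-Leibler term that compares the Gaussian
summaries (mean, standard deviation) of the label and prediction
distributions:

    KL = 1/2 [ (sT/sP)^2 + (muT - muP)^2 / sP^2 - 1 + ln(sP^2 / sT^2) ]

which is the closed-form KL divergence between Normal(muT, sT^2) and
Normal(muP, sP^2).  When active, the moments are computed over the whole
training batch (the full 100-mutant training set in the standard
protocol).

The VAE loss is reconstruction error plus the closed-form KL divergence
of the diagonal-Gaussian posterior from the standard normal prior,
summed over latent dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor


@dataclass(frozen=True)
class MomentPair:
    """Means and standard deviations of label and prediction distributions."""

    mu_true: float
    sigma_true: float
    mu_pred: float
    sigma_pred: float

    def __post_init__(self) -> None:
        if not (self.sigma_true > 0 and self.sigma_pred > 0):
            raise ValueError(
                f"standard deviations must be positive "
                f"(sigma_true={self.sigma_true}, sigma_pred={self.sigma_pred})"
            )


def kl_moment_loss(m: MomentPair) -> float:
    """Closed-form Gaussian KL divergence between the two moment pairs.

    Non-negative everywhere; zero exactly when the moments coincide.
    """
    r2 = (m.sigma_true / m.sigma_pred) ** 2
    shift = (m.mu_true - m.mu_pred) ** 2 / m.sigma_pred ** 2
    return 0.5 * (r2 + shift - 1.0 + np.log(m.sigma_pred ** 2 / m.sigma_true ** 2))


_EPS = 1e-12  # variance floor inside the differentiable loss


def mse_tensor(y: Tensor, y_pred: Tensor) -> Tensor:
    d = y_pred - y
    return (d * d).mean()


def kl_moment_tensor(y: Tensor, y_pred: Tensor) -> Tensor:
    """Differentiable moment-KL over a batch of labels and predictions."""
    mu_t = y.mean()
    mu_p = y_pred.mean()
    var_t = ((y - mu_t) * (y - mu_t)).mean() + _EPS
    var_p = ((y_pred - mu_p) * (y_pred - mu_p)).mean() + _EPS
    shift = (mu_t - mu_p) * (mu_t - mu_p)
    return (var_t / var_p + shift / var_p - 1.0 + (var_p / var_t).log()) * 0.5


def combined_loss(y: Tensor, y_pred: Tensor, kl: bool = True) -> Tensor:
    """1:1 combination of MSE and the moment-KL term.

    With ``kl=False`` this is plain MSE.  The KL term needs at least two
    samples for moment estimation.
    """
    loss = mse_tensor(y, y_pred)
    if kl:
        if y.value.size < 2:
            raise ValueError("moment-KL loss needs a batch of at least 2 samples")
        loss = loss + kl_moment_tensor(y, y_pred)
    return loss


def combined_loss_np(y: np.ndarray, y_pred: np.ndarray, kl: bool = True) -> float:
    """Numpy evaluation of :func:`combined_loss` for reporting."""
    y = np.asarray(y, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    loss = float(np.mean((y_pred - y) ** 2))
    if kl:
        m = MomentPair(y.mean(), max(y.std(), np.sqrt(_EPS)),
                       y_pred.mean(), max(y_pred.std(), np.sqrt(_EPS)))
        loss += kl_moment_loss(m)
    return loss


def gaussian_prior_kl(mu: Tensor, logvar: Tensor) -> Tensor:
    """KL( N(mu, exp(logvar)) || N(0, I) ), summed over latent dims, mean over batch.

    Closed form per dimension: 1/2 (mu^2 + sigma^2 - 1 - ln sigma^2).
    """
    var = logvar.exp()
    per_dim = (mu * mu + var - 1.0 - logvar) * 0.5
    return per_dim.sum(axis=-1).mean()


def vae_loss(x: Tensor, x_hat: Tensor, mu: Tensor, logvar: Tensor,
             recon: str = "sum", kl_weight: float = 1.0) -> Tensor:
    """Reconstruction error plus standard-normal prior KL.

    ``recon='sum'`` (default) sums squared reconstruction error over
    features before averaging over the batch, which keeps the
    reconstruction and regularisation terms on comparable scales for the
    62-63 feature inputs used here; ``recon='mean'`` uses plain MSE.

    ``kl_weight`` scales the prior KL; training uses it for warm-up
    annealing (the weight ramps to 1, so the converged objective is the
    standard one).
    """
    d = x_hat - x
    if recon == "sum":
        rec = (d * d).sum(axis=-1).mean()
    elif recon == "mean":
        rec = (d * d).mean()
    else:
        raise ValueError(f"unknown reconstruction mode {recon!r}")
    kl = gaussian_prior_kl(mu, logvar)
    if kl_weight != 1.0:
        kl = kl * kl_weight
    return rec + kl
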