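"""Generalized-Gaussian statistics and discriminant-unit mathematics.

Bandpass filter responses to natural images are well modelled by the
generalized Gaussian distribution (GGD)

    p(x; alpha, beta) = beta / (2 alpha Gamma(1/beta)) exp(-(|x|/alpha)^beta),

with scale ``alpha`` and shape ``beta`` (around 0.5 for natural imagery).
A discriminant unit models one feature channel under a *target* and a
*background* (null) hypothesis, differing only in scale.  The unit's
log-likelihood ratio is an affine function of ``|x|^beta``,

    g(x) = gamma |x|^beta - T,
    gamma = 1/alpha0^beta - 1/alpha1^beta,   T = log(alpha1/alpha0),

so half-wave rectifying it yields a *parametric ReLU* psi(x) = max(g(x), 0)
whose gain and threshold are tuned by the class statistics.  Depending on
the sign of gamma the unit detects feature presence (gamma > 0) or feature
absence (gamma < 0).

Scales are stored and exchanged as ``alpha^beta`` ("scale power")
throughout: every formula in the model consumes that quantity, and it is
the direct output of the conjugate-prior MAP estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, gamma as gamma_fn

__all__ = [
    "GGDClassModel",
    "RectifierParams",
    "EstimatorPrior",
    "ggd_pdf",
    "map_scale_estimate",
    "log_likelihood_ratio",
    "rectifier_from_model",
    "parametric_relu",
    "target_posterior",
    "expected_saliency",
]

DEFAULT_SHAPE = 0.5


@dataclass(frozen=True)
class EstimatorPrior:
    """Hyper-parameters of the conjugate Gamma prior of the MAP scale estimator.

    ``eta`` enters the effective sample size kappa = n + eta*beta and ``nu``
    is an additive pseudo-observation mass that keeps estimates away from
    zero.  Neither value is critical; the defaults follow the model's
    reference configuration.
    """

    eta: float = 1.0
    nu: float = 1e-3

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.nu <= 0:
            raise ValueError(f"prior hyper-parameters must be positive, got eta={self.eta}, nu={self.nu}")


@dataclass(frozen=True)
class GGDClassModel:
    """Per-channel GGD scale powers for background (index 0) and target (index 1).

    Parameters
    ----------
    scale_pow_background : float
        alpha0^beta, in units response^beta.
    scale_pow_target : float
        alpha1^beta, same units.
    shape : float
        Shared shape beta, in (0, 2].
    """

    scale_pow_background: float
    scale_pow_target: float
    shape: float = DEFAULT_SHAPE

    def __post_init__(self) -> None:
        if self.scale_pow_background <= 0 or self.scale_pow_target <= 0:
            raise ValueError("GGD scale powers must be strictly positive")
        if not 0 < self.shape <= 2:
            raise ValueError(f"GGD shape must lie in (0, 2], got {self.shape}")

    def to_dict(self) -> dict:
        return {
            "scale_pow_background": self.scale_pow_background,
            "scale_pow_target": self.scale_pow_target,
            "shape": self.shape,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GGDClassModel":
        return cls(**d)


@dataclass(frozen=True)
class RectifierParams:
    """Gain/threshold pair (gamma, T) of the class-tuned parametric ReLU."""

    gain: float
    threshold: float
    shape: float = DEFAULT_SHAPE

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("shape must be positive")
        # gamma and T always share a sign: both are monotone in alpha1/alpha0,
        # and they vanish together (exactly when alpha1 = alpha0).
        if np.sign(self.gain) != np.sign(self.threshold):
            raise ValueError("gain and threshold must share their sign (both zero iff scales match)")

    def to_dict(self) -> dict:
        return {"gain": self.gain, "threshold": self.threshold, "shape": self.shape}

    @classmethod
    def from_dict(cls, d: dict) -> "RectifierParams":
        return cls(**d)


def ggd_pdf(x, scale, shape):
    """Generalized Gaussian density with scale ``alpha`` and shape ``beta``.

    Vectorized over ``x``.  Symmetric, unimodal at 0, integrates to one.
    """
    if scale <= 0 or shape <= 0:
        raise ValueError(f"scale and shape must be positive, got scale={scale}, shape={shape}")
    x = np.asarray(x, dtype=float)
    norm = shape / (2.0 * scale * gamma_fn(1.0 / shape))
    return norm * np.exp(-np.power(np.abs(x) / scale, shape))


def abs_pow(x, shape):
    """|x|^beta with the convention 0^beta = 0 exactly (feedforward only)."""
    x = np.asarray(x, dtype=float)
    out = np.power(np.abs(x), shape)
    return out


def map_scale_estimate(samples, shape=DEFAULT_SHAPE, prior: EstimatorPrior | None = EstimatorPrior()):
    """MAP estimate of the GGD scale power alpha^beta under a conjugate Gamma prior.

        alpha^beta = (sum_j |x_j|^beta + nu) / kappa,   kappa = n + eta*beta.

    ``prior=None`` disables the prior entirely (eta = nu = 0), reducing the
    estimator to the plain sample mean of |x|^beta.  Note the estimator
    converges to E|X|^beta = alpha^beta / beta, not alpha^beta itself; all
    consumers in the model use the same estimator, so the ratios that define
    the rectifier threshold are unaffected.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size and not np.all(np.isfinite(samples)):
        raise ValueError("samples must be finite")
    if prior is None:
        if samples.size == 0:
            raise ValueError("prior-free estimation needs at least one sample")
        return float(np.sum(abs_pow(samples, shape)) / samples.size)
    kappa = samples.size + prior.eta * shape
    return float((np.sum(abs_pow(samples, shape)) + prior.nu) / kappa)


def log_likelihood_ratio(x, model: GGDClassModel):
    """Log-likelihood ratio g(x) = gamma |x|^beta - T of target vs background.

    Even in x; g(0) = log(alpha0/alpha1) = -T.
    """
    r = rectifier_from_model(model)
    return r.gain * abs_pow(x, model.shape) - r.threshold


def rectifier_from_model(model: GGDClassModel) -> RectifierParams:
    """Derive the parametric-ReLU (gamma, T) from a two-class GGD model.

    gamma = 1/alpha0^beta - 1/alpha1^beta and T = log(alpha1/alpha0); when
    the two scales coincide both vanish and the unit is silent.
    """
    a0 = model.scale_pow_background
    a1 = model.scale_pow_target
    gain = 1.0 / a0 - 1.0 / a1
    # log(alpha1/alpha0) = (1/beta) log(alpha1^beta / alpha0^beta)
    threshold = np.log(a1 / a0) / model.shape
    if gain == 0.0 or threshold == 0.0:
        # the two vanish together analytically; keep that exact in floats
        gain = 0.0
        threshold = 0.0
    return RectifierParams(gain=float(gain), threshold=float(threshold), shape=model.shape)


def parametric_relu(x, params: RectifierParams):
    """Class-tuned rectifier psi(x) = max(gamma |x|^beta - T, 0).

    Identical to half-wave rectifying the log-likelihood ratio.  Its dead
    zone (output exactly zero) sits at |x|^beta <= T/gamma for a presence
    detector (gamma > 0) and at |x|^beta >= T/gamma for an absence detector
    (gamma < 0).
    """
    g = params.gain * abs_pow(x, params.shape) - params.threshold
    return np.maximum(g, 0.0)


def target_posterior(x, model: GGDClassModel):
    """Posterior probability of the target class, sigma(g(x))."""
    return expit(log_likelihood_ratio(x, model))


def expected_saliency(model: GGDClassModel, local_scale_pow):
    """Expected saliency gamma * alpha1^beta(l) - T from a local scale estimate.

    ``local_scale_pow`` is a MAP estimate of the scale power over a pooling
    neighborhood; since that estimator converges to E|X|^beta, the returned
    value equals E[g(X) | target] in the large-sample limit (the KL
    divergence between the local response distribution and the background).
    """
    local_scale_pow = np.asarray(local_scale_pow, dtype=float)
    if np.any(local_scale_pow <= 0):
        raise ValueError("local_scale_pow must be strictly positive")
    r = rectifier_from_model(model)
    out = r.gain * local_scale_pow - r.threshold
    return float(out) if out.ndim == 0 else out
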