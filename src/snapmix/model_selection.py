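"""Bayesian evidence (IS-HME), BIC/AIC, and normalized model weights.

The evidence P(h|M) = integral L(theta) pi(theta) dtheta is estimated with
the importance-sampled harmonic-mean estimator of Robert & Wraith: an
importance density phi supported strictly inside the posterior — here the
uniform density on the Mahalanobis ellipsoid (in log-parameter space) that
contains an alpha-fraction of the posterior draws — gives the unbiased
identity

    1/Z = E_post[ phi(theta) / (L(theta) pi(theta)) ],

estimated by an average over the stored MCMC draws.  Working in ln(theta)
coordinates keeps phi and the (there-uniform) log-uniform prior density in
the same measure.  BIC and AIC are the usual large-sample surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .mcmc import PosteriorChain, PriorSpec

__all__ = [
    "EvidenceResult",
    "ishme_core",
    "is_hme_evidence",
    "bic",
    "aic",
    "model_weights",
    "ModelRanking",
]


@dataclass
class EvidenceResult:
    log_evidence: float
    standard_error: float
    method: str
    k: int | None = None
    n: int | None = None
    n_inside: int | None = None


def ishme_core(
    draws: np.ndarray,
    log_target: np.ndarray,
    alpha: float = 0.25,
    n_batches: int = 20,
) -> EvidenceResult:
    """Robert-Wraith estimator from posterior draws in arbitrary coordinates.

    Parameters
    ----------
    draws
        (T, d) posterior draws, in whatever coordinates the densities use.
    log_target
        Unnormalized log posterior density at each draw, *in the same
        coordinates* (log-likelihood + log prior density with its
        normalization constant).
    alpha
        Fraction of draws the importance ellipsoid must contain.
    """
    X = np.atleast_2d(np.asarray(draws, dtype=float))
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError("need at least d + 2 draws")
    log_target = np.asarray(log_target, dtype=float)
    T, d = X.shape
    mu = X.mean(axis=0)
    cov = np.cov(X, rowvar=False).reshape(d, d)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0 or not np.isfinite(logdet):
        raise np.linalg.LinAlgError(
            "singular posterior covariance; thin less or jitter the draws"
        )
    Z = X - mu
    maha = np.einsum("ij,jk,ik->i", Z, np.linalg.inv(cov), Z)
    q_alpha = float(np.quantile(maha, alpha))
    if q_alpha <= 0:
        raise ValueError("degenerate draws: alpha-quantile of Mahalanobis^2 is 0")
    inside = maha <= q_alpha
    n_inside = int(inside.sum())
    if n_inside == 0:
        raise ValueError("no draws inside the importance ellipsoid")
    log_volume = (
        0.5 * d * np.log(np.pi)
        - gammaln(0.5 * d + 1.0)
        + 0.5 * d * np.log(q_alpha)
        + 0.5 * logdet
    )
    log_phi = -log_volume
    # harmonic-mean terms: phi / target for draws inside, 0 outside
    terms = np.where(inside, log_phi - log_target, -np.inf)
    log_inv_z = logsumexp(terms) - np.log(T)
    # batch means on the linear scale (delta method for the log)
    scale = terms[np.isfinite(terms)].max()
    w = np.where(np.isfinite(terms), np.exp(terms - scale), 0.0)
    nb = min(n_batches, max(2, T // 4))
    batches = np.array_split(w, nb)
    means = np.array([b.mean() for b in batches])
    se_lin = means.std(ddof=1) / np.sqrt(nb)
    se = float(se_lin / w.mean()) if w.mean() > 0 else np.inf
    return EvidenceResult(
        log_evidence=float(-log_inv_z),
        standard_error=se,
        method="IS-HME",
        n_inside=n_inside,
    )


def is_hme_evidence(
    chain: PosteriorChain,
    prior: PriorSpec,
    alpha: float = 0.25,
    log_l: np.ndarray | None = None,
) -> EvidenceResult:
    """Evidence of a fitted model from its posterior chain.

    Draws are mapped to ln(theta) coordinates, where the log-uniform prior
    density is the constant ``prior.log_density_logspace()``.  ``log_l``
    overrides the stored log-likelihoods (e.g. after re-evaluating draws
    with a larger mixture kernel).
    """
    ll = chain.log_l if log_l is None else np.asarray(log_l, dtype=float)
    if ll.shape[0] != chain.n_draws:
        raise ValueError("log_l length mismatch")
    X = np.log(chain.draws)
    log_target = ll + prior.log_density_logspace()
    res = ishme_core(X, log_target, alpha=alpha)
    res.k = chain.draws.shape[1]
    return res


def bic(max_log_l: float, k: int, n: int) -> float:
    """Schwarz criterion: k ln n - 2 max ln L (lower is better)."""
    if n < 1 or k < 0:
        raise ValueError("need n >= 1 and k >= 0")
    return k * float(np.log(n)) - 2.0 * max_log_l


def aic(max_log_l: float, k: int) -> float:
    """Akaike criterion: 2k - 2 max ln L (lower is better)."""
    if k < 0:
        raise ValueError("need k >= 0")
    return 2.0 * k - 2.0 * max_log_l


@dataclass
class ModelRanking:
    table: pd.DataFrame  # columns: code, value, weight; sorted by weight desc

    @property
    def codes(self) -> list[str]:
        return list(self.table["code"])

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy()


def model_weights(values: dict[str, float], kind: str) -> ModelRanking:
    """Normalized model probabilities from log-evidences or criterion values.

    kind='evidence': w_i = exp(logZ_i - logsumexp(logZ)).
    kind='bic'/'aic': w_i proportional to exp(-(value_i - min value)/2).
    Returned sorted by decreasing weight.
    """
    if not values:
        raise ValueError("need at least one model")
    codes = list(values)
    v = np.array([values[c] for c in codes], dtype=float)
    if kind == "evidence":
        logw = v - logsumexp(v)
    elif kind in ("bic", "aic"):
        logw = -(v - v.min()) / 2.0
        logw -= logsumexp(logw)
    else:
        raise ValueError("kind must be 'evidence', 'bic' or 'aic'")
    w = np.exp(logw)
    df = pd.DataFrame({"code": codes, "value": v, "weight": w})
    df = df.sort_values("weight", ascending=False, kind="stable").reset_index(drop=True)
    return ModelRanking(df)
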