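"""Step 1: maximum-likelihood NB parameters from annotated single-cell counts.

The model for a count of gene g in cell c of type z is

    y_gc ~ NB(s_c * r_gz, p_g),    s_c = library size of cell c,

with the pmf convention

    P(k) = Gamma(k + r) / (Gamma(r) k!) * p^k * (1 - p)^r,

so the mean is r p / (1 - p) and, crucially, NB variables sharing p are
additive in r: NB(r1, p) + NB(r2, p) ~ NB(r1 + r2, p). The per-type rates
r_gz and per-gene success probabilities p_g are found by minimizing the
negative log-likelihood with Adam on unconstrained parameters
(rates through softplus, probabilities through a sigmoid).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, expit, gammaln

from .data_io import Annotation, ExpressionMatrix, ValidationError
from .optim import Adam
from .preprocess import drop_zero_genes, drop_zero_observations, library_sizes

_RATE_FLOOR = 1e-12


def softplus(x: np.ndarray | float) -> np.ndarray | float:
    return np.logaddexp(0.0, x)


def _inv_softplus(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    # log(e^y - 1), stable for large y
    return y + np.log1p(-np.exp(-np.maximum(y, 1e-12)))


def nb_log_pmf(k, r, p):
    """Log pmf of the negative binomial in the (rate, success-prob) convention.

    ``log Gamma(k+r) - log Gamma(r) - log k! + k log p + r log(1-p)``.
    Broadcasts over array inputs. Domain violations raise ``ValueError``.
    """
    k = np.asarray(k, dtype=float)
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if (k < 0).any() or np.any(k != np.round(k)):
        raise ValueError("k must be a nonnegative integer count")
    if (r <= 0).any():
        raise ValueError("rate r must be positive")
    if (p <= 0).any() or (p >= 1).any():
        raise ValueError("success probability p must lie in (0, 1)")
    out = (
        gammaln(k + r) - gammaln(r) - gammaln(k + 1)
        + k * np.log(p) + r * np.log1p(-p)
    )
    return out if out.ndim else float(out)


@dataclass
class FitConfig:
    """Gradient-fit settings; defaults follow the reference analysis values."""

    epochs: int = 50_000
    learning_rate: float = 0.01
    batch_size: int | None = None  # None = full batch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class SCParams:
    """Fitted single-cell NB parameters.

    ``log_rates`` and ``p_logits`` are the unconstrained optimizer variables;
    the model-scale parameters are ``rates = softplus(log_rates)`` and
    ``p = sigmoid(p_logits)``.
    """

    type_labels: list[str]
    gene_ids: list[str]
    log_rates: np.ndarray  # |G| x |Z|
    p_logits: np.ndarray  # |G|
    loss_history: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.log_rates = np.asarray(self.log_rates, dtype=float)
        self.p_logits = np.asarray(self.p_logits, dtype=float)
        G, Z = len(self.gene_ids), len(self.type_labels)
        if self.log_rates.shape != (G, Z):
            raise ValidationError("log_rates shape mismatch")
        if self.p_logits.shape != (G,):
            raise ValidationError("p_logits shape mismatch")

    @property
    def rates(self) -> np.ndarray:
        return softplus(self.log_rates)

    @property
    def p(self) -> np.ndarray:
        return expit(self.p_logits)


def _nll_terms(Y: np.ndarray, mu: np.ndarray, log_p: np.ndarray,
               log_1mp: np.ndarray, gl_k1: np.ndarray) -> float:
    """Negative log-likelihood of counts Y under rates mu (same shape)."""
    ll = gammaln(Y + mu) - gammaln(mu) - gl_k1 + Y * log_p + mu * log_1mp
    return float(-ll.sum())


def fit_sc(sc: ExpressionMatrix, ann: Annotation, cfg: FitConfig | None = None) -> SCParams:
    """Maximum-likelihood fit of r_gz and p_g by Adam on the NB NLL.

    Cells with zero library size are dropped with a warning; genes with zero
    total count are removed before fitting (their rate is unidentifiable).
    All types' rates and the shared p are optimized jointly — the likelihood
    factorizes over genes, so this equals per-gene fitting.
    """
    cfg = cfg or FitConfig()
    sc = drop_zero_observations(sc, "cells")
    sc = drop_zero_genes(sc)
    ann = ann.subset(sc.obs_ids)

    types = ann.types
    type_index = {t: i for i, t in enumerate(types)}
    G, Z = sc.n_genes, len(types)
    C = sc.n_obs
    Y = np.asarray(sc.dense(), dtype=float)
    s = library_sizes(sc)
    zidx = np.array([type_index[l] for l in ann.labels])
    gl_k1 = gammaln(Y + 1.0)

    rng = np.random.default_rng(cfg.seed)
    # method-of-moments start: at the p = 0.5 initialization the NB mean is
    # s_c * r, so r0 = per-type mean count over library size; jitter breaks ties
    r0 = np.empty((G, Z))
    for z in range(Z):
        mask = zidx == z
        r0[:, z] = Y[mask].sum(axis=0) / s[mask].sum()
    U = _inv_softplus(np.maximum(r0, 1e-6)) + rng.normal(0.0, 0.1, size=(G, Z))
    q = np.zeros(G)  # p logits, start at p = 0.5
    opt = Adam([U, q], lr=cfg.learning_rate)
    batch = cfg.batch_size if cfg.batch_size is not None and cfg.batch_size < C else None

    history = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        if batch is None:
            Yb, sb, zb, glb, scale = Y, s, zidx, gl_k1, 1.0
        else:
            sel = rng.choice(C, size=batch, replace=False)
            Yb, sb, zb, glb = Y[sel], s[sel], zidx[sel], gl_k1[sel]
            scale = C / batch
        R = softplus(U) + _RATE_FLOOR
        p = expit(q)
        log_p, log_1mp = np.log(p), np.log1p(-p)
        mu = sb[:, None] * R[:, zb].T
        A = digamma(Yb + mu) - digamma(mu) + log_1mp[None, :]
        acc = np.zeros((Z, G))
        np.add.at(acc, zb, A * sb[:, None])
        gU = -scale * acc.T * expit(U)
        gq = -scale * (Yb * (1.0 - p)[None, :] - mu * p[None, :]).sum(axis=0)
        nll = scale * _nll_terms(Yb, mu, log_p, log_1mp, glb)
        if not np.isfinite(nll):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}; try a lower learning rate"
            )
        opt.step([gU, gq])
        history[epoch] = nll

    return SCParams(types, list(sc.gene_ids), U, q, history)


def sc_nll(params: SCParams, sc: ExpressionMatrix, ann: Annotation) -> float:
    """Negative log-likelihood of single-cell counts under fitted parameters."""
    ann = ann.subset(sc.obs_ids)
    Y = np.asarray(sc.subset_genes(params.gene_ids).dense(), dtype=float)
    s = library_sizes(sc)
    zidx = np.array([params.type_labels.index(l) for l in ann.labels])
    mu = s[:, None] * params.rates[:, zidx].T
    return float(-nb_log_pmf(Y, mu, params.p[None, :]).sum())
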