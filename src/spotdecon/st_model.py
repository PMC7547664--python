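"""Step 2: MAP deconvolution of spatial spots given frozen single-cell params.

Each spot's counts are modeled as

    x_sg ~ NB(beta_g * v_s . r_g + gamma_s * eps_g, p_g)

where r_g (per-type rates) and p_g come from the single-cell fit and are
held fixed; v_sz is the scaled quantity coefficient (spot scaling factor
times cell count — only their product is identifiable), beta_g a per-gene
technique bias, and (gamma_s, eps_g) a noise-absorbing "dummy" type whose
rates carry a standard-normal prior to discourage promiscuous use. All free
parameters are unconstrained with softplus positivity transforms; the prior
is placed on the unconstrained dummy-rate parameter. Proportions are the
within-spot normalization of v, the dummy type excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, expit, gammaln

from .data_io import ExpressionMatrix, ProportionMatrix, ValidationError
from .optim import Adam
from .preprocess import drop_zero_observations
from .sc_model import (
    FitConfig,
    SCParams,
    _RATE_FLOOR,
    _inv_softplus as _inv_sp,
    _nll_terms,
    softplus,
)

_OFF = -30.0  # unconstrained value whose softplus is numerically negligible


@dataclass
class SpatialFit:
    """MAP point estimates for one joint spatial fit."""

    spot_ids: list[str]
    type_labels: list[str]
    v: np.ndarray  # |S| x |Z|, > 0
    beta: np.ndarray  # |G|, > 0
    gamma: np.ndarray  # |S|, > 0
    epsilon: np.ndarray  # |G|, unconstrained dummy-rate parameters
    gene_ids: list[str] = field(default_factory=list)
    loss_history: np.ndarray = field(default_factory=lambda: np.array([]))
    # per-fit global scale constants: v and gamma are reported in "cell
    # quantity" units where the type rates are r * v_scale and the dummy
    # type's gene rates are eps_scale * softplus(epsilon); proportions and
    # dummy shares are invariant to both
    v_scale: float = 1.0
    eps_scale: float = 1.0

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        S, Z = len(self.spot_ids), len(self.type_labels)
        if self.v.shape != (S, Z):
            raise ValidationError("v shape mismatch")
        if self.gamma.shape != (S,):
            raise ValidationError("gamma shape mismatch")
        if self.beta.shape != self.epsilon.shape:
            raise ValidationError("beta/epsilon shape mismatch")
        if (self.v <= 0).any() or (self.beta <= 0).any() or (self.gamma <= 0).any():
            raise ValidationError("v, beta and gamma must be strictly positive")

    @property
    def dummy_share(self) -> np.ndarray:
        """Unnormalized weight of the dummy type: gamma / (gamma + sum_z v)."""
        tot = self.v.sum(axis=1)
        return self.gamma / (self.gamma + tot)


def spot_rate(v_s, beta_g, r_g, gamma_s=0.0, eps_g=_OFF):
    """NB rate of one (spot, gene): beta_g * v_s . r_g + gamma_s * softplus(eps_g)."""
    v_s = np.asarray(v_s, dtype=float)
    r_g = np.asarray(r_g, dtype=float)
    if not (np.all(np.isfinite(v_s)) and np.isfinite(beta_g) and np.isfinite(gamma_s)
            and np.all(np.isfinite(r_g)) and np.isfinite(eps_g)):
        raise ValueError("non-finite input to spot_rate")
    if (v_s < 0).any() or beta_g <= 0 or (r_g <= 0).any() or gamma_s < 0:
        raise ValueError("positivity constraint violated in spot_rate")
    return float(beta_g * v_s @ r_g + gamma_s * softplus(eps_g))


def fit_st(
    sp: ExpressionMatrix,
    params: SCParams,
    cfg: FitConfig | None = None,
    *,
    use_dummy: bool = True,
    fit_beta: bool = True,
    dummy_prior: bool = True,
) -> SpatialFit:
    """MAP fit of v, beta, gamma, eps with r and p frozen.

    Genes are aligned by id to the single-cell parameters (order of the
    single-cell gene list restricted to the intersection); spots with zero
    total count are dropped with a warning. ``use_dummy=False`` and
    ``fit_beta=False`` pin those components to their neutral values, which
    is useful for controlled comparisons against exhaustive searches.
    """
    cfg = cfg or FitConfig()
    genes = [g for g in params.gene_ids if g in set(sp.gene_ids)]
    if not genes:
        raise ValidationError("no genes shared between spatial data and parameters")
    sp = sp.subset_genes(genes)
    sp = drop_zero_observations(sp, "spots")
    gidx = [params.gene_ids.index(g) for g in genes]
    R = params.rates[gidx]  # G x Z, fixed
    p = params.p[gidx]
    S, G = sp.n_obs, sp.n_genes
    Z = len(params.type_labels)
    X = np.asarray(sp.dense(), dtype=float)
    gl_k1 = gammaln(X + 1.0)
    log_p, log_1mp = np.log(p), np.log1p(-p)

    rng = np.random.default_rng(cfg.seed)
    # Rescale the frozen rates so the per-spot quantities v are O(1): with
    # beta = 1 and equal proportions the expected spot total is
    # sum_gz v0 r_gz p_g/(1-p_g), so solving for v0 gives the natural scale.
    # Softplus behaves like identity far above 0, so Adam's bounded steps
    # cannot traverse v ~ 1e4; folding the median v0 into the rates keeps
    # the unconstrained parameters in a well-conditioned range. Proportions
    # are invariant to this per-fit global rescaling.
    odds = p / (1.0 - p)
    denom = float((R * odds[:, None]).sum())
    v0 = np.maximum(X.sum(axis=1) / max(denom, _RATE_FLOOR), 1e-6)
    v_scale = float(np.median(v0))
    R_fit = R * v_scale
    # the dummy type's per-gene rates are e0 * softplus(eps): e0 pins them to
    # the magnitude of a typical cell type's rates, so gamma lives in the
    # same quantity units as v (a flat-prior reparameterization of gamma)
    e0 = float(R_fit.mean())
    Uv = _inv_sp(np.repeat(v0[:, None] / v_scale, Z, axis=1)) + rng.normal(
        0.0, 0.1, size=(S, Z)
    )
    Ub = rng.normal(0.0, 0.1, size=G) if fit_beta else None
    Ug = rng.normal(0.0, 0.1, size=S) if use_dummy else None
    Ue = rng.normal(0.0, 0.1, size=G) if use_dummy else None

    free = [Uv] + [u for u in (Ub, Ug, Ue) if u is not None]
    opt = Adam(free, lr=cfg.learning_rate)
    batch = cfg.batch_size if cfg.batch_size is not None and cfg.batch_size < S else None

    history = np.empty(cfg.epochs)
    ones_g = np.ones(G)
    for epoch in range(cfg.epochs):
        if batch is None:
            rows, scale = slice(None), 1.0
        else:
            rows, scale = rng.choice(S, size=batch, replace=False), S / batch
        v = softplus(Uv[rows]) + _RATE_FLOOR
        beta = softplus(Ub) + _RATE_FLOOR if fit_beta else ones_g
        M = v @ R_fit.T  # spots x genes, sum_z v_sz r_gz
        mu = beta[None, :] * M
        if use_dummy:
            gam = softplus(Ug[rows]) + _RATE_FLOOR
            eps_pos = e0 * softplus(Ue) + _RATE_FLOOR
            mu = mu + gam[:, None] * eps_pos[None, :]
        Xb, glb = X[rows], gl_k1[rows]
        D = digamma(Xb + mu) - digamma(mu) + log_1mp[None, :]

        grads = []
        gUv = np.zeros_like(Uv)
        gUv[rows] = -scale * ((D * beta[None, :]) @ R_fit) * expit(Uv[rows])
        grads.append(gUv)
        if fit_beta:
            grads.append(-scale * (D * M).sum(axis=0) * expit(Ub))
        if use_dummy:
            gUg = np.zeros_like(Ug)
            gUg[rows] = -scale * (D @ eps_pos) * expit(Ug[rows])
            grads.append(gUg)
            gUe = -scale * e0 * (D * gam[:, None]).sum(axis=0) * expit(Ue)
            if dummy_prior:
                gUe = gUe + Ue
            grads.append(gUe)

        loss = scale * _nll_terms(Xb, mu, log_p, log_1mp, glb)
        if use_dummy and dummy_prior:
            loss += 0.5 * float(Ue @ Ue)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"non-finite loss at epoch {epoch}; try a lower learning rate"
            )
        opt.step(grads)
        history[epoch] = loss

    return SpatialFit(
        spot_ids=list(sp.obs_ids),
        type_labels=list(params.type_labels),
        v=softplus(Uv) + _RATE_FLOOR,
        beta=softplus(Ub) + _RATE_FLOOR if fit_beta else ones_g.copy(),
        gamma=softplus(Ug) + _RATE_FLOOR if use_dummy else np.full(S, _RATE_FLOOR),
        epsilon=Ue.copy() if use_dummy else np.full(G, _OFF),
        gene_ids=genes,
        loss_history=history,
        v_scale=v_scale,
        eps_scale=e0,
    )


def st_nll(fit: SpatialFit, sp: ExpressionMatrix, params: SCParams) -> float:
    """Data negative log-likelihood of spatial counts under a fit (no prior)."""
    from .sc_model import nb_log_pmf

    sp = sp.subset_genes(fit.gene_ids)
    gidx = [params.gene_ids.index(g) for g in fit.gene_ids]
    R, p = params.rates[gidx], params.p[gidx]
    X = np.asarray(sp.subset_obs(fit.spot_ids).dense(), dtype=float)
    mu = (
        fit.beta[None, :] * (fit.v @ (R * fit.v_scale).T)
        + fit.gamma[:, None] * fit.eps_scale * softplus(fit.epsilon)[None, :]
    )
    return float(-nb_log_pmf(X, mu, p[None, :]).sum())


def compute_proportions(fit: SpatialFit) -> ProportionMatrix:
    """Within-spot normalization of v (dummy excluded): w_sz = v_sz / sum_z v_sz."""
    tot = fit.v.sum(axis=1)
    if (tot <= 0).any():
        raise ValidationError("cannot normalize a spot with all-zero quantities")
    w = fit.v / tot[:, None]
    return ProportionMatrix(
        list(fit.spot_ids), list(fit.type_labels), w, dummy_share=fit.dummy_share
    )
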